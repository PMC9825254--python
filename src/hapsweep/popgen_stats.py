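"""Haplotype homozygosity statistics, diversity and linkage disequilibrium.

The sweep-detection statistics operate on the *haplotype frequency spectrum*
of a window: H1 = sum(p_i^2) is standard haplotype homozygosity, H12 pools the
two most frequent haplotypes, H2 = H1 - p_1^2 excludes the most frequent one,
and H2/H1 rises monotonically with the softness of a sweep (low for hard
sweeps, where a single haplotype dominates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class HaplotypeSpectrum:
    """Descending haplotype-class frequencies for one analysis window."""

    frequencies: np.ndarray  # descending, sums to 1
    n: int
    singleton_count: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size == 0:
            raise ValueError("empty spectrum")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if np.any(np.diff(self.frequencies) > 1e-15):
            raise ValueError("frequencies must be sorted descending")


@dataclass
class HStats:
    h1: float
    h2: float
    h12: float
    h2_h1: float


@dataclass
class DiversityEstimate:
    s_per_bp: float
    pi_per_bp: float
    s_ci: tuple[float, float]
    pi_ci: tuple[float, float]
    n_windows: int


@dataclass
class LDProfile:
    """Pairwise R² against distance: binned means plus the raw pair records."""

    distances: np.ndarray  # bin representative distance (bp) or raw distance
    r2: np.ndarray
    raw: np.ndarray | None = None  # (n_pairs, 2): distance, r2


def haplotype_spectrum(
    mat: HaplotypeMatrix | np.ndarray, max_missing_fraction: float = 0.10
) -> HaplotypeSpectrum:
    """Haplotype frequency spectrum of a window.

    Haplotypes with a missing fraction above ``max_missing_fraction`` each
    contribute a singleton class of frequency 1/N (the "1/N rule", guarding
    H12 against inflation by heavily-masked inbred lines).  Remaining
    haplotypes group by exact identity over all sites, with residual MISSING
    treated as a distinct allele state.
    """
    hap = mat.haplotypes if isinstance(mat, HaplotypeMatrix) else np.asarray(mat, dtype=np.int8)
    n, m = hap.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if m == 0:
        raise ValueError("empty matrix")
    miss = (hap == MISSING).mean(axis=1)
    bad = miss > max_missing_fraction
    n_bad = int(bad.sum())
    counts = []
    good = np.ascontiguousarray(hap[~bad])
    if good.shape[0]:
        void = good.view([("", good.dtype)] * m).ravel()
        _, class_counts = np.unique(void, return_counts=True)
        counts.extend(class_counts.tolist())
    counts.extend([1] * n_bad)
    freqs = np.sort(np.asarray(counts, dtype=float))[::-1] / n
    singletons = int(sum(1 for c in counts if c == 1))
    return HaplotypeSpectrum(freqs, n, singletons)


def h_stats(spec: HaplotypeSpectrum) -> HStats:
    """H1, H2, H12 and H2/H1 from a haplotype frequency spectrum."""
    p = spec.frequencies
    h1 = float(np.sum(p ** 2))
    h2 = h1 - float(p[0] ** 2)
    if p.size >= 2:
        h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        h12 = h1
    h2_h1 = h2 / h1 if h1 > 0 else 0.0
    return HStats(h1=h1, h2=h2, h12=h12, h2_h1=h2_h1)


def _window_edges(positions: np.ndarray, window_bp: int) -> np.ndarray:
    last = int(positions[-1])
    return np.arange(1, last + window_bp + 1, window_bp)


def diversity(
    mat: HaplotypeMatrix,
    window_bp: int = 10_000,
    bootstrap_reps: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> DiversityEstimate:
    """S/bp and π/bp in non-overlapping windows with bootstrap CIs.

    π uses the unbiased per-site estimator ``2*p*q*n_c/(n_c - 1)`` with the
    site-specific callable count ``n_c``; windows are resampled with
    replacement for percentile confidence intervals.
    """
    rng = rng or np.random.default_rng()
    hap, pos = mat.haplotypes, mat.positions
    called = hap != MISSING
    n_c = called.sum(axis=0)
    ones = ((hap == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_c > 0, ones / np.maximum(n_c, 1), 0.0)
        seg = (ones > 0) & (ones < n_c)
        pi_site = np.where(n_c > 1, 2.0 * p * (1 - p) * n_c / np.maximum(n_c - 1, 1), 0.0)
    edges = _window_edges(pos, window_bp)
    if len(edges) < 2:
        raise ValueError("matrix must span at least one window")
    idx = np.searchsorted(edges, pos, side="right") - 1
    nwin = len(edges) - 1
    s_win = np.bincount(idx, weights=seg.astype(float), minlength=nwin) / window_bp
    pi_win = np.bincount(idx, weights=pi_site, minlength=nwin) / window_bp
    calls_win = np.bincount(idx, weights=(n_c > 0).astype(float), minlength=nwin)
    if (calls_win == 0).any():
        log.info("diversity: %d windows with zero callable sites contribute 0",
                 int((calls_win == 0).sum()))
    s_hat, pi_hat = float(s_win.mean()), float(pi_win.mean())
    boots_s = np.empty(bootstrap_reps)
    boots_pi = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        pick = rng.integers(0, nwin, nwin)
        boots_s[b] = s_win[pick].mean()
        boots_pi[b] = pi_win[pick].mean()
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    return DiversityEstimate(
        s_per_bp=s_hat,
        pi_per_bp=pi_hat,
        s_ci=(float(np.percentile(boots_s, lo)), float(np.percentile(boots_s, hi))),
        pi_ci=(float(np.percentile(boots_pi, lo)), float(np.percentile(boots_pi, hi))),
        n_windows=nwin,
    )


def ld_r2(
    mat: HaplotypeMatrix,
    window_bp: int = 10_000,
    step_bp: int = 50,
    maf_range: tuple[float, float] = (0.05, 0.95),
    min_pairs: int = 4,
) -> LDProfile:
    """Pairwise R² for SNP pairs separated by at most ``window_bp``.

    SNPs must have allele frequency inside ``maf_range`` (computed over
    non-missing calls) and each pair needs at least ``min_pairs`` haplotypes
    called at both sites.  ``step_bp`` is kept for interface parity with
    sliding-window implementations; the pair set — all qualifying pairs within
    one window length — is the same.
    """
    hap, pos = mat.haplotypes, mat.positions
    called = hap != MISSING
    n_c = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_c > 0, ((hap == 1) & called).sum(axis=0) / np.maximum(n_c, 1), 0.0)
    ok = (freq >= maf_range[0]) & (freq <= maf_range[1])
    keep = np.flatnonzero(ok)
    records = []
    for ii, i in enumerate(keep):
        for j in keep[ii + 1:]:
            d = int(pos[j] - pos[i])
            if d > window_bp:
                break
            both = called[:, i] & called[:, j]
            nb = int(both.sum())
            if nb < min_pairs:
                continue
            a = hap[both, i].astype(float)
            b = hap[both, j].astype(float)
            p1, p2 = a.mean(), b.mean()
            denom = p1 * (1 - p1) * p2 * (1 - p2)
            if denom <= 0:
                continue
            d_coef = (a * b).mean() - p1 * p2
            records.append((d, d_coef * d_coef / denom))
    raw = np.asarray(records, dtype=float).reshape(-1, 2)
    return LDProfile(distances=raw[:, 0], r2=raw[:, 1], raw=raw)


def smooth_ld(profile: LDProfile, fine_bp: int = 20, fine_until: int = 300,
              coarse_bp: int = 150) -> LDProfile:
    """Mean R² per distance bin: 20-bp bins up to 300 bp, 150-bp bins after.

    Bins are ``[1,20], (20,40], ..., (280,300], (300,450], ...``; empty bins
    are omitted.  Bin distance reported as the bin midpoint.
    """
    if profile.raw is None or len(profile.raw) == 0:
        return LDProfile(distances=np.empty(0), r2=np.empty(0), raw=profile.raw)
    d = profile.raw[:, 0]
    r2 = profile.raw[:, 1]
    fine = (np.ceil(d / fine_bp) - 1).astype(int)  # bin index for d <= fine_until
    nfine = fine_until // fine_bp
    coarse = nfine + (np.ceil((d - fine_until) / coarse_bp) - 1).astype(int)
    bin_idx = np.where(d <= fine_until, fine, coarse)
    mids, means = [], []
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        if b < nfine:
            lo, hi = b * fine_bp, (b + 1) * fine_bp
        else:
            lo = fine_until + (b - nfine) * coarse_bp
            hi = lo + coarse_bp
        mids.append((lo + hi) / 2.0)
        means.append(float(r2[sel].mean()))
    return LDProfile(distances=np.asarray(mids), r2=np.asarray(means), raw=profile.raw)
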