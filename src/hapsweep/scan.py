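"""Density-calibrated sliding-window H12 scan, FDR thresholding, peak calling.

Analysis windows are defined in SNPs, not base pairs, so that H12 does not
co-vary with local SNP density; the X-chromosome window size is recalibrated
from the ratio of median S/bp values so that X and autosomal windows are
comparable in physical length.  The genome-wide significance threshold is the
10th highest H12 among neutral simulations numbering ten times the count of
independent analysis windows (a 1-per-genome FDR line), and significant
windows are grouped into peaks with a 500-kb exclusion zone and masking of
low-recombination regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, HaplotypeMatrix, RecombinationMap
from .popgen_stats import HaplotypeSpectrum, h_stats

log = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class WindowSpec:
    n_snps: int
    downsample_to: int | None = None
    step_snps: int = 1

    def __post_init__(self) -> None:
        if self.downsample_to is not None and self.downsample_to > self.n_snps:
            raise ValueError("downsample_to must be <= n_snps")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")


@dataclass
class ScanResult:
    """Per-window H12 and H2/H1 series, ordered by window center."""

    centers: np.ndarray  # bp
    starts: np.ndarray
    ends: np.ndarray
    h12: np.ndarray
    h2_h1: np.ndarray
    n_low_quality: np.ndarray  # haplotypes assigned frequency 1/N per window
    chrom_label: str = "chr"

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class Peak:
    apex_pos: int
    apex_h12: float
    apex_h2_h1: float
    start: int
    end: int
    member_index: np.ndarray
    rank: int = 0
    masked: bool = False


@dataclass
class FootprintModel:
    s: float
    ne: float
    rho_cm_per_bp: float


def expected_window_length(n_snps: int, s_per_bp: float) -> int:
    """Expected physical window length (bp) for an ``n_snps`` SNP window.

    At the DGRP autosomal median S/bp of 0.0345, 401-SNP windows span
    11,623 bp; at the X median 0.0227, they would span 17,665 bp.
    """
    if s_per_bp <= 0:
        raise ValueError("SNP density must be > 0")
    return _round_half_up(n_snps / s_per_bp)


def calibrate_x_window(n_snps_auto: int, s_per_bp_auto: float, s_per_bp_x: float) -> int:
    """X window size (SNPs) giving the same physical span as the autosomal one."""
    if s_per_bp_auto <= 0 or s_per_bp_x <= 0:
        raise ValueError("SNP densities must be > 0")
    # two-step: physical autosomal window length first, then X SNP count
    return _round_half_up(s_per_bp_x * expected_window_length(n_snps_auto, s_per_bp_auto))


def window_h_stats(
    hap: np.ndarray, max_missing_fraction: float = 0.10
) -> tuple[float, float, int]:
    """(H12, H2/H1, n haplotypes assigned 1/N) for one window matrix."""
    n, w = hap.shape
    miss = (hap == MISSING).mean(axis=1)
    bad = miss > max_missing_fraction
    n_bad = int(bad.sum())
    counts: list[int] = [1] * n_bad
    good = np.ascontiguousarray(hap[~bad])
    if good.shape[0]:
        void = good.view([("", good.dtype)] * w).ravel()
        _, cc = np.unique(void, return_counts=True)
        counts.extend(cc.tolist())
    freqs = np.sort(np.asarray(counts, float))[::-1] / n
    hs = h_stats(HaplotypeSpectrum(freqs, n))
    return hs.h12, hs.h2_h1, n_bad


def sliding_h12(
    mat: HaplotypeMatrix,
    spec: WindowSpec,
    max_missing_fraction: float = 0.10,
    seed: int | None = None,
) -> ScanResult:
    """Sliding H12 scan over windows of ``spec.n_snps`` consecutive SNPs.

    When ``spec.downsample_to`` is set, each window independently subsamples
    that many SNPs uniformly without replacement (fresh draw per window from
    the seeded stream).  Haplotypes with more than ``max_missing_fraction``
    missing data in a window are assigned a frequency of 1/N.
    """
    if mat.m < spec.n_snps:
        raise ValueError("window spec larger than data")
    rng = np.random.default_rng(seed)
    hap, pos = mat.haplotypes, mat.positions
    starts_idx = np.arange(0, mat.m - spec.n_snps + 1, spec.step_snps)
    centers = np.empty(starts_idx.size, dtype=np.int64)
    starts = np.empty_like(centers)
    ends = np.empty_like(centers)
    h12 = np.empty(starts_idx.size)
    h2h1 = np.empty(starts_idx.size)
    nlow = np.empty(starts_idx.size, dtype=np.int64)
    for k, i in enumerate(starts_idx):
        cols = np.arange(i, i + spec.n_snps)
        if spec.downsample_to is not None and spec.downsample_to < spec.n_snps:
            cols = np.sort(rng.choice(cols, size=spec.downsample_to, replace=False))
        win = hap[:, cols]
        h12[k], h2h1[k], nlow[k] = window_h_stats(win, max_missing_fraction)
        starts[k] = pos[i]
        ends[k] = pos[i + spec.n_snps - 1]
        centers[k] = (starts[k] + ends[k]) // 2
    return ScanResult(centers, starts, ends, h12, h2h1, nlow, mat.chrom_label)


def fdr_threshold(neutral_h12_values, n_independent_windows: int | None = None) -> float:
    """1-per-genome FDR critical value: the 10th highest neutral H12.

    The neutral set should number ten times the independent analysis windows
    in the data; a smaller set is used as given, with a warning.
    """
    vals = np.sort(np.asarray(list(neutral_h12_values), dtype=float))[::-1]
    if vals.size < 10:
        raise ValueError("need at least 10 neutral H12 values")
    if n_independent_windows is not None and vals.size < 10 * n_independent_windows:
        log.warning(
            "fdr_threshold: %d neutral values < 10 x %d independent windows",
            vals.size, n_independent_windows,
        )
    return float(vals[9])


def call_peaks(
    scan: ScanResult,
    threshold: float,
    rmap: RecombinationMap | None = None,
    min_rho: float = 5e-7,
    exclusion_bp: int = 500_000,
    include_masked: bool = False,
) -> list[Peak]:
    """Group significant windows into peaks with exclusion and masking rules.

    Consecutive above-threshold windows form one candidate peak whose value
    and position are those of its highest window (ties: smaller coordinate).
    Candidates are accepted highest-apex-first; a candidate whose apex lies
    within ``exclusion_bp`` of an accepted apex is dropped.  Accepted peaks
    overlapping map intervals with rate < ``min_rho`` cM/bp are flagged
    masked and omitted unless ``include_masked``.
    """
    above = scan.h12 > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    groups = np.split(idx, breaks + 1)
    candidates = []
    for g in groups:
        apex_local = g[np.argmax(scan.h12[g])]  # argmax: first max = smaller coord
        candidates.append(
            Peak(
                apex_pos=int(scan.centers[apex_local]),
                apex_h12=float(scan.h12[apex_local]),
                apex_h2_h1=float(scan.h2_h1[apex_local]),
                start=int(scan.starts[g[0]]),
                end=int(scan.ends[g[-1]]),
                member_index=g,
            )
        )
    candidates.sort(key=lambda p: (-p.apex_h12, p.apex_pos))
    accepted: list[Peak] = []
    for cand in candidates:
        if any(abs(cand.apex_pos - p.apex_pos) < exclusion_bp for p in accepted):
            continue
        cand.rank = len(accepted) + 1
        if rmap is not None:
            cand.masked = rmap.low_recombination_overlap(
                scan.chrom_label, cand.start, cand.end, min_rho
            )
        accepted.append(cand)
    if include_masked:
        return accepted
    return [p for p in accepted if not p.masked]


def footprint_length(model: FootprintModel) -> float:
    """Heuristic sweep footprint L = s / (ln(Ne*s) * rho_Morgans_per_bp).

    ``rho`` is converted from cM/bp to Morgans/bp.  Exposed as a rough guide
    to which selection strengths a window length can capture; requires
    Ne*s > 1 so the log is positive.
    """
    if model.ne * model.s <= 1:
        raise ValueError("footprint model needs Ne*s > 1")
    if model.rho_cm_per_bp <= 0:
        raise ValueError("rho must be > 0")
    rho_m = model.rho_cm_per_bp / 100.0
    return model.s / (math.log(model.ne * model.s) * rho_m)
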