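"""DGRP-like synthetic inputs: neutral regions, embedded sweeps, missingness.

Neutral phased haplotype matrices come from msprime coalescent simulations
with mutation and recombination rates chosen to match target SNP densities
(autosome-like median S/bp ~ 0.0345, X-like ~ 0.0227, X regions at 0.75 Ne).
Sweeps are embedded parametrically: one core haplotype (hard) or k cores
with Dirichlet-distributed frequencies (soft) replace sampled rows around
the sweep position, with light mutational noise.  Missingness mimics the
masked residual-heterozygosity tracts of inbred lines: contiguous missing
tracts per haplotype plus site-level dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .io_formats import AUTOSOME, MISSING, X, HaplotypeMatrix, RecombinationMap

#: Harmonic number H_{n-1}, Watterson's a_n for sample size n.
def watterson_a(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class SweepSpec:
    kind: str = "hard"  # hard | soft
    position: int = 500_000
    pf: float = 1.0  # frequency of the swept haplotype class(es)
    n_origins: int = 10  # soft sweeps only
    span_bp: int = 50_000
    noise_per_hap: float = 1.5  # mean mutations per swept haplotype over the span

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "soft"):
            raise ValueError("sweep kind must be 'hard' or 'soft'")
        if not 0 < self.pf <= 1:
            raise ValueError("PF must be in (0, 1]")


@dataclass
class MissingnessSpec:
    """Per-haplotype contiguous missing tracts + site-level dropout."""

    hap_fraction_range: tuple[float, float] = (0.0, 0.15)
    tract_bp: int = 20_000
    site_drop_fraction: float = 0.0  # fraction of sites hit by heavy dropout
    site_drop_call_loss: float = 0.6  # per-haplotype loss prob at a hit site


@dataclass
class SynthConfig:
    n_haplotypes: int = 100
    region_bp: int = 1_000_000
    s_per_bp: float = 0.0345  # target median SNP density in the sample
    rho_cm_per_bp: float = 5e-7
    chrom_class: str = AUTOSOME
    ne: int = 10_000  # coalescent Ne; densities fix theta, Ne only sets scale
    sweeps: list[SweepSpec] = field(default_factory=list)
    missingness: MissingnessSpec | None = None
    chrom_label: str = "synth"
    seed: int = 0

    @property
    def theta_per_bp(self) -> float:
        """Population-scaled mutation rate implied by the target S/bp."""
        return self.s_per_bp / watterson_a(self.n_haplotypes)


def generate_neutral_region(cfg: SynthConfig) -> HaplotypeMatrix:
    """Neutral coalescent sample at the requested density, n and rho.

    X-class regions use a coalescent size of 0.75 Ne.  The mutation rate is
    derived from ``s_per_bp`` at the realized size, so ``s_per_bp`` is the
    expected sample density for either chromosome class; the X-vs-autosome
    density contrast is expressed by the caller's choice of target (e.g.
    0.0227 vs 0.0345, or a 0.75 theta ratio).
    """
    ne = cfg.ne if cfg.chrom_class == AUTOSOME else int(round(0.75 * cfg.ne))
    mu = cfg.theta_per_bp / (4 * ne)  # per-bp per-generation
    r = cfg.rho_cm_per_bp / 100.0
    if cfg.n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (diploid samples)")
    ts = msprime.sim_ancestry(
        samples=cfg.n_haplotypes // 2,
        population_size=ne,
        sequence_length=cfg.region_bp,
        recombination_rate=r,
        random_seed=(cfg.seed % (2**31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=(cfg.seed % (2**31 - 2)) + 2,
        model=msprime.BinaryMutationModel(),
    )
    gm = ts.genotype_matrix()  # (sites, haplotypes)
    biallelic = gm.max(axis=1) <= 1
    gm = gm[biallelic]
    pos = np.array([s.position for s in ts.sites()])[biallelic]
    ipos = np.floor(pos).astype(np.int64) + 1
    for j in range(1, ipos.size):
        if ipos[j] <= ipos[j - 1]:
            ipos[j] = ipos[j - 1] + 1
    return HaplotypeMatrix(
        gm.T.astype(np.int8), ipos, cfg.chrom_label, cfg.chrom_class,
        [f"s{i}|{k}" for i in range(cfg.n_haplotypes // 2) for k in (1, 2)],
    )


def _distinct_cores(hap: np.ndarray, cols: np.ndarray, k: int,
                    rng: np.random.Generator, min_diff: int = 5) -> np.ndarray:
    """Draw ``k`` core haplotypes over ``cols`` that are pairwise distinct.

    Neutral sample rows can be near-identical through shared ancestry; a
    "soft sweep with k origins" fixture is only truthfully labelled if its k
    cores are distinguishable, so candidate draws are retried (best kept)
    until every pair differs at ``min_diff`` sites or more.
    """
    n = hap.shape[0]
    best, best_score = None, -1
    for _ in range(100):
        rows = rng.choice(n, size=k, replace=False)
        cand = hap[np.ix_(rows, cols)]
        if k == 1:
            return cand.copy()
        dists = [
            int((cand[i] != cand[j]).sum())
            for i in range(k) for j in range(i + 1, k)
        ]
        score = min(dists)
        if score > best_score:
            best, best_score = cand.copy(), score
        if score >= min_diff:
            break
    return best


def embed_sweep(mat: HaplotypeMatrix, sweep: SweepSpec,
                rng: np.random.Generator | None = None) -> HaplotypeMatrix:
    """Overwrite the region around ``sweep.position`` with sweep structure.

    ``round(pf * n)`` rows become sweeping haplotypes: all copies of one core
    row (hard), or of ``n_origins`` cores with Dirichlet(1,...,1) relative
    frequencies (soft).  Each swept row then receives Poisson mutational
    noise over the span.
    """
    rng = rng or np.random.default_rng()
    n = mat.n
    n_swept = int(round(sweep.pf * n))
    if n_swept < 1:
        raise ValueError("PF * n < 1: no haplotypes would sweep")
    hap = mat.haplotypes.copy()
    lo = sweep.position - sweep.span_bp // 2
    hi = sweep.position + sweep.span_bp // 2
    cols = np.flatnonzero((mat.positions >= lo) & (mat.positions <= hi))
    if cols.size == 0:
        raise ValueError("sweep span contains no sites")
    swept_rows = rng.choice(n, size=n_swept, replace=False)
    if sweep.kind == "hard":
        assignment = np.zeros(n_swept, dtype=int)
        k = 1
    else:
        k = sweep.n_origins
        weights = rng.dirichlet(np.ones(k))
        assignment = rng.choice(k, size=n_swept, p=weights)
    cores = _distinct_cores(hap, cols, k, rng)
    for i, row in enumerate(swept_rows):
        hap[row, cols] = cores[assignment[i]]
        n_noise = rng.poisson(sweep.noise_per_hap)
        if n_noise:
            j = rng.integers(0, cols.size, size=n_noise)
            hap[row, cols[j]] = 1 - np.maximum(hap[row, cols[j]], 0)
    out = HaplotypeMatrix(
        hap, mat.positions.copy(), mat.chrom_label, mat.chrom_class,
        list(mat.sample_ids),
    )
    return out


def apply_missingness(mat: HaplotypeMatrix, spec: MissingnessSpec,
                      rng: np.random.Generator | None = None) -> HaplotypeMatrix:
    """Contiguous per-haplotype missing tracts, then site-level dropout.

    Each haplotype draws a target missing fraction uniformly from
    ``hap_fraction_range`` and accumulates random ``tract_bp`` tracts until
    it is met — mimicking masked residual-heterozygosity tracts.  Then a
    fraction of sites lose each call independently with probability
    ``site_drop_call_loss``.
    """
    rng = rng or np.random.default_rng()
    hap = mat.haplotypes.copy()
    pos = mat.positions
    span = int(pos[-1] - pos[0] + 1)
    lo_f, hi_f = spec.hap_fraction_range
    for i in range(mat.n):
        target = rng.uniform(lo_f, hi_f)
        if target <= 0:
            continue
        missing = np.zeros(mat.m, dtype=bool)
        guard = 0
        while missing.mean() < target and guard < 1000:
            start = rng.integers(pos[0], pos[-1] + 1)
            tract = (pos >= start) & (pos < start + spec.tract_bp)
            missing |= tract
            guard += 1
            if spec.tract_bp >= span:
                break
        hap[i, missing] = MISSING
    if spec.site_drop_fraction > 0:
        hit = rng.random(mat.m) < spec.site_drop_fraction
        for j in np.flatnonzero(hit):
            lost = rng.random(mat.n) < spec.site_drop_call_loss
            hap[lost, j] = MISSING
    keep = np.flatnonzero((hap != MISSING).any(axis=0))
    return HaplotypeMatrix(
        hap[:, keep], pos[keep], mat.chrom_label, mat.chrom_class,
        list(mat.sample_ids),
    )


def make_recombination_map(
    region_bp: int,
    baseline_rate: float = 5e-7,
    low_rho_intervals: list[tuple[int, int, float]] | None = None,
    chrom_label: str = "synth",
) -> RecombinationMap:
    """Piecewise-constant map with optional low-recombination cold spots.

    ``low_rho_intervals`` is a list of ``(start, end, rate)`` half-open
    intervals inside ``[0, region_bp)``; the rest of the region stays at
    ``baseline_rate``.
    """
    cold = sorted(low_rho_intervals or [])
    rows = []
    cursor = 0
    for start, end, rate in cold:
        if start < cursor or end > region_bp:
            raise ValueError("cold spots must be non-overlapping and inside the region")
        if start > cursor:
            rows.append((chrom_label, cursor, start, baseline_rate))
        rows.append((chrom_label, start, end, rate))
        cursor = end
    if cursor < region_bp:
        rows.append((chrom_label, cursor, region_bp, baseline_rate))
    import pandas as pd

    return RecombinationMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"]))
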