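"""Approximate Bayesian computation for hard/soft sweep classification.

Hard sweeps are trained at a low population-scaled adaptive mutation rate
(theta_A = 0.01) and soft sweeps at a high one (theta_A = 10); each training
replicate draws the nuisance parameters — selection coefficient s, time since
selection ceased T_E, final sweep frequency PF and dominance h — from uniform
priors, simulates the selected-locus dynamics forward, and summarizes the
resulting sample window by its (H12, H2/H1) pair.  The Bayes factor at an
observed point is the ratio of soft to hard training points within Euclidean
distance < 0.1; BF <= 1 calls a hard sweep, BF > 1 soft, and BF >= 30 strong
evidence for a soft sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernel
from .io_formats import AUTOSOME, X
from .scan import Peak, window_h_stats
from .synthetic_data import SynthConfig, generate_neutral_region, watterson_a
from .wf_sim import SelectedLocusSim, SimParams

log = logging.getLogger(__name__)

THETA_HARD = 0.01
THETA_SOFT = 10.0


@dataclass
class ABCPriors:
    """Uniform nuisance priors for the training simulations."""

    s_range: tuple[float, float] = (0.0, 1.0)
    t_e_scale: float = 1e-3  # T_E ~ U[0, t_e_scale] * 4 Ne generations
    pf_range: tuple[float, float] = (0.0, 1.0)
    h_range: tuple[float, float] = (0.0, 1.0)
    theta_hard: float = THETA_HARD
    theta_soft: float = THETA_SOFT


@dataclass
class TrainingConfig:
    """Desk-scale forward-training model shared by both sweep classes.

    ``ne`` is the rescaled diploid size of the forward engine.  ``x_mode``
    selects the X convention: ``"scaled"`` (0.75 Ne, no hemizygosity — the
    coalescent convention) or ``"hemizygous"`` (explicit X transmission).
    """

    ne: int = 1000
    chrom_class: str = AUTOSOME
    x_mode: str = "hemizygous"
    window_snps: int = 265
    s_per_bp: float = 0.0345
    rho_cm_per_bp: float = 5e-7
    sample_k: int = 100
    max_gens_factor: int = 400
    #: Population size of the constant-Ne model whose mutational clock sets
    #: within-sweep noise.  The forward dynamics run at the rescaled ``ne``,
    #: but new-mutation accumulation on sweeping haplotypes is charged at the
    #: nominal per-generation rate theta/(4*noise_ne): at the study scale a
    #: sweep is far too brief for appreciable within-sweep mutation, and a
    #: desk-scale clock would grossly inflate it.
    noise_ne: float = 2.7e6

    def engine_params(self, theta_a: float, s: float, h: float) -> SimParams:
        if self.chrom_class == X and self.x_mode == "scaled":
            return SimParams(
                ne=int(round(0.75 * self.ne)), chrom_class=AUTOSOME,
                theta_adaptive=theta_a, s=s, h=h,
                rho_cm_per_bp=self.rho_cm_per_bp,
            )
        return SimParams(
            ne=self.ne, chrom_class=self.chrom_class,
            theta_adaptive=theta_a, s=s, h=h,
            rho_cm_per_bp=self.rho_cm_per_bp,
        )


@dataclass
class BFGrid:
    """Bayes-factor surface over the (H12, H2/H1) unit square.

    The grid nodes exist for visualization and caching; classification
    re-counts neighbors at the observed point with the same radius and
    training points, removing grid-step sensitivity.
    """

    hard_points: np.ndarray  # (n, 2)
    soft_points: np.ndarray
    radius: float = 0.1
    grid_step: float = 0.025
    nodes: np.ndarray = field(init=False)
    count_hard: np.ndarray = field(init=False)
    count_soft: np.ndarray = field(init=False)
    bf: np.ndarray = field(init=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hard_points = np.asarray(self.hard_points, float).reshape(-1, 2)
        self.soft_points = np.asarray(self.soft_points, float).reshape(-1, 2)
        if not len(self.hard_points) or not len(self.soft_points):
            raise ValueError("both training point sets must be non-empty")
        self._tree_hard = cKDTree(self.hard_points)
        self._tree_soft = cKDTree(self.soft_points)
        ax = np.arange(0.0, 1.0 + 1e-9, self.grid_step)
        gx, gy = np.meshgrid(ax, ax, indexing="ij")
        self.nodes = np.column_stack([gx.ravel(), gy.ravel()])
        self.count_hard, self.count_soft = self._counts(self.nodes)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.bf = self.count_soft / self.count_hard
        self.bf[(self.count_hard == 0) & (self.count_soft > 0)] = np.inf
        self.bf[(self.count_hard == 0) & (self.count_soft == 0)] = np.nan

    def _counts(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Strict-radius neighbor counts (Euclidean distance < radius)."""
        pts = np.asarray(pts, float).reshape(-1, 2)
        ch = np.empty(len(pts), dtype=float)
        cs = np.empty(len(pts), dtype=float)
        for i, p in enumerate(pts):
            ih = self._tree_hard.query_ball_point(p, self.radius)
            is_ = self._tree_soft.query_ball_point(p, self.radius)
            ch[i] = sum(
                1 for j in ih if np.linalg.norm(self.hard_points[j] - p) < self.radius
            )
            cs[i] = sum(
                1 for j in is_ if np.linalg.norm(self.soft_points[j] - p) < self.radius
            )
        return ch, cs

    def bayes_factor(self, h12: float, h2_h1: float) -> float:
        """BF at the observed point (NaN when no training neighbors)."""
        ch, cs = self._counts([[h12, h2_h1]])
        if ch[0] == 0 and cs[0] == 0:
            return float("nan")
        if ch[0] == 0:
            return float("inf")
        return float(cs[0] / ch[0])


@dataclass
class SweepCall:
    peak: Peak | None
    h12: float
    h2_h1: float
    bf: float
    label: str  # hard | soft | soft_strong | unclassified


def label_from_bf(bf: float, strong: float = 30.0) -> str:
    if np.isnan(bf):
        return "unclassified"
    if bf <= 1.0:
        return "hard"
    return "soft_strong" if bf >= strong else "soft"


# ---------------------------------------------------------------------------
# Training simulations
# ---------------------------------------------------------------------------

def _training_point(
    cfg: TrainingConfig, priors: ABCPriors, theta_a: float,
    seed: int, background: np.ndarray, mu_per_site: float,
) -> tuple[float, float] | None:
    """One (H12, H2/H1) training replicate; None if the sweep never starts."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(*priors.s_range)
    h = rng.uniform(*priors.h_range)
    pf = rng.uniform(*priors.pf_range)
    t_e = rng.uniform(0, priors.t_e_scale) * 4 * cfg.ne
    params = cfg.engine_params(theta_a, max(s, 1e-3), h)
    sim = SelectedLocusSim(params, seed=seed)
    status = sim.run_phase(
        max_gens=cfg.max_gens_factor * params.ne,
        stop_on_fix=True, stop_freq=max(pf, 1.0 / params.ne),
    )
    if status == _kernel.STATUS_CAP and sim.n_carr == 0:
        return None
    if t_e >= 1:
        sim.run_phase(max_gens=int(t_e), s=0.0, mu=0.0)
    labels = sim.sample_origins(cfg.sample_k)
    window = _assemble_window(labels, sim, background, mu_per_site, rng)
    h12, h2h1, _ = window_h_stats(window)
    return h12, h2h1


def _assemble_window(
    labels: np.ndarray, sim: SelectedLocusSim, background: np.ndarray,
    mu_per_site: float, rng: np.random.Generator,
) -> np.ndarray:
    """Sample window from origin labels plus a neutral background matrix.

    Copies sharing a mutational origin inherit that origin's background row
    (their common ancestor haplotype); each then accumulates Poisson
    mutational noise proportional to the origin's age, at the neutral
    per-site rate.  Non-sweeping copies keep their own background rows.
    """
    k, w = background.shape
    window = background.copy()
    now = sim.gen
    for origin in np.unique(labels[labels > 0]):
        rows = np.flatnonzero(labels == origin)
        core = background[rows[0]].copy()
        age = max(now - int(sim.origin_gen[origin]), 0)
        lam = mu_per_site * w * age
        for r in rows:
            window[r] = core
            n_noise = rng.poisson(lam)
            if n_noise:
                j = rng.integers(0, w, size=n_noise)
                window[r, j] = 1 - window[r, j]
    return window


def simulate_training(
    cfg: TrainingConfig, priors: ABCPriors, sweep_class: str,
    n_sims: int, seed: int = 0,
) -> np.ndarray:
    """(H12, H2/H1) training points for one sweep class.

    ``sweep_class`` is ``"hard"`` (theta_A = 0.01) or ``"soft"``
    (theta_A = 10).  Neutral window backgrounds come from msprime at the
    configured SNP density; the selected-locus dynamics come from the sparse
    forward engine at the desk-scale rescaled Ne.
    """
    if sweep_class not in ("hard", "soft"):
        raise ValueError("sweep_class must be 'hard' or 'soft'")
    if n_sims < 100:
        log.warning("simulate_training: n_sims=%d < 100, grid will be unstable", n_sims)
    theta_a = priors.theta_hard if sweep_class == "hard" else priors.theta_soft
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 3)) + 1 for s in ss.spawn(2 * n_sims)]
    window_bp = int(cfg.window_snps / cfg.s_per_bp * 1.5)
    # per-SNP-column neutral rate: (theta_bp/4Ne) * (1/s_per_bp) = 1/(a_n * 4Ne)
    mu_per_site = 1.0 / (watterson_a(cfg.sample_k) * 4 * cfg.noise_ne)
    points = []
    si = 0
    while len(points) < n_sims and si < len(seeds):
        sd = seeds[si]
        si += 1
        bg_cfg = SynthConfig(
            n_haplotypes=cfg.sample_k, region_bp=window_bp,
            s_per_bp=cfg.s_per_bp, rho_cm_per_bp=cfg.rho_cm_per_bp,
            chrom_class=AUTOSOME, ne=cfg.ne, seed=sd,
        )
        bg = generate_neutral_region(bg_cfg).haplotypes
        if bg.shape[1] < cfg.window_snps:
            continue
        lo = (bg.shape[1] - cfg.window_snps) // 2
        bg = np.ascontiguousarray(bg[:, lo: lo + cfg.window_snps])
        pt = _training_point(cfg, priors, theta_a, sd, bg, mu_per_site)
        if pt is not None:
            points.append(pt)
    return np.asarray(points, dtype=float).reshape(-1, 2)


def build_bf_grid(
    hard_pts: np.ndarray, soft_pts: np.ndarray,
    radius: float = 0.1, grid_step: float = 0.025, meta: dict | None = None,
) -> BFGrid:
    """Bayes-factor grid from hard- and soft-sweep training points."""
    return BFGrid(hard_pts, soft_pts, radius=radius, grid_step=grid_step,
                  meta=meta or {})


def classify_point(grid: BFGrid, h12: float, h2_h1: float) -> SweepCall:
    bf = grid.bayes_factor(h12, h2_h1)
    return SweepCall(peak=None, h12=h12, h2_h1=h2_h1, bf=bf, label=label_from_bf(bf))


def classify_peaks(peaks: list[Peak], grid: BFGrid) -> list[SweepCall]:
    """Evaluate each peak's (H12, H2/H1) against the training neighborhoods.

    Counts are recomputed at the observed point — not the nearest node —
    with the grid's radius.  Peaks with no training neighbors come back
    ``unclassified``.
    """
    calls = []
    for pk in peaks:
        bf = grid.bayes_factor(pk.apex_h12, pk.apex_h2_h1)
        if np.isnan(bf):
            log.warning("peak at %d has no training neighbors", pk.apex_pos)
        calls.append(SweepCall(
            peak=pk, h12=pk.apex_h12, h2_h1=pk.apex_h2_h1,
            bf=bf, label=label_from_bf(bf),
        ))
    return calls
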