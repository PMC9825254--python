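"""Replicated sweep-simulation designs and hard/soft outcome classification.

Four experiment families, mirroring the classic X-vs-autosome contrasts:

* recurrent beneficial mutations (multiple-origin sweeps),
* adaptation from standing variation with a single origin,
* dominance shifts (deleterious and recessive before an environmental change,
  beneficial and dominant after),
* sexually antagonistic selection.

A sweep is *soft* when the sampled copies at fixation carry two or more
distinct mutational origins, *hard* when exactly one.  For single-origin
standing-variation sweeps the proxy for softness is the number of distinct
haplotypes bearing the adaptive allele in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .wf_sim import Population, SelectedLocusSim, SimParams

HARD = "hard"
SOFT = "soft"
LOST = "lost"
NO_SGV = "no_sgv"
NOT_FIXED = "not_fixed"
FIXED_UNCLASSIFIED = "fixed_unclassified"

CATEGORIES = (HARD, SOFT, LOST, NO_SGV, NOT_FIXED, FIXED_UNCLASSIFIED)


@dataclass
class SweepOutcome:
    category: str
    n_origins: int = 0
    n_distinct_haplotypes: int = 0
    fixation_generation: int | None = None
    origins_from_sgv_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class ShiftParams:
    """Two-regime selection: (s_d, h_d) before, (s_b, h_b) after the shift."""

    s_d: float = -0.05
    h_d: float = 0.0
    s_b: float = 0.05
    h_b: float = 1.0
    theta_del: float = 0.4
    pf: float = 0.001
    recurrent_after_shift: bool = False
    k: float = 0.1  # deleterious scalar for sexual antagonism

    def __post_init__(self) -> None:
        if self.s_d > 0 or self.s_b < 0:
            raise ValueError("need s_d <= 0 <= s_b")


def _classify(n_origins: int) -> str:
    return HARD if n_origins == 1 else SOFT


def run_recurrent_sweep(
    params: SimParams, sample_k: int = 100, seed: int = 0,
    max_gens: int | None = None,
) -> SweepOutcome:
    """Recurrent beneficial mutations at theta_A until fixation; count origins."""
    if params.s <= 0:
        raise ValueError("recurrent sweep needs s > 0")
    cap = max_gens if max_gens is not None else 100 * params.ne
    sim = SelectedLocusSim(params, seed=seed)
    status = sim.run_phase(max_gens=cap, stop_on_fix=True)
    if status != _kernel.STATUS_FIXED:
        return SweepOutcome(NOT_FIXED, seed=seed)
    origins = sim.sample_origins(sample_k)
    n = len(set(origins[origins > 0]))
    return SweepOutcome(_classify(n), n_origins=n, fixation_generation=sim.gen, seed=seed)


def run_dominance_shift(
    params: SimParams, shift: ShiftParams, sample_k: int = 100, seed: int = 0,
    burn_gens: int | None = None, max_gens: int | None = None,
) -> SweepOutcome:
    """Multiple-origin adaptation from standing variation after a shift.

    Recurrent mutations at ``theta_del`` with (s_d, h_d) for 10*Ne
    generations; then selection becomes (s_b, h_b) and — unless
    ``recurrent_after_shift`` — mutation stops.  Outcomes: ``no_sgv`` (no
    copies at the shift), ``lost``, or hard/soft by sampled origins.
    """
    burn = burn_gens if burn_gens is not None else 10 * params.ne
    cap = max_gens if max_gens is not None else 100 * params.ne
    mu_del = shift.theta_del / (4 * params.ne)
    sim = SelectedLocusSim(params, seed=seed)
    sim.run_phase(max_gens=burn, s=shift.s_d, h=shift.h_d, mu=mu_del)
    if sim.n_carr == 0:
        return SweepOutcome(NO_SGV, seed=seed)
    shift_marker = sim.next_origin
    mu_after = mu_del if shift.recurrent_after_shift else 0.0
    status = sim.run_phase(
        max_gens=cap, s=shift.s_b, h=shift.h_b, mu=mu_after,
        stop_on_fix=True, stop_on_loss=not shift.recurrent_after_shift,
    )
    if status == _kernel.STATUS_LOST:
        return SweepOutcome(LOST, seed=seed)
    if status != _kernel.STATUS_FIXED:
        return SweepOutcome(NOT_FIXED, seed=seed)
    origins = sim.sample_origins(sample_k)
    distinct = set(origins[origins > 0])
    n = len(distinct)
    sgv_frac = None
    if shift.recurrent_after_shift and n:
        sgv_frac = sum(1 for o in distinct if o < shift_marker) / n
    return SweepOutcome(
        _classify(n), n_origins=n, fixation_generation=sim.gen,
        origins_from_sgv_fraction=sgv_frac, seed=seed,
    )


def run_sexual_antagonism(
    params: SimParams, shift: ShiftParams, advantaged_sex: str,
    sample_k: int = 100, seed: int = 0, max_gens: int | None = None,
) -> SweepOutcome:
    """Sex-dependent selection: beneficial s_b in one sex, -k*s_b in the other.

    Recurrent mutations at theta_A; hemizygous X males experience the
    homozygous effect of the male coefficient.  Non-fixing runs (generation
    cap) are reported as ``not_fixed``.
    """
    if advantaged_sex not in ("male", "female"):
        raise ValueError("advantaged_sex must be 'male' or 'female'")
    cap = max_gens if max_gens is not None else 200 * params.ne
    s_b = shift.s_b
    s_d = -shift.k * s_b
    s_f, s_m = (s_b, s_d) if advantaged_sex == "female" else (s_d, s_b)
    sim = SelectedLocusSim(params, seed=seed)
    status = sim.run_phase(
        max_gens=cap, h=params.h, s_female=s_f, s_male=s_m,
        mu=params.mu_adaptive, stop_on_fix=True,
    )
    if status != _kernel.STATUS_FIXED:
        return SweepOutcome(NOT_FIXED, seed=seed)
    origins = sim.sample_origins(sample_k)
    n = len(set(origins[origins > 0]))
    return SweepOutcome(_classify(n), n_origins=n, fixation_generation=sim.gen, seed=seed)


def run_sgv_single_origin(
    params: SimParams, shift: ShiftParams, sample_k: int = 100, seed: int = 0,
    neutral_burn_gens: int | None = None, restart_cap: int = 1_000_000,
    fixation_attempts: int = 200,
) -> SweepOutcome:
    """Single-origin sweep from standing variation (full engine).

    After a neutral burn-in, one deleterious mutation (s_d, h_d) is
    introduced at the locus center and re-introduced on loss until it reaches
    the conditioning frequency PF; selection then switches to (s_b, h_b) and
    runs to fixation or loss (loss restarts the conditioning, up to
    ``fixation_attempts``).  On fixation, reports the number of distinct
    haplotypes bearing the adaptive allele in a sample — the softness proxy
    for single-origin sweeps.
    """
    if not 0 < shift.pf < 1:
        raise ValueError("PF must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pop = Population(params, rng=rng)
    burn = neutral_burn_gens if neutral_burn_gens is not None else 10 * params.ne
    for _ in range(burn):
        pop.step(s=0.0, mu_adaptive=0.0)
    for _attempt in range(fixation_attempts):
        # conditioning phase: reach PF under (s_d, h_d)
        restarts = 0
        pop.introduce_single_copy()
        while True:
            pop.step(s=shift.s_d, h=shift.h_d, mu_adaptive=0.0)
            if pop.frequency() >= shift.pf and pop.mutant_copies() >= 1:
                break
            if pop.mutant_copies() == 0:
                restarts += 1
                if restarts > restart_cap:
                    raise RuntimeError("restart cap exceeded before reaching PF")
                pop.introduce_single_copy()
        # beneficial phase
        lost = False
        while True:
            pop.step(s=shift.s_b, h=shift.h_b, mu_adaptive=0.0)
            if pop.mutant_copies() == 0:
                lost = True
                break
            if pop.frequency() >= 1.0:
                break
        if not lost:
            mat, sel = pop.sample_haplotypes(sample_k)
            carriers = mat.haplotypes[sel > 0]
            if carriers.shape[0] == 0:
                return SweepOutcome(FIXED_UNCLASSIFIED, seed=seed)
            void = np.ascontiguousarray(carriers).view(
                [("", carriers.dtype)] * carriers.shape[1]
            ).ravel()
            n_hap = len(np.unique(void))
            return SweepOutcome(
                HARD if n_hap == 1 else SOFT,
                n_origins=1, n_distinct_haplotypes=int(n_hap),
                fixation_generation=pop.gen, seed=seed,
            )
    return SweepOutcome(LOST, seed=seed)


# ---------------------------------------------------------------------------
# Batch helpers and summaries
# ---------------------------------------------------------------------------

def run_batch(runner, n_reps: int, seed: int, **kwargs) -> list[SweepOutcome]:
    """Run ``runner`` for ``n_reps`` independent replicate seeds."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]
    return [runner(seed=s, **kwargs) for s in seeds]


def _wilson_ci(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def summarize(outcomes: list[SweepOutcome], label: str = "") -> pd.DataFrame:
    """Aggregate replicate outcomes: mean origins and category proportions.

    Proportions sum to 1 over the exhaustive category labels; binomial 95%
    Wilson intervals accompany each proportion.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    n = len(outcomes)
    fixed = [o for o in outcomes if o.category in (HARD, SOFT)]
    rows = []
    for cat in CATEGORIES:
        k = sum(1 for o in outcomes if o.category == cat)
        lo, hi = _wilson_ci(k, n)
        rows.append({
            "label": label, "category": cat, "count": k, "proportion": k / n,
            "ci_low": lo, "ci_high": hi,
        })
    df = pd.DataFrame(rows)
    df.attrs["n"] = n
    df.attrs["mean_origins"] = float(np.mean([o.n_origins for o in fixed])) if fixed else float("nan")
    df.attrs["mean_distinct_haplotypes"] = (
        float(np.mean([o.n_distinct_haplotypes for o in fixed])) if fixed else float("nan")
    )
    assert abs(df["proportion"].sum() - 1.0) < 1e-9
    return df


@dataclass
class ExperimentResult:
    """Outcome list plus its summary for one parameter combination."""

    label: str
    outcomes: list[SweepOutcome]
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.summary = summarize(self.outcomes, self.label)

    @property
    def mean_origins(self) -> float:
        return self.summary.attrs["mean_origins"]

    def proportion(self, category: str) -> float:
        row = self.summary[self.summary["category"] == category]
        return float(row["proportion"].iloc[0])

    def origins_array(self) -> np.ndarray:
        return np.asarray(
            [o.n_origins for o in self.outcomes if o.category in (HARD, SOFT)]
        )


def adjusted_x_ne(ne_auto: int) -> int:
    """Individuals needed so that the X effective size equals the autosomal one.

    With an equal sex ratio Ne_X = 0.75 N; raising N to 4/3 Ne_auto restores
    Ne_X = Ne_auto (and, at fixed mu, theta_AX = theta_Aauto).
    """
    return int(round(ne_auto * 4 / 3))
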