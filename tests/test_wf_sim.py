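"""Engine correctness: rescaling algebra, transmission genetics, neutral
equilibrium and agreement between the sparse and full engines."""

import numpy as np
import pytest
from scipy import stats

from hapsweep import _kernel
from hapsweep.synthetic_data import watterson_a
from hapsweep.wf_sim import (
    Population,
    SelectedLocusSim,
    SimParams,
    rescale,
    x_autosome_theta_ratio,
)


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------

def test_rescale_q50_scales_all_rates():
    p = SimParams(ne=1_000_000, theta_adaptive=0.4, theta_neutral=40.0,
                  s=0.0001, rho_cm_per_bp=5e-7, q=50)
    r = rescale(p)
    assert r.ne == 20_000
    assert r.s == pytest.approx(0.005)
    assert r.rho_cm_per_bp == pytest.approx(5e-7 * 50)
    # per-copy mutation rate scaled up by Q
    assert r.mu_adaptive == pytest.approx(p.mu_adaptive * 50)


def test_rescale_identity_and_invariants():
    p = SimParams(ne=10_000, theta_adaptive=0.4, s=0.01, q=1)
    assert rescale(p) is p
    p2 = SimParams(ne=10_000, theta_adaptive=0.4, theta_neutral=7.0, s=0.002, q=10)
    r = rescale(p2)
    assert r.theta_adaptive == pytest.approx(p2.theta_adaptive, abs=1e-12)
    assert r.theta_neutral == pytest.approx(p2.theta_neutral, abs=1e-12)
    assert r.ne * r.s == pytest.approx(p2.ne * p2.s, rel=1e-12)


def test_rescale_warns_on_strong_selection():
    p = SimParams(ne=100_000, s=0.005, q=50)
    with pytest.warns(UserWarning, match="0.1"):
        rescale(p)


def test_theta_ratio_from_copy_counting():
    assert x_autosome_theta_ratio() == pytest.approx(0.75)
    assert x_autosome_theta_ratio(7, 1) == pytest.approx(15 / 16)


# ---------------------------------------------------------------------------
# Full engine basics
# ---------------------------------------------------------------------------

def test_copy_number_conservation():
    for chrom in ("autosome", "X"):
        p = SimParams(ne=60, chrom_class=chrom, theta_neutral=5.0)
        pop = Population(p, rng=np.random.default_rng(1))
        for _ in range(20):
            pop.step(s=0.0, mu_adaptive=0.0)
            n_f = int(pop.sex.sum())
            expected = 2 * n_f + (60 - n_f) if chrom == "X" else 120
            assert pop.total_copies() == expected
            assert len(pop.valid_copy_rows()) == expected


def test_seeded_determinism_full_engine():
    outs = []
    for _ in range(2):
        p = SimParams(ne=40, theta_neutral=5.0, s=0.0)
        pop = Population(p, rng=np.random.default_rng(42))
        for _ in range(50):
            pop.step()
        mat, _ = pop.sample_haplotypes(10, rng=np.random.default_rng(7))
        outs.append((mat.haplotypes.copy(), mat.positions.copy()))
    np.testing.assert_array_equal(outs[0][0], outs[1][0])
    np.testing.assert_array_equal(outs[0][1], outs[1][1])


def test_fixed_allele_stays_fixed_without_mutation():
    p = SimParams(ne=30, theta_neutral=0.0, s=0.05)
    pop = Population(p, rng=np.random.default_rng(3))
    for i in range(pop.n):  # fix the allele by hand
        pop.sel[i, 0] = 1
        if pop.sel[i, 1] != -1:
            pop.sel[i, 1] = 1
    for _ in range(30):
        pop.step(mu_adaptive=0.0)
        assert pop.frequency() == 1.0


def test_dosage_compensation_fitness_scheme():
    """Hemizygous carrier males get the homozygous-female fitness 1+s."""
    p = SimParams(ne=40, chrom_class="X", s=0.3, h=0.1)
    pop = Population(p, rng=np.random.default_rng(0))
    males = np.flatnonzero(~pop.sex)
    females = np.flatnonzero(pop.sex)
    pop.sel[males[0], 0] = 1  # hemizygous carrier
    pop.sel[females[0], 0] = 1  # het female
    pop.sel[females[1], :] = 1  # hom female
    w = pop._fitness(p.s, p.h)
    assert w[males[0]] == pytest.approx(1 + p.s)
    assert w[females[0]] == pytest.approx(1 + p.h * p.s)
    assert w[females[1]] == pytest.approx(1 + p.s)


def test_sample_haplotypes_census_and_monomorphic():
    p = SimParams(ne=20, theta_neutral=0.0)
    pop = Population(p, rng=np.random.default_rng(5))
    mat, sel = pop.sample_haplotypes(pop.total_copies())
    assert mat.n == pop.total_copies()
    assert (sel == 0).all()
    with pytest.raises(ValueError):
        pop.sample_haplotypes(pop.total_copies() + 1)


# ---------------------------------------------------------------------------
# Sparse kernel vs theory and vs the full engine
# ---------------------------------------------------------------------------

def test_fixation_probability_matches_branching_oracle():
    """P(fix) of one new mutant ~ 2hs (Haldane) within 3 binomial SEs."""
    n, fixed = 3000, 0
    p = SimParams(ne=1000, s=0.05, h=0.5)
    for i in range(n):
        sim = SelectedLocusSim(p, seed=40_000 + i)
        sim.introduce_single_copy()
        st = sim.run_phase(max_gens=10**7, mu=0.0, stop_on_fix=True, stop_on_loss=True)
        fixed += st == _kernel.STATUS_FIXED
    phat = fixed / n
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(phat - 2 * p.h * p.s) < 3 * se


def test_sparse_and_full_engines_agree_on_fixation_probability():
    """Dual-route check: same law for the selected locus in both engines."""
    ne, s, h, n = 120, 0.2, 0.5, 400
    fixed_sparse = 0
    for i in range(n):
        sim = SelectedLocusSim(SimParams(ne=ne, s=s, h=h), seed=9_000 + i)
        sim.introduce_single_copy()
        st = sim.run_phase(max_gens=10**6, mu=0.0, stop_on_fix=True, stop_on_loss=True)
        fixed_sparse += st == _kernel.STATUS_FIXED
    fixed_full = 0
    for i in range(n):
        pop = Population(SimParams(ne=ne, theta_neutral=0.0, s=s, h=h),
                         rng=np.random.default_rng(20_000 + i))
        pop.introduce_single_copy()
        while 0 < pop.frequency() < 1:
            pop.step(mu_adaptive=0.0)
        fixed_full += pop.frequency() == 1.0
    p1, p2 = fixed_sparse / n, fixed_full / n
    pooled = (fixed_sparse + fixed_full) / (2 * n)
    se = np.sqrt(2 * pooled * (1 - pooled) / n)
    assert abs(p1 - p2) < 3 * se


def test_x_sweeps_faster_when_recessive():
    """Hemizygous exposure: recessive sweeps finish faster on the X."""
    from hapsweep.sweep_experiments import HARD, SOFT, run_batch, run_recurrent_sweep

    def times(chrom):
        p = SimParams(ne=500, chrom_class=chrom, theta_adaptive=0.4, s=0.1, h=0.0)
        outs = run_batch(run_recurrent_sweep, 500, 31 + (chrom == "X"), params=p)
        return np.array([o.fixation_generation for o in outs
                         if o.category in (HARD, SOFT)])

    tx, ta = times("X"), times("autosome")
    assert stats.mannwhitneyu(tx, ta, alternative="less").pvalue < 0.01


def test_neutral_runs_invariant_under_rescaling():
    """S in samples agrees between Q=10 and Q=50 rescalings of one model."""
    base = SimParams(ne=2000, theta_neutral=8.0, rho_cm_per_bp=5e-7)

    def mean_s(q, seed0):
        p = rescale(SimParams(ne=base.ne, theta_neutral=base.theta_neutral,
                              rho_cm_per_bp=base.rho_cm_per_bp, q=q))
        vals = []
        for rep in range(12):
            pop = Population(p, rng=np.random.default_rng(seed0 + rep))
            for _ in range(12 * p.ne):
                pop.step(s=0.0, mu_adaptive=0.0)
            mat, _ = pop.sample_haplotypes(16)
            seg = ((mat.haplotypes == 1).any(0)) & ((mat.haplotypes == 0).any(0))
            vals.append(int(seg.sum()))
        return np.asarray(vals, dtype=float)

    s10, s50 = mean_s(10, 100), mean_s(50, 200)
    se = np.sqrt(s10.var(ddof=1) / len(s10) + s50.var(ddof=1) / len(s50))
    assert abs(s10.mean() - s50.mean()) < 3 * se
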