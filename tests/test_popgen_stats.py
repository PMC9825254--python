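"""Spectrum construction, H statistics, diversity and LD against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapsweep.io_formats import MISSING, HaplotypeMatrix
from hapsweep.popgen_stats import (
    HaplotypeSpectrum,
    diversity,
    h_stats,
    haplotype_spectrum,
    ld_r2,
    smooth_ld,
)


def brute_force_h(counts):
    """Pair-matching oracle: homozygosity = probability two draws (with
    replacement) fall in the same class, enumerated over all ordered pairs."""
    counts = list(counts)
    n = sum(counts)
    h1 = sum(c * c for c in counts) / n**2
    top = max(counts)
    idx = counts.index(top)
    merged = [c for i, c in enumerate(counts) if i != idx]
    second = max(merged) if merged else 0
    merged.remove(second) if merged else None
    merged = [top + second] + merged
    h12 = sum(c * c for c in merged) / n**2
    h2 = h1 - (top / n) ** 2
    return h1, h2, h12


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def test_spectrum_identical_haplotypes():
    hap = np.zeros((4, 3), dtype=np.int8)
    spec = haplotype_spectrum(HaplotypeMatrix(hap, np.array([1, 2, 3])))
    np.testing.assert_allclose(spec.frequencies, [1.0])


def test_spectrum_one_over_n_rule():
    """N=10, one haplotype 20% missing among nine identical -> {0.9, 0.1}."""
    hap = np.zeros((10, 10), dtype=np.int8)
    hap[0, :2] = MISSING
    spec = haplotype_spectrum(HaplotypeMatrix(hap, np.arange(1, 11)),
                              max_missing_fraction=0.10)
    np.testing.assert_allclose(spec.frequencies, [0.9, 0.1])
    assert spec.singleton_count == 1


def test_spectrum_counts_classes(small_matrix):
    spec = haplotype_spectrum(small_matrix)
    np.testing.assert_allclose(spec.frequencies, [3 / 6, 2 / 6, 1 / 6])


def test_spectrum_missing_is_distinct_state():
    """Residual MISSING below the 1/N cutoff separates otherwise equal rows."""
    hap = np.zeros((3, 20), dtype=np.int8)
    hap[0, 0] = MISSING  # 5% missing: kept, but distinct from the others
    spec = haplotype_spectrum(HaplotypeMatrix(hap, np.arange(1, 21)))
    np.testing.assert_allclose(spec.frequencies, [2 / 3, 1 / 3])


# ---------------------------------------------------------------------------
# H statistics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "freqs, expected",
    [
        ([1.0], dict(h1=1, h2=0, h12=1, h2_h1=0)),
        ([0.5, 0.3, 0.2], dict(h1=0.38, h2=0.13, h12=0.68, h2_h1=0.13 / 0.38)),
    ],
)
def test_h_stats_arithmetic(freqs, expected):
    hs = h_stats(HaplotypeSpectrum(np.array(freqs), n=10))
    for key, val in expected.items():
        assert getattr(hs, key) == pytest.approx(val, abs=1e-12)


def test_h_stats_all_singletons():
    """100 singletons: h1=0.01, h12=0.02^2 + 98*1e-4, h2/h1=0.99."""
    spec = HaplotypeSpectrum(np.full(100, 0.01), n=100)
    hs = h_stats(spec)
    assert hs.h1 == pytest.approx(0.01, abs=1e-12)
    assert hs.h12 == pytest.approx(0.0102, abs=1e-12)
    assert hs.h2_h1 == pytest.approx(0.99, abs=1e-12)


@given(st.lists(st.integers(1, 50), min_size=1, max_size=40))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_h_stats_matches_pair_matching_oracle(counts):
    n = sum(counts)
    freqs = np.sort(np.array(counts, float))[::-1] / n
    hs = h_stats(HaplotypeSpectrum(freqs, n=n))
    h1, h2, h12 = brute_force_h(counts)
    assert hs.h1 == pytest.approx(h1, abs=1e-12)
    assert hs.h2 == pytest.approx(h2, abs=1e-12)
    assert hs.h12 == pytest.approx(h12, abs=1e-12)
    assert hs.h12 >= hs.h1 >= hs.h2 >= 0
    assert 0 <= hs.h2_h1 < 1


@given(st.lists(st.integers(1, 30), min_size=2, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_merging_classes_increases_homozygosity(counts):
    n = sum(counts)
    freqs = np.sort(np.array(counts, float))[::-1] / n
    merged = np.sort(np.concatenate([[freqs[0] + freqs[1]], freqs[2:]]))[::-1]
    a = h_stats(HaplotypeSpectrum(freqs, n=n))
    b = h_stats(HaplotypeSpectrum(merged, n=n))
    assert b.h1 > a.h1
    assert b.h12 >= a.h12 - 1e-12


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def test_diversity_two_haplotypes_one_difference():
    hap = np.zeros((2, 3), dtype=np.int8)
    hap[0, 1] = 1
    mat = HaplotypeMatrix(hap, np.array([2, 5, 9]))
    est = diversity(mat, window_bp=10, bootstrap_reps=50,
                    rng=np.random.default_rng(0))
    assert est.s_per_bp == pytest.approx(0.1)
    assert est.pi_per_bp == pytest.approx(0.1)


def test_diversity_monomorphic():
    hap = np.zeros((4, 5), dtype=np.int8)
    mat = HaplotypeMatrix(hap, np.array([1, 3, 5, 7, 9]))
    est = diversity(mat, window_bp=10, bootstrap_reps=50,
                    rng=np.random.default_rng(0))
    assert est.s_per_bp == 0 and est.pi_per_bp == 0
    assert est.s_ci == (0, 0) and est.pi_ci == (0, 0)


def test_diversity_unbiased_pi_with_four_haplotypes():
    """One site at frequency 0.5 among 4: pi/bp = (2*0.25*4/3)/10."""
    hap = np.zeros((4, 1), dtype=np.int8)
    hap[:2, 0] = 1
    mat = HaplotypeMatrix(hap, np.array([4]))
    est = diversity(mat, window_bp=10, bootstrap_reps=10,
                    rng=np.random.default_rng(0))
    assert est.pi_per_bp == pytest.approx(2 * 0.25 * (4 / 3) / 10)


def test_diversity_ci_brackets_point():
    rng = np.random.default_rng(5)
    hap = rng.integers(0, 2, size=(20, 200)).astype(np.int8)
    mat = HaplotypeMatrix(hap, np.sort(rng.choice(np.arange(1, 50_001), 200, replace=False)))
    est = diversity(mat, window_bp=10_000, bootstrap_reps=200, rng=rng)
    assert est.s_ci[0] <= est.s_per_bp <= est.s_ci[1]
    assert est.pi_ci[0] <= est.pi_per_bp <= est.pi_ci[1]


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _ld_mat(rows):
    hap = np.array(rows, dtype=np.int8)
    return HaplotypeMatrix(hap, np.arange(1, hap.shape[1] + 1) * 10)


def test_ld_perfect_coupling():
    mat = _ld_mat([[1, 1]] * 5 + [[0, 0]] * 5)
    prof = ld_r2(mat)
    assert prof.r2[0] == pytest.approx(1.0)


def test_ld_independence():
    mat = _ld_mat([[1, 1], [1, 0], [0, 1], [0, 0]])
    prof = ld_r2(mat)
    assert prof.r2[0] == pytest.approx(0.0, abs=1e-12)


def test_ld_two_by_two_table():
    """{11x4, 10x1, 01x1, 00x4}: R2 = (0.4-0.25)^2/(0.25*0.25) = 0.36."""
    mat = _ld_mat([[1, 1]] * 4 + [[1, 0], [0, 1]] + [[0, 0]] * 4)
    prof = ld_r2(mat)
    assert prof.r2[0] == pytest.approx(0.36)


def test_ld_maf_and_min_pairs_filters():
    rows = [[1, 1, 0]] + [[0, 0, 0]] * 24  # site 1 and 2 at MAF 0.04
    mat = _ld_mat(rows)
    prof = ld_r2(mat, maf_range=(0.05, 0.95))
    assert len(prof.r2) == 0
    # missingness reduces complete pairs below min_pairs
    hap = np.array([[1, 1], [1, 1], [0, 0], [0, 0], [1, 0], [0, 1]], dtype=np.int8)
    hap[3:, 0] = MISSING
    mat2 = HaplotypeMatrix(hap, np.array([10, 20]))
    assert len(ld_r2(mat2, min_pairs=4).r2) == 0


def test_smooth_ld_bins():
    from hapsweep.popgen_stats import LDProfile
    raw = np.array([[5, 0.2], [15, 0.4], [310, 0.7]])
    prof = smooth_ld(LDProfile(raw[:, 0], raw[:, 1], raw=raw))
    assert prof.r2[0] == pytest.approx(0.3)  # [1, 20] bin mean
    assert prof.distances[-1] == pytest.approx(375.0)  # (300, 450] midpoint
    assert prof.r2[-1] == pytest.approx(0.7)
    empty = smooth_ld(LDProfile(np.empty(0), np.empty(0), raw=np.empty((0, 2))))
    assert len(empty.r2) == 0


def test_smooth_ld_preserves_global_mean_when_balanced():
    rng = np.random.default_rng(1)
    d = np.concatenate([rng.integers(1 + 20 * b, 20 * (b + 1) + 1, 10) for b in range(15)])
    r2 = rng.random(d.size)
    from hapsweep.popgen_stats import LDProfile
    raw = np.column_stack([d, r2]).astype(float)
    prof = smooth_ld(LDProfile(raw[:, 0], raw[:, 1], raw=raw))
    assert prof.r2.mean() == pytest.approx(r2.mean(), abs=1e-9)
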