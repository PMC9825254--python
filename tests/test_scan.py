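"""Window calibration arithmetic, sliding H12, FDR threshold and peak rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapsweep.io_formats import MISSING, HaplotypeMatrix, RecombinationMap
from hapsweep.scan import (
    FootprintModel,
    ScanResult,
    WindowSpec,
    calibrate_x_window,
    call_peaks,
    expected_window_length,
    fdr_threshold,
    footprint_length,
    sliding_h12,
)


# ---------------------------------------------------------------------------
# Calibration arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_snps, density, expected", [
    (401, 0.0345, 11_623),
    (401, 0.0227, 17_665),
    (100, 0.01, 10_000),
])
def test_expected_window_length(n_snps, density, expected):
    assert expected_window_length(n_snps, density) == expected


@pytest.mark.parametrize("args, expected", [
    ((401, 0.0345, 0.0227), 264),  # 0.0227 * 11623.19 = 263.8
    ((401, 0.02, 0.02), 401),
    ((401, 0.02, 0.01), 201),  # 200.5 rounds half-up
])
def test_calibrate_x_window(args, expected):
    assert calibrate_x_window(*args) == expected


def test_footprint_length_formula():
    L = footprint_length(FootprintModel(s=0.0005, ne=1e6, rho_cm_per_bp=5e-7))
    assert L == pytest.approx(0.0005 / (np.log(500) * 5e-9), rel=1e-12)
    base = footprint_length(FootprintModel(s=0.01, ne=1e5, rho_cm_per_bp=5e-7))
    double = footprint_length(FootprintModel(s=0.01, ne=1e5, rho_cm_per_bp=1e-6))
    assert base == pytest.approx(2 * double, rel=1e-12)
    with pytest.raises(ValueError):
        footprint_length(FootprintModel(s=1e-9, ne=10, rho_cm_per_bp=5e-7))


# ---------------------------------------------------------------------------
# Sliding H12
# ---------------------------------------------------------------------------

def _matrix(hap):
    hap = np.asarray(hap, dtype=np.int8)
    return HaplotypeMatrix(hap, np.arange(1, hap.shape[1] + 1) * 100)


def test_sliding_h12_identical_haplotypes():
    mat = _matrix(np.zeros((100, 30)))
    res = sliding_h12(mat, WindowSpec(n_snps=10))
    assert np.allclose(res.h12, 1.0)
    assert len(res) == 21


def test_sliding_h12_all_singletons():
    rng = np.random.default_rng(0)
    hap = rng.integers(0, 2, size=(100, 40))
    # make rows unique by a distinct prefix pattern
    hap[:, :7] = (np.arange(100)[:, None] >> np.arange(7)) & 1
    res = sliding_h12(_matrix(hap), WindowSpec(n_snps=40))
    assert res.h12[0] == pytest.approx(0.0102, abs=1e-12)


def test_sliding_h12_downsample_full_is_identity():
    rng = np.random.default_rng(1)
    hap = rng.integers(0, 2, size=(20, 60))
    mat = _matrix(hap)
    a = sliding_h12(mat, WindowSpec(n_snps=30, downsample_to=30), seed=1)
    b = sliding_h12(mat, WindowSpec(n_snps=30), seed=99)
    np.testing.assert_allclose(a.h12, b.h12)


def test_sliding_h12_window_coordinates():
    mat = _matrix(np.zeros((4, 10)))
    res = sliding_h12(mat, WindowSpec(n_snps=4, step_snps=3))
    assert res.starts[0] == 100 and res.ends[0] == 400 and res.centers[0] == 250
    assert res.starts[1] == 400


def test_sliding_h12_downsampling_regression_guard():
    """401->265 down-sampling does not alter the scan's results: the sweep
    peak stays at the same place and window H12 moves far less than the
    scan's own between-window variation."""
    from hapsweep.synthetic_data import SweepSpec, SynthConfig, embed_sweep, generate_neutral_region
    mat = generate_neutral_region(SynthConfig(
        n_haplotypes=100, region_bp=200_000, s_per_bp=0.0345, seed=77))
    mat = embed_sweep(mat, SweepSpec(kind="hard", position=100_000, pf=0.8),
                      np.random.default_rng(3))
    full = sliding_h12(mat, WindowSpec(401, step_snps=25))
    down = sliding_h12(mat, WindowSpec(401, downsample_to=265, step_snps=25), seed=5)
    assert np.mean(np.abs(full.h12 - down.h12)) < np.std(full.h12)
    assert abs(full.centers[np.argmax(full.h12)] - down.centers[np.argmax(down.h12)]) < 12_000


# ---------------------------------------------------------------------------
# FDR threshold
# ---------------------------------------------------------------------------

def test_fdr_threshold_order_statistic():
    vals = np.arange(1, 101)  # 1..100
    assert fdr_threshold(vals, n_independent_windows=10) == 91
    assert fdr_threshold([0.3] * 10) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        fdr_threshold([0.1] * 9)


@given(st.lists(st.floats(0, 1, width=32), min_size=10, max_size=60))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_fdr_threshold_permutation_invariant_and_monotone(vals):
    rng = np.random.default_rng(0)
    t = fdr_threshold(vals)
    assert fdr_threshold(rng.permutation(vals)) == t
    assert fdr_threshold(vals + [t + 0.5]) >= t


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def _scan_from(h12_by_center, chrom="chr"):
    centers = np.array(sorted(h12_by_center), dtype=np.int64)
    h12 = np.array([h12_by_center[c] for c in centers])
    return ScanResult(centers, centers - 50, centers + 50, h12,
                      np.zeros_like(h12), np.zeros_like(centers), chrom)


def test_call_peaks_empty_below_threshold():
    scan = _scan_from({1000: 0.01, 2000: 0.02})
    assert call_peaks(scan, 0.05) == []


def test_call_peaks_500kb_exclusion():
    scan = _scan_from({100_000: 0.4, 110_000: 0.35, 250_000: 0.01,
                       400_000: 0.3, 410_000: 0.25})
    peaks = call_peaks(scan, 0.1, exclusion_bp=500_000)
    assert len(peaks) == 1
    assert peaks[0].apex_pos == 100_000 and peaks[0].apex_h12 == pytest.approx(0.4)
    far = _scan_from({100_000: 0.4, 250_000: 0.01, 700_000: 0.3})
    assert len(call_peaks(far, 0.1)) == 2


def test_call_peaks_low_recombination_masking():
    scan = _scan_from({100_000: 0.4})
    rmap = RecombinationMap([("chr", 0, 1_000_000, 1e-8)])
    assert call_peaks(scan, 0.1, rmap) == []
    masked = call_peaks(scan, 0.1, rmap, include_masked=True)
    assert len(masked) == 1 and masked[0].masked


def test_call_peaks_grouping_and_apex():
    scan = _scan_from({1000: 0.2, 1100: 0.5, 1200: 0.3,
                       2_000_000: 0.01, 5_000_000: 0.25})
    peaks = call_peaks(scan, 0.1)
    assert peaks[0].apex_pos == 1100
    assert peaks[0].start == 1000 - 50 and peaks[0].end == 1200 + 50
    assert [p.rank for p in peaks] == [1, 2]


def test_call_peaks_surviving_apexes_far_apart():
    rng = np.random.default_rng(2)
    centers = np.arange(0, 5_000_000, 10_000)
    h12 = rng.random(centers.size) * 0.5
    scan = ScanResult(centers, centers - 500, centers + 500, h12,
                      np.zeros_like(h12), np.zeros_like(centers))
    peaks = call_peaks(scan, 0.25)
    pos = sorted(p.apex_pos for p in peaks)
    assert all(b - a >= 500_000 for a, b in zip(pos, pos[1:]))
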