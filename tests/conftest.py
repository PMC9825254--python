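import numpy as np
import pytest

from hapsweep.abc_classifier import ABCPriors, TrainingConfig, build_bf_grid, simulate_training
from hapsweep.io_formats import MISSING, HaplotypeMatrix


@pytest.fixture
def small_matrix():
    """6 haplotypes x 5 sites with known class structure (3, 2, 1)."""
    hap = np.array([
        [0, 1, 0, 1, 0],
        [0, 1, 0, 1, 0],
        [0, 1, 0, 1, 0],
        [1, 0, 0, 1, 0],
        [1, 0, 0, 1, 0],
        [1, 1, 1, 1, 1],
    ], dtype=np.int8)
    return HaplotypeMatrix(hap, np.array([10, 20, 30, 40, 50]))


@pytest.fixture
def missing_matrix():
    hap = np.array([
        [0, MISSING, 1, 0],
        [0, 0, 1, 0],
        [1, 0, MISSING, MISSING],
        [1, 0, 1, 0],
    ], dtype=np.int8)
    return HaplotypeMatrix(hap, np.array([5, 15, 25, 35]))


@pytest.fixture(scope="session")
def trained_grid():
    """Desk-scale ABC grid (2000 sims/class) shared by classifier tests.

    Window spec matches the scan fixtures (265 SNPs, DGRP autosomal density).
    """
    cfg = TrainingConfig(ne=1000, window_snps=265)
    priors = ABCPriors()
    hard = simulate_training(cfg, priors, "hard", 2000, seed=101)
    soft = simulate_training(cfg, priors, "soft", 2000, seed=202)
    return build_bf_grid(hard, soft, meta={"config": cfg, "priors": priors})
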