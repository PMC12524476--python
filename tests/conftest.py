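import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cycledecon import (
    SimConfig,
    TimeCourseMatrix,
    cycling_gene_set,
    filter_low_counts,
    normalize_pair,
    simulate_timecourse,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noisy_sim():
    """Default multinomial simulation at seed 42 with its ground truth."""
    pair, truth = simulate_timecourse(SimConfig(seed=42))
    return pair, truth


@pytest.fixture(scope="session")
def noisy_filtered(noisy_sim):
    """Normalized + low-count-filtered spliced matrix of the seed-42 run."""
    pair, truth = noisy_sim
    norm_pair, sf = normalize_pair(pair)
    mat = filter_low_counts(norm_pair.spliced.with_layer("normalized"), 10.0)
    return mat, norm_pair, sf, truth


@pytest.fixture(scope="session")
def expectation_sim():
    """Deterministic expectation-mode simulation at the default seed."""
    pair, truth = simulate_timecourse(SimConfig(seed=0, noise_mode="expectation"))
    return pair, truth


@pytest.fixture(scope="session")
def expectation_filtered(expectation_sim):
    pair, truth = expectation_sim
    norm_pair, sf = normalize_pair(pair)
    mat = filter_low_counts(norm_pair.spliced.with_layer("normalized"), 10.0)
    return mat, truth


@pytest.fixture
def tiny_matrix():
    """A small fixed matrix for container/normalization unit tests."""
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.integers(1, 50, size=(6, 5)).astype(float),
        index=[f"g{i}" for i in range(6)],
        columns=[f"D{i + 1}" for i in range(5)],
    )
    return TimeCourseMatrix(df, layer="raw")


def sinusoid_matrix(n=14, cycles=2, amplitude=50.0, baseline=100.0, n_genes=1):
    """Pure Fourier-frequency cosine gene(s), noise-free."""
    t = np.arange(n)
    x = baseline + amplitude * np.cos(2 * np.pi * cycles * t / n)
    df = pd.DataFrame(
        np.tile(x, (n_genes, 1)),
        index=[f"sin{i}" for i in range(n_genes)],
        columns=[f"D{i + 1}" for i in range(n)],
    )
    return TimeCourseMatrix(df, layer="normalized")
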