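import numpy as np
import pytest

from rwbrmda import (
    FixtureSpec,
    PipelineParams,
    all_walks,
    compute_profiles,
    generate,
)


@pytest.fixture(scope="session")
def small_fixture():
    """Planted 3-block fixture small enough for strict per-fold evaluation."""
    spec = FixtureSpec(
        n_mirna=60, n_disease=12, n_blocks=3,
        within_block_assoc_prob=0.6, cross_block_assoc_prob=0.05,
        fs_within_mean=0.8, fs_cross_mean=0.2, fs_noise_sd=0.05,
        fs_coverage=0.7, seed=1,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_profiles(small_fixture):
    assoc, fs, _ = small_fixture
    sm, profiles = compute_profiles(assoc, fs, PipelineParams())
    return sm, profiles


def random_stochastic(rng, n):
    """Random column-stochastic matrix with strictly positive entries."""
    T = rng.random((n, n)) + 1e-3
    return T / T.sum(axis=0, keepdims=True)


def random_prob_vector(rng, n):
    p = rng.random(n) + 1e-3
    return p / p.sum()
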