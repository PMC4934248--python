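import numpy as np
import pytest

from pirwatch.hmm import HMMParams
from pirwatch.sensing import PartitionConfig, build_partition


@pytest.fixture(scope="session")
def default_partition():
    return build_partition(PartitionConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hmm(rng, n_states, n_mix=1, n_features=1, mean_scale=2.0):
    """Random valid HMM parameters for oracle tests."""
    return HMMParams(
        startprob=rng.dirichlet(np.ones(n_states)),
        transmat=rng.dirichlet(np.ones(n_states), size=n_states),
        weights=rng.dirichlet(np.ones(n_mix), size=n_states),
        means=rng.normal(0.0, mean_scale, (n_states, n_mix, n_features)),
        covars=rng.uniform(0.2, 2.0, (n_states, n_mix, n_features)),
    )


def separated_hmms(k=4, n_features=3, spread=6.0):
    """k well-separated 2-state generating HMMs for clustering checks.

    State means of model j live around +/- spread in a direction unique to j,
    so sequences from different models are far apart in likelihood space.
    """
    models = []
    rng = np.random.default_rng(777)
    for j in range(k):
        direction = np.zeros(n_features)
        direction[j % n_features] = 1.0
        base = spread * (1 + j // n_features) * direction
        models.append(HMMParams(
            startprob=[0.5, 0.5],
            transmat=[[0.9, 0.1], [0.1, 0.9]],
            weights=np.ones((2, 1)),
            means=np.stack([(base + 1.5)[None, :], (base - 1.5)[None, :]]),
            covars=np.full((2, 1, n_features), 0.5),
        ))
    return models


def assert_em_monotone(history, slack=1e-6):
    """Training log-likelihood must be non-decreasing up to numerical slack."""
    h = np.asarray(history, dtype=float)
    diffs = np.diff(h)
    bound = -slack * np.maximum(1.0, np.abs(h[:-1]))
    assert np.all(diffs >= bound), f"EM log-likelihood decreased: {diffs.min()}"
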