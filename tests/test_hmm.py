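"""HMM core tests: forward algorithm against oracles, EM behavior."""

import itertools
import warnings

import numpy as np
import pytest

from pirwatch.hmm import (
    HMMParams,
    fit_hmm,
    frame_log_likelihood,
    log_likelihood,
    log_likelihood_batch,
    sample_hmm,
)
from pirwatch.hmm import _as_frames, _forward_log, _forward_scaled

from conftest import assert_em_monotone, random_hmm


def brute_force_loglik(y, params):
    """Sum over all state paths — the forward algorithm's defining identity."""
    frames = _as_frames(y)
    flp = frame_log_likelihood(frames, params)
    t_len, s = flp.shape
    total = -np.inf
    for path in itertools.product(range(s), repeat=t_len):
        lp = np.log(params.startprob[path[0]]) + flp[0, path[0]]
        for t in range(1, t_len):
            lp += np.log(params.transmat[path[t - 1], path[t]]) + flp[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


class TestForward:
    def test_matches_path_enumeration(self, rng):
        for _ in range(25):
            s = int(rng.integers(1, 4))
            t = int(rng.integers(1, 6))
            d = int(rng.integers(1, 4))
            params = random_hmm(rng, s, 1, d)
            y = rng.normal(0, 2, (d, t))
            got = log_likelihood(y, params)
            want = brute_force_loglik(y, params)
            assert got == pytest.approx(want, rel=1e-8)

    def test_one_state_model_is_iid_gaussian_density(self, rng):
        """With a single state the forward sum collapses to a product of
        per-frame Gaussian densities."""
        from scipy.stats import multivariate_normal
        params = random_hmm(rng, 1, 1, 3)
        y = rng.normal(0, 1, (3, 20))
        mvn = multivariate_normal(params.means[0, 0], np.diag(params.covars[0, 0]))
        want = mvn.logpdf(y.T).sum()
        assert log_likelihood(y, params) == pytest.approx(want, rel=1e-10)

    def test_scaled_and_log_space_agree(self, rng):
        params = random_hmm(rng, 4, 2, 3)
        y = rng.normal(0, 2, (3, 150))
        flp = frame_log_likelihood(_as_frames(y), params)
        _, logc, offset = _forward_scaled(flp, params.startprob, params.transmat)
        scaled = logc.sum() + offset.sum()
        logspace = _forward_log(flp, params.startprob, params.transmat)
        assert scaled == pytest.approx(logspace, abs=1e-9 * abs(logspace))

    def test_batch_agrees_with_single(self, rng):
        params = random_hmm(rng, 3, 2, 2)
        seqs = [rng.normal(0, 2, (2, int(rng.integers(3, 40)))) for _ in range(15)]
        batch = log_likelihood_batch(seqs, params)
        single = [log_likelihood(y, params) for y in seqs]
        np.testing.assert_allclose(batch, single, rtol=1e-10)

    def test_agrees_with_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = random_hmm(rng, 3, 2, 2)
        ref = hmmlearn.GMMHMM(n_components=3, n_mix=2, covariance_type="diag",
                              init_params="")
        ref.startprob_ = params.startprob
        ref.transmat_ = params.transmat
        ref.weights_ = params.weights
        ref.means_ = params.means
        ref.covars_ = params.covars
        y = rng.normal(0, 2, (2, 80))
        assert log_likelihood(y, params) == pytest.approx(ref.score(y.T), rel=1e-10)

    def test_state_permutation_invariance(self, rng):
        params = random_hmm(rng, 3, 2, 2)
        perm = np.array([2, 0, 1])
        permuted = HMMParams(
            startprob=params.startprob[perm],
            transmat=params.transmat[np.ix_(perm, perm)],
            weights=params.weights[perm],
            means=params.means[perm],
            covars=params.covars[perm],
        )
        y = rng.normal(0, 1, (2, 30))
        assert log_likelihood(y, params) == pytest.approx(
            log_likelihood(y, permuted), rel=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        params = random_hmm(rng, 2, 1, 3)
        with pytest.raises(ValueError, match="mismatch"):
            log_likelihood(rng.normal(0, 1, (2, 10)), params)


class TestFit:
    def test_recovers_separated_two_state_model(self):
        true = HMMParams(startprob=[0.6, 0.4], transmat=[[0.9, 0.1], [0.2, 0.8]],
                         weights=np.ones((2, 1)), means=[[[5.0]], [[-5.0]]],
                         covars=[[[1.0]], [[1.0]]])
        y, _ = sample_hmm(true, 2000, seed=11)
        fit = fit_hmm(y, n_states=2, n_mix=1, seed=0)
        recovered = np.sort(fit.means.ravel())
        np.testing.assert_allclose(recovered, [-5.0, 5.0], atol=0.2)
        assert_em_monotone(fit.history)

    def test_normalization_invariants(self, rng):
        y = rng.normal(0, 1, (3, 120))
        fit = fit_hmm(y, n_states=3, n_mix=2, seed=1, max_iter=15)
        assert fit.startprob.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.transmat.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(fit.covars >= 1e-3 - 1e-15)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(0, 1, (2, 80))
        a = fit_hmm(y, n_states=3, n_mix=2, seed=7, max_iter=10)
        b = fit_hmm(y, n_states=3, n_mix=2, seed=7, max_iter=10)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transmat, b.transmat)
        assert a.history == b.history

    def test_multi_sequence_fit_monotone(self, rng):
        seqs = [rng.normal(0, 1, (2, int(rng.integers(20, 60)))) for _ in range(5)]
        fit = fit_hmm(seqs, n_states=3, n_mix=2, seed=2, max_iter=25)
        assert_em_monotone(fit.history)

    def test_constant_sequence_warns_and_floors(self):
        y = np.full((2, 50), 1.5)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_hmm(y, n_states=2, n_mix=1, seed=0, max_iter=5)
        assert np.all(fit.covars == 1e-3)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_hmm(np.zeros((2, 3)), n_states=8)

    def test_serialization_roundtrip(self, rng):
        fit = fit_hmm(rng.normal(0, 1, (2, 60)), n_states=2, n_mix=2, seed=3,
                      max_iter=5)
        clone = HMMParams.from_dict(fit.to_dict())
        y = rng.normal(0, 1, (2, 20))
        assert log_likelihood(y, clone) == pytest.approx(
            log_likelihood(y, fit), rel=1e-12)


class TestSample:
    def test_sample_shape_and_determinism(self, rng):
        params = random_hmm(rng, 2, 2, 3)
        y1, s1 = sample_hmm(params, 50, seed=4)
        y2, s2 = sample_hmm(params, 50, seed=4)
        assert y1.shape == (3, 50)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(s1, s2)
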