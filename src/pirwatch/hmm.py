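"""Gaussian-mixture-emission hidden Markov models.

Activity samples are short multichannel sequences; each is modeled by an HMM
lambda = {pi, A, {c, mu, Sigma}} with diagonal-covariance Gaussian-mixture
emissions.  This module implements Baum-Welch (EM) fitting with a covariance
floor and a full per-iteration training log-likelihood history, plus the
forward-algorithm log-likelihood in two numerically stabilized variants
(scaled linear-domain and log-space) that agree to rounding error.

Sequences follow the node convention throughout: arrays of shape
(n_channels, n_samples), one column per time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "HMMParams",
    "fit_hmm",
    "log_likelihood",
    "log_likelihood_batch",
    "sample_hmm",
    "frame_log_likelihood",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """Parameters of a Gaussian-mixture-emission HMM (diagonal covariances)."""

    startprob: np.ndarray          # (S,)
    transmat: np.ndarray           # (S, S)
    weights: np.ndarray            # (S, K) mixture weights per state
    means: np.ndarray              # (S, K, D)
    covars: np.ndarray             # (S, K, D) diagonal entries
    history: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int | None = None

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covars = np.asarray(self.covars, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_mix(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.means.shape[2]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states, "n_mix": self.n_mix, "seed": self.seed,
            "startprob": self.startprob.tolist(), "transmat": self.transmat.tolist(),
            "weights": self.weights.tolist(), "means": self.means.tolist(),
            "covars": self.covars.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(startprob=d["startprob"], transmat=d["transmat"],
                   weights=d["weights"], means=d["means"], covars=d["covars"],
                   seed=d.get("seed"))


def _as_frames(y: np.ndarray) -> np.ndarray:
    """Channels-by-samples sequence -> (T, D) frame matrix."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.ndim != 2:
        raise ValueError("observation sequence must be a 2-D channels x samples array")
    if not np.all(np.isfinite(y)):
        raise ValueError("observation sequence contains non-finite values")
    return y.T


def _component_logpdf(frames: np.ndarray, params: HMMParams) -> np.ndarray:
    """Per state-mixture Gaussian log densities, shape (T, S, K)."""
    x = frames[:, None, None, :]                       # (T,1,1,D)
    diff = x - params.means[None]                      # (T,S,K,D)
    inv = 1.0 / params.covars
    quad = np.einsum("tskd,skd->tsk", diff ** 2, inv)
    logdet = np.log(params.covars).sum(axis=-1)        # (S,K)
    d = params.n_features
    return -0.5 * (quad + logdet[None] + d * _LOG_2PI)


def frame_log_likelihood(frames: np.ndarray, params: HMMParams) -> np.ndarray:
    """Emission log density of each frame under each state, shape (T, S)."""
    comp = _component_logpdf(frames, params)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    return logsumexp(comp + logw[None], axis=2)


def _forward_log(flp: np.ndarray, startprob: np.ndarray, transmat: np.ndarray) -> float:
    """Log-space forward recursion; returns total log-likelihood."""
    with np.errstate(divide="ignore"):
        log_start = np.log(startprob)
        log_trans = np.log(transmat)
    alpha = log_start + flp[0]
    for t in range(1, len(flp)):
        alpha = logsumexp(alpha[:, None] + log_trans, axis=0) + flp[t]
    return float(logsumexp(alpha))


def _forward_scaled(flp: np.ndarray, startprob: np.ndarray, transmat: np.ndarray):
    """Scaled linear-domain forward pass.

    Returns (alpha_hat (T,S) row-normalized, per-step log normalizers (T,),
    per-frame emission offsets (T,)); total log-likelihood is the sum of the
    last two.  The offsets keep ``exp`` in range for arbitrary densities.
    """
    t_len, s = flp.shape
    offset = flp.max(axis=1)
    b = np.exp(flp - offset[:, None])
    alpha = np.empty((t_len, s))
    logc = np.empty(t_len)
    a = startprob * b[0]
    for t in range(t_len):
        if t > 0:
            a = (alpha[t - 1] @ transmat) * b[t]
        norm = a.sum()
        if norm <= 0 or not np.isfinite(norm):
            raise FloatingPointError("forward pass underflowed to zero probability")
        alpha[t] = a / norm
        logc[t] = np.log(norm)
    return alpha, logc, offset


def log_likelihood(y: np.ndarray, params: HMMParams) -> float:
    """Natural-log forward-algorithm likelihood of a sequence under a model."""
    frames = _as_frames(y)
    if frames.shape[1] != params.n_features:
        raise ValueError(
            f"dimension mismatch: sequence has {frames.shape[1]} channels, "
            f"model expects {params.n_features}")
    flp = frame_log_likelihood(frames, params)
    return _forward_log(flp, params.startprob, params.transmat)


def log_likelihood_batch(sequences: list[np.ndarray], params: HMMParams) -> np.ndarray:
    """Forward log-likelihood of many sequences under one model.

    Vectorizes the scaled forward pass across sequences (padded to the longest
    length); agrees with :func:`log_likelihood` to rounding error.
    """
    frames_list = [_as_frames(y) for y in sequences]
    for f in frames_list:
        if f.shape[1] != params.n_features:
            raise ValueError("dimension mismatch in batch scoring")
    lens = np.array([len(f) for f in frames_list])
    n, t_max, s = len(frames_list), int(lens.max()), params.n_states
    flp_all = frame_log_likelihood(np.concatenate(frames_list), params)
    flp = np.zeros((n, t_max, s))
    pos = 0
    for i, ln in enumerate(lens):
        flp[i, :ln] = flp_all[pos:pos + ln]
        pos += ln
    # log-domain recursion with a per-sequence running offset: robust to the
    # extreme emission mismatches that arise when cross-scoring sequences
    # under models fitted to very different activities
    with np.errstate(divide="ignore"):
        log_start = np.log(params.startprob)
    alpha = log_start[None, :] + flp[:, 0]         # (n, S)
    for t in range(1, t_max):
        m = alpha.max(axis=1)
        m_safe = np.where(np.isfinite(m), m, 0.0)
        lin = np.exp(alpha - m_safe[:, None])
        with np.errstate(divide="ignore"):
            a_new = np.log(lin @ params.transmat) + m_safe[:, None] + flp[:, t]
        alpha = np.where((t < lens)[:, None], a_new, alpha)
    return logsumexp(alpha, axis=1)


def sample_hmm(params: HMMParams, n_samples: int, seed: int | None = None):
    """Draw one sequence from the model; returns (channels x samples, states)."""
    rng = np.random.default_rng(seed)
    s_seq = np.empty(n_samples, dtype=int)
    x = np.empty((n_samples, params.n_features))
    state = rng.choice(params.n_states, p=params.startprob)
    for t in range(n_samples):
        if t > 0:
            state = rng.choice(params.n_states, p=params.transmat[state])
        s_seq[t] = state
        k = rng.choice(params.n_mix, p=params.weights[state])
        x[t] = rng.normal(params.means[state, k], np.sqrt(params.covars[state, k]))
    return x.T, s_seq


_PROB_FLOOR = 1e-10


def _floored(p: np.ndarray, floor: float = _PROB_FLOOR) -> np.ndarray:
    """Clip a (row-)stochastic array away from zero and renormalize."""
    p = np.maximum(p, floor)
    return p / p.sum(axis=-1, keepdims=True)


def _init_params(frames: np.ndarray, n_states: int, n_mix: int,
                 covar_floor: float, seed: int) -> HMMParams:
    """K-means means, pooled variances, uniform-plus-jitter pi/A/weights."""
    rng = np.random.default_rng(seed)
    d = frames.shape[1]
    pooled_var = np.maximum(frames.var(axis=0), covar_floor)
    scale = np.sqrt(pooled_var)
    n_unique = len(np.unique(frames, axis=0))
    if n_unique >= n_states:
        km = KMeans(n_clusters=n_states, n_init=4, random_state=seed)
        centers = km.fit(frames).cluster_centers_
    else:
        centers = frames[rng.integers(0, len(frames), size=n_states)]
    means = np.empty((n_states, n_mix, d))
    for s in range(n_states):
        for k in range(n_mix):
            means[s, k] = centers[s] + 0.1 * scale * rng.standard_normal(d)
    covars = np.tile(pooled_var, (n_states, n_mix, 1))
    start = rng.uniform(0.9, 1.1, n_states)
    trans = rng.uniform(0.9, 1.1, (n_states, n_states))
    weights = rng.uniform(0.9, 1.1, (n_states, n_mix))
    return HMMParams(
        startprob=start / start.sum(),
        transmat=trans / trans.sum(axis=1, keepdims=True),
        weights=weights / weights.sum(axis=1, keepdims=True),
        means=means, covars=covars, seed=seed)


def fit_hmm(
    sequences,
    n_states: int = 8,
    n_mix: int = 2,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    covar_floor: float = 1e-3,
) -> HMMParams:
    """Baum-Welch fit of a GMM-emission HMM to one or more sequences.

    ``sequences`` is a channels x samples array or a list of them (multi-
    sequence EM sums sufficient statistics over sequences).  The fit is
    deterministic given ``seed``; ``params.history`` records the training
    log-likelihood at the start of every EM iteration, which is non-decreasing
    up to numerical rounding (variance flooring is a constrained M-step and
    preserves monotonicity).  Convergence: absolute log-likelihood change
    below ``tol``.
    """
    if not isinstance(sequences, (list, tuple)):
        sequences = [sequences]
    frames_list = [_as_frames(y) for y in sequences]
    if not frames_list:
        raise ValueError("no training sequences given")
    d = frames_list[0].shape[1]
    if any(f.shape[1] != d for f in frames_list):
        raise ValueError("all sequences must share the channel count")
    pooled = np.concatenate(frames_list)
    if len(pooled) < n_states:
        raise ValueError(
            f"too few observations ({len(pooled)}) for {n_states} states")
    if np.all(pooled.var(axis=0) < covar_floor):
        warnings.warn("degenerate (near-constant) training data; "
                      "covariances held at the floor", RuntimeWarning)
    params = _init_params(pooled, n_states, n_mix, covar_floor, seed)
    s, k = n_states, n_mix
    prev_ll = -np.inf
    for _ in range(max_iter):
        start_acc = np.zeros(s)
        trans_acc = np.zeros((s, s))
        w_acc = np.zeros((s, k))
        x_acc = np.zeros((s, k, d))
        x2_acc = np.zeros((s, k, d))
        total_ll = 0.0
        for frames in frames_list:
            comp = _component_logpdf(frames, params)   # (T,S,K)
            with np.errstate(divide="ignore"):
                logw = np.log(params.weights)
            comp_w = comp + logw[None]
            flp = logsumexp(comp_w, axis=2)            # (T,S)
            alpha, logc, offset = _forward_scaled(flp, params.startprob, params.transmat)
            total_ll += float(logc.sum() + offset.sum())
            # scaled backward pass with the same per-frame offsets
            t_len = len(frames)
            b = np.exp(flp - offset[:, None])
            beta = np.empty_like(alpha)
            beta[-1] = 1.0
            for t in range(t_len - 2, -1, -1):
                beta[t] = (params.transmat @ (b[t + 1] * beta[t + 1]))
                beta[t] /= np.exp(logc[t + 1])
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            start_acc += gamma[0]
            if t_len > 1:
                # xi summed over t in the scaled domain:
                # xi_t = alpha_t (.) A (.) (b_{t+1} beta_{t+1}) / c_{t+1}
                rhs = (b[1:] * beta[1:]) / np.exp(logc[1:])[:, None]
                trans_acc += params.transmat * (alpha[:-1].T @ rhs)
            # per-mixture responsibilities within each state
            resp = np.exp(comp_w - flp[:, :, None]) * gamma[:, :, None]
            w_acc += resp.sum(axis=0)
            x_acc += np.einsum("tsk,td->skd", resp, frames)
            x2_acc += np.einsum("tsk,td->skd", resp, frames ** 2)
        params.history.append(total_ll)
        if total_ll - prev_ll < tol and np.isfinite(prev_ll):
            params.converged = True
            break
        prev_ll = total_ll
        # M-step; empty states/components keep their previous parameters so the
        # update remains a (generalized) EM step.  Discrete distributions are
        # floored at a tiny probability: exact zeros would make later cross-
        # scoring of unrelated sequences degenerate, and the floor perturbs the
        # objective far below the monotonicity slack.
        new_start = _floored(start_acc / start_acc.sum())
        trans_rows = trans_acc.sum(axis=1)
        new_trans = params.transmat.copy()
        ok = trans_rows > 1e-300
        new_trans[ok] = trans_acc[ok] / trans_rows[ok, None]
        new_trans = _floored(new_trans)
        state_tot = w_acc.sum(axis=1)
        new_w = params.weights.copy()
        oks = state_tot > 1e-300
        new_w[oks] = w_acc[oks] / state_tot[oks, None]
        new_w = _floored(new_w)
        new_means = params.means.copy()
        new_cov = params.covars.copy()
        okk = w_acc > 1e-10
        mu = x_acc[okk] / w_acc[okk][:, None]
        new_means[okk] = mu
        new_cov[okk] = np.maximum(x2_acc[okk] / w_acc[okk][:, None] - mu ** 2,
                                  covar_floor)
        params = HMMParams(startprob=new_start, transmat=new_trans, weights=new_w,
                           means=new_means, covars=new_cov,
                           history=params.history, converged=params.converged,
                           seed=seed)
    return params
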