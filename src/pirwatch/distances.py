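"""Likelihood-space sequence distances.

Each of the N training sequences is modeled by its own HMM; the likelihood
matrix l[i, j] = log P(Y_j; lambda_i) / len(Y_j) treats the N fitted models as
a discrete approximation of the model space.  Normalizing each column into a
probability distribution over models (column-wise softmax, computed with
log-sum-exp) turns every sequence into a pdf over the shared model set, and
the symmetrized Kullback-Leibler divergence between these pdfs gives a
distance that reflects the whole collection, not just the pair.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .hmm import HMMParams, fit_hmm, log_likelihood_batch

__all__ = [
    "likelihood_matrix",
    "normalize_columns",
    "kl_divergence",
    "symmetric_kl",
    "distance_matrix",
    "hmm_distance_matrix",
    "fit_sequence_models",
]

KL_FLOOR = 1e-12  # guards against underflowed softmax entries


def likelihood_matrix(sequences, models: list[HMMParams]) -> np.ndarray:
    """Length-normalized log-likelihood of every sequence under every model.

    Entry (i, j) is ``log P(Y_j; lambda_i) / len(Y_j)`` — rows are models,
    columns are sequences; model i is expected to have been trained on
    sequence i.  Raises on any non-finite entry, naming the offending pair.
    """
    n = len(sequences)
    if len(models) != n:
        raise ValueError(f"{n} sequences but {len(models)} models")
    lengths = np.array([np.atleast_2d(np.asarray(y)).shape[1] for y in sequences])
    l = np.empty((n, n))
    for i, model in enumerate(models):
        l[i] = log_likelihood_batch(sequences, model) / lengths
    if not np.all(np.isfinite(l)):
        i, j = np.argwhere(~np.isfinite(l))[0]
        raise FloatingPointError(
            f"non-finite log-likelihood for model {i}, sequence {j}")
    return l


def normalize_columns(l: np.ndarray) -> np.ndarray:
    """Column-stochastic normalization of the likelihood matrix.

    Column j becomes the softmax over models of l[:, j] (log-sum-exp for
    stability): a pdf over the approximated model space conditioned on Y_j.
    """
    l = np.asarray(l, dtype=float)
    if not np.all(np.isfinite(l)):
        raise ValueError("likelihood matrix must be finite")
    return np.exp(l - logsumexp(l, axis=0, keepdims=True))


def kl_divergence(fp: np.ndarray, fq: np.ndarray, floor: float = KL_FLOOR) -> float:
    """Discrete KL divergence D(fp || fq), in nats.

    Uses the conventions 0 log(0/q) = 0 and q floored at ``floor``.
    """
    fp = np.asarray(fp, dtype=float)
    fq = np.asarray(fq, dtype=float)
    if fp.shape != fq.shape:
        raise ValueError("distributions must have the same support size")
    q = np.maximum(fq, floor)
    mask = fp > 0
    return float(np.sum(fp[mask] * np.log(fp[mask] / q[mask])))


def symmetric_kl(fp: np.ndarray, fq: np.ndarray, floor: float = KL_FLOOR) -> float:
    """Symmetrized KL: the average of both directed divergences."""
    return 0.5 * (kl_divergence(fp, fq, floor) + kl_divergence(fq, fp, floor))


def distance_matrix(ln: np.ndarray, floor: float = KL_FLOOR) -> np.ndarray:
    """Pairwise symmetrized-KL distances between the columns of ``ln``.

    Exploits sym-KL(p, q) = 1/2 sum_k (p_k - q_k)(log p_k - log q_k) with both
    pdfs floored, which makes the result exactly symmetric with a zero
    diagonal.  Returns an N x N non-negative matrix.
    """
    p = np.maximum(np.asarray(ln, dtype=float), floor)
    logp = np.log(p)
    n = p.shape[1]
    d = np.empty((n, n))
    for i in range(n):
        d[i] = 0.5 * np.sum(
            (p[:, i][:, None] - p) * (logp[:, i][:, None] - logp), axis=0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def fit_sequence_models(
    sequences,
    n_states: int = 8,
    n_mix: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> list[HMMParams]:
    """Fit one HMM per sequence (seeded deterministically per index)."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=len(sequences))
    return [fit_hmm(y, n_states=n_states, n_mix=n_mix, seed=int(s), **fit_kwargs)
            for y, s in zip(sequences, seeds)]


def hmm_distance_matrix(
    sequences,
    n_states: int = 8,
    n_mix: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Full chain: per-sequence HMMs -> likelihoods -> normalize -> sym-KL."""
    models = fit_sequence_models(sequences, n_states=n_states, n_mix=n_mix,
                                 seed=seed, **fit_kwargs)
    l = likelihood_matrix(sequences, models)
    return distance_matrix(normalize_columns(l))
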