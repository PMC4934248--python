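"""Normal-activity profiling and abnormality scoring.

After clustering, each cluster of normal activity samples is modeled by one
GMM-emission HMM; a sample's feature vector is its log-likelihood under each
of the C cluster models.  A one-class SVM in its support-vector-data-
description (SVDD) reading — the minimal sphere in RBF feature space that
contains most of the training data — profiles the normal feature vectors, and
the signed score R^2 - ||phi(x) - a||^2 (negative = abnormal) is kept
continuous for ROC sweeping.  A single-HMM baseline ("OneHMM"), which skips
clustering entirely, is provided for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import OneClassSVM

from .hmm import HMMParams, fit_hmm, log_likelihood_batch

__all__ = [
    "fit_cluster_models",
    "extract_features",
    "OSVMModel",
    "train_osvm",
    "decision_score",
    "onehmm_baseline",
]


def fit_cluster_models(
    sequences,
    labels,
    n_states: int = 8,
    n_mix: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> list[HMMParams]:
    """One multi-sequence Baum-Welch fit per cluster, in label order."""
    labels = np.asarray(labels)
    models = []
    root = np.random.default_rng(seed)
    for c in np.unique(labels):
        members = [y for y, l in zip(sequences, labels) if l == c]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        models.append(fit_hmm(members, n_states=n_states, n_mix=n_mix,
                              seed=int(root.integers(0, 2**31 - 1)), **fit_kwargs))
    return models


def extract_features(sequences, cluster_models: list[HMMParams]) -> np.ndarray:
    """C-dimensional log-likelihood feature vectors.

    Component j of a sample's vector is its forward log-likelihood under
    cluster model j.  Accepts one sequence (returns shape (C,)) or a list
    (returns (n, C)).
    """
    single = isinstance(sequences, np.ndarray) and np.ndim(sequences) == 2
    seq_list = [sequences] if single else list(sequences)
    feats = np.column_stack(
        [log_likelihood_batch(seq_list, m) for m in cluster_models])
    return feats[0] if single else feats


class OSVMModel:
    """SVDD solution derived from the one-class SVM dual.

    Support coefficients are normalized to sum to one, so the kernel-space
    center is a = sum_i alpha_i phi(x_i) and, with the RBF kernel
    (k(x, x) = 1), the squared distance of a point to the center is
    ``1 - 2 sum_i alpha_i k(x, x_i) + alpha' K alpha``.  The radius is read
    off the boundary support vectors (0 < alpha_i < 1/(nu n)); features are
    standardized with training statistics before the kernel.
    """

    def __init__(self, support_vectors, alpha, gamma, nu, radius2, const_term,
                 mean, scale, log_compress=False):
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.alpha = np.asarray(alpha, dtype=float)
        self.gamma = float(gamma)
        self.nu = float(nu)
        self.radius2 = float(radius2)
        self.const_term = float(const_term)  # alpha' K alpha
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.log_compress = bool(log_compress)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "alpha": self.alpha.tolist(), "gamma": self.gamma, "nu": self.nu,
            "radius2": self.radius2, "const_term": self.const_term,
            "mean": self.mean.tolist(), "scale": self.scale.tolist(),
            "log_compress": self.log_compress,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OSVMModel":
        return cls(d["support_vectors"], d["alpha"], d["gamma"], d["nu"],
                   d["radius2"], d["const_term"], d["mean"], d["scale"],
                   d.get("log_compress", False))


def _median_sq_dist(x: np.ndarray) -> float:
    diff = x[:, None, :] - x[None, :, :]
    sq = (diff ** 2).sum(axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return float(np.median(sq[iu])) if len(iu[0]) else 0.0


def _compress(x: np.ndarray) -> np.ndarray:
    """Log-magnitude compression of (negative) log-likelihood features.

    Raw log-likelihoods span orders of magnitude with sequence length; the
    monotone map x -> -log(-x) tames the heavy tail so the sphere profile is
    not dominated by the longest recordings.
    """
    return -np.log(np.maximum(-x, 1.0))


def train_osvm(features: np.ndarray, nu: float = 0.01, gamma="median",
               standardize: bool = True, log_compress: bool = False) -> OSVMModel:
    """Fit the minimal-sphere profile of the normal feature vectors.

    ``nu`` upper-bounds the fraction of training points left outside the
    sphere (and lower-bounds the support-vector fraction).  ``gamma='median'``
    sets the RBF width to 1 / (2 * median pairwise squared distance) of the
    standardized features.  ``log_compress`` applies the log-magnitude map to
    each component before standardization (for raw log-likelihood features).
    The dual problem (box bound 1/(nu n), coefficients summing to one) is
    solved by libsvm via scikit-learn.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("need at least one training vector")
    if not 0 < nu <= 1:
        raise ValueError(
            f"nu={nu} with n={n} gives an infeasible dual: need 0 < nu <= 1 "
            "(box bound 1/(nu*n) must admit sum(alpha)=1)")
    if log_compress:
        x = _compress(x)
    if standardize:
        mean = x.mean(axis=0)
        scale = np.maximum(x.std(axis=0), 1e-9)
    else:
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    xs = (x - mean) / scale
    med = _median_sq_dist(xs)
    if med <= 0:
        # all training points coincide: zero-radius sphere at that point
        g = 1.0 if gamma == "median" else float(gamma)
        sv = xs[:1]
        return OSVMModel(sv, [1.0], g, nu, 0.0, 1.0, mean, scale, log_compress)
    g = 1.0 / (2.0 * med) if gamma == "median" else float(gamma)
    svm = OneClassSVM(kernel="rbf", gamma=g, nu=nu, tol=1e-8)
    svm.fit(xs)
    alpha = svm.dual_coef_.ravel()
    alpha = alpha / alpha.sum()
    sv = svm.support_vectors_
    k_sv = rbf_kernel(sv, sv, gamma=g)
    const = float(alpha @ k_sv @ alpha)
    dist2 = 1.0 - 2.0 * (k_sv @ alpha) + const
    box = 1.0 / (nu * n)
    boundary = alpha < box * (1.0 - 1e-6)
    if boundary.any():
        radius2 = float(np.median(dist2[boundary]))
    else:  # every support vector at the box bound; fall back to all of them
        radius2 = float(np.median(dist2))
    return OSVMModel(sv, alpha, g, nu, radius2, const, mean, scale, log_compress)


def decision_score(x: np.ndarray, model: OSVMModel) -> float | np.ndarray:
    """Signed sphere score R^2 - ||phi(x) - a||^2; negative means abnormal."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if model.log_compress:
        x2 = _compress(x2)
    xs = (x2 - model.mean) / model.scale
    k = rbf_kernel(xs, model.support_vectors, gamma=model.gamma)
    dist2 = 1.0 - 2.0 * (k @ model.alpha) + model.const_term
    score = model.radius2 - dist2
    return float(score[0]) if single else score


def onehmm_baseline(
    train_sequences,
    test_sequences,
    n_states: int = 8,
    n_mix: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Single-HMM baseline: no clustering, one model for all normal activity.

    All training sequences are pooled into one multi-sequence Baum-Welch fit;
    the score of a test sequence is its length-normalized log-likelihood
    (higher = more normal), to be thresholded or swept into an ROC.
    """
    if not len(train_sequences):
        raise ValueError("training set is empty")
    model = fit_hmm(list(train_sequences), n_states=n_states, n_mix=n_mix,
                    seed=seed, **fit_kwargs)
    lengths = np.array([np.atleast_2d(np.asarray(y)).shape[1]
                        for y in test_sequences])
    return log_likelihood_batch(list(test_sequences), model) / lengths
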