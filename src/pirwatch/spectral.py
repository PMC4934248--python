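"""Self-tuning spectral clustering with automatic model selection.

Builds a locally scaled affinity from a distance matrix (each point's kernel
width is its distance to the K-th neighbor), forms the symmetric normalized
Laplacian D^{-1/2} S D^{-1/2}, and — for each candidate cluster count c —
rotates the top-c eigenvector matrix X toward a cluster-indicator form by
minimizing the alignment cost

    J = sum_i sum_j Z_ij^2 / max_j Z_ij^2,        Z = X R,

over rotations R parameterized as a product of c(c-1)/2 Givens rotations,
optimized by incremental gradient descent on the angles.  J is bounded by
N <= J <= N*c and equals N exactly when every row of Z has a single non-zero
entry.  The selected cluster count is the *largest* candidate whose cost ties
the minimum (within a tolerance), and points are assigned to the column
carrying their row-wise maximum of Z^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag, eigh, polar

__all__ = [
    "SpectralConfig",
    "RotationResult",
    "ClusterSolution",
    "local_scales",
    "affinity",
    "normalized_laplacian",
    "top_eigenvectors",
    "align_rotation",
    "select_and_cluster",
    "cluster_distances",
]

_SCALE_FLOOR = 1e-12


@dataclass(frozen=True)
class SpectralConfig:
    """Knobs of the self-tuning clustering stage.

    ``c_max`` is the largest candidate cluster count; ``k_neighbors`` the
    local-scaling neighbor index; the remaining fields control the rotation
    gradient descent and the cost tie tolerance (a candidate within
    ``tie_tol * N`` of the minimal cost counts as minimal — the tolerance only
    absorbs floating-point noise in genuinely tied costs; anything larger lets
    the near-flat cost region above the true cluster count drag the selection
    to ``c_max`` on cleanly separated data).
    """

    c_max: int = 10
    k_neighbors: int = 7
    step: float = 0.1
    max_sweeps: int = 200
    tol: float = 1e-6
    tie_tol: float = 1e-6


@dataclass
class RotationResult:
    """Outcome of aligning an eigenvector basis with the canonical axes."""

    z: np.ndarray               # rotated eigenvectors, N x c
    rotation: np.ndarray        # recovered orthogonal rotation, c x c
    row_maxima: np.ndarray      # per-row max_j |Z_ij|
    cost: float                 # alignment cost J
    n_clusters: int
    converged: bool = True


@dataclass
class ClusterSolution:
    """Labels, selected cluster count, and the candidate cost curve."""

    labels: np.ndarray
    c_best: int
    costs: dict[int, float] = field(default_factory=dict)
    rotation: RotationResult | None = None
    eigenvalues: np.ndarray | None = None


def local_scales(d: np.ndarray, k: int = 7) -> np.ndarray:
    """Per-point kernel widths: distance to the k-th nearest neighbor.

    Self-distances are excluded; duplicates can give zero scales, which are
    floored at a tiny positive value.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    others = np.sort(d + np.diag(np.full(n, np.inf)), axis=1)
    return np.maximum(others[:, k - 1], _SCALE_FLOOR)


def affinity(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Locally scaled Gaussian affinity exp(-d_ij^2 / (sigma_i sigma_j)).

    Symmetric with an exactly zero diagonal; entries in [0, 1].
    """
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("scales must be positive")
    s = np.exp(-(d ** 2) / np.outer(sigma, sigma))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    return s


def normalized_laplacian(s: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian La = D^{-1/2} S D^{-1/2}.

    The largest eigenvalue is 1 (Perron pair D^{1/2} 1); an isolated vertex
    (zero degree) is an error.
    """
    s = np.asarray(s, dtype=float)
    deg = s.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("graph has an isolated vertex (zero degree)")
    inv_sqrt = 1.0 / np.sqrt(deg)
    la = s * np.outer(inv_sqrt, inv_sqrt)
    return 0.5 * (la + la.T)


def top_eigenvectors(la: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-c eigenpairs of a symmetric matrix, eigenvalues descending.

    Eigenvector signs are canonicalized (largest-magnitude entry positive)
    so results are reproducible across eigensolver conventions.
    """
    w, u = eigh(la)
    order = np.argsort(w)[::-1]
    w, u = w[order[:c]], u[:, order[:c]]
    for j in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, j])), j] < 0:
            u[:, j] = -u[:, j]
    return w, u


# --- rotation alignment --------------------------------------------------------------

def _givens_pairs(c: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(c - 1) for j in range(i + 1, c)]


def _givens(c: int, i: int, j: int, theta: float) -> np.ndarray:
    g = np.eye(c)
    cs, sn = math.cos(theta), math.sin(theta)
    g[i, i] = cs
    g[j, j] = cs
    g[i, j] = -sn
    g[j, i] = sn
    return g


def _dgivens(c: int, i: int, j: int, theta: float) -> np.ndarray:
    g = np.zeros((c, c))
    cs, sn = math.cos(theta), math.sin(theta)
    g[i, i] = -sn
    g[j, j] = -sn
    g[i, j] = -cs
    g[j, i] = cs
    return g


def _rotation(theta: np.ndarray, pairs, c: int) -> np.ndarray:
    r = np.eye(c)
    for (i, j), t in zip(pairs, theta):
        r = r @ _givens(c, i, j, t)
    return r


def _cost(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Alignment cost: every row contributes rowsum/max >= 1 (an exactly zero
    row — a point invisible to the chosen eigenvectors — counts as 1, its
    minimum), so N <= J <= N*c holds even on disconnected graphs."""
    z2 = z ** 2
    m2 = z2.max(axis=1)
    rows = z2.sum(axis=1)
    contrib = np.where(m2 > 0.0, rows / np.where(m2 > 0.0, m2, 1.0), 1.0)
    return float(contrib.sum()), m2


def _cost_gradient(z: np.ndarray, dz: np.ndarray) -> float:
    """d/d(theta_k) of the alignment cost, holding each row's argmax fixed."""
    z2 = z ** 2
    arg = np.argmax(z2, axis=1)
    rows = np.arange(len(z))
    m2 = np.maximum(z2[rows, arg], 1e-300)
    dm2 = 2.0 * z[rows, arg] * dz[rows, arg]
    row_sums = z2.sum(axis=1)
    d_row_sums = (2.0 * z * dz).sum(axis=1)
    return float(np.sum(d_row_sums / m2 - row_sums * dm2 / m2 ** 2))


def _greedy_init(x: np.ndarray) -> np.ndarray:
    """Initial rotation from c mutually most-orthogonal rows of X.

    In the near-ideal case X is a one-hot indicator matrix times an unknown
    rotation, so rows belonging to different clusters are orthogonal; the
    orthonormalized (polar) transpose of c such rows maps them near the
    canonical axes.
    """
    n, c = x.shape
    norms = np.linalg.norm(x, axis=1)
    chosen = [int(np.argmax(norms))]
    basis = x[chosen[0]] / max(norms[chosen[0]], 1e-30)
    q = basis[None, :]
    for _ in range(c - 1):
        proj = x @ q.T                       # (N, len(chosen))
        residual = norms ** 2 - (proj ** 2).sum(axis=1)
        residual[chosen] = -np.inf
        nxt = int(np.argmax(residual))
        chosen.append(nxt)
        v = x[nxt] - q.T @ (q @ x[nxt])
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            q = np.vstack([q, v / nv])
        else:                                # degenerate: fall back to identity axis
            q = np.vstack([q, np.eye(c)[len(chosen) - 1]])
    u, _ = polar(x[chosen].T)                # orthonormal factor closest to rows^T
    return u


def align_rotation(
    x: np.ndarray,
    r0: np.ndarray | None = None,
    step: float = 0.1,
    max_sweeps: int = 200,
    tol: float = 1e-6,
) -> RotationResult:
    """Recover the rotation aligning eigenvector columns with canonical axes.

    Minimizes the alignment cost by incremental gradient descent over the
    Givens angles of R = R0 * prod_k G(i_k, j_k, theta_k), starting from
    ``r0`` (default: the greedy orthogonal-rows initialization).  The step is
    halved whenever a proposed update increases the cost; descent stops when a
    full sweep changes the cost by less than ``tol`` (relative).  The returned
    cost never exceeds the cost at the initial rotation.
    """
    x = np.asarray(x, dtype=float)
    n, c = x.shape
    if c == 1:
        z = x.copy()
        j, m2 = _cost(z)
        return RotationResult(z=z, rotation=np.eye(1), row_maxima=np.sqrt(m2),
                              cost=j, n_clusters=1)
    if r0 is None:
        r0 = _greedy_init(x)
    pairs = _givens_pairs(c)
    theta = np.zeros(len(pairs))
    xr = x @ r0
    j_init, _ = _cost(xr)
    # keep whichever of (r0, identity) starts lower
    j_id, _ = _cost(x)
    if j_id < j_init:
        r0, xr, j_init = np.eye(c), x.copy(), j_id
    best_j = j_cur = j_init
    best_theta = theta.copy()
    alpha = step
    converged = False
    for _ in range(max_sweeps):
        j_sweep_start = j_cur
        for k, (i, jj) in enumerate(pairs):
            prefix = _rotation(theta[:k], pairs[:k], c)
            suffix = _rotation(theta[k + 1:], pairs[k + 1:], c)
            g = _givens(c, i, jj, theta[k])
            dg = _dgivens(c, i, jj, theta[k])
            base = xr @ prefix
            z = base @ g @ suffix
            dz = base @ dg @ suffix
            grad = _cost_gradient(z, dz)
            proposal = theta[k] - alpha * grad
            z_new = base @ _givens(c, i, jj, proposal) @ suffix
            j_new, _ = _cost(z_new)
            if j_new <= j_cur:
                theta[k] = proposal
                j_cur = j_new
            else:
                alpha = max(alpha * 0.5, 1e-5)
        if j_cur < best_j:
            best_j = j_cur
            best_theta = theta.copy()
        if abs(j_sweep_start - j_cur) <= tol * max(abs(j_sweep_start), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn("rotation alignment did not converge; returning best so far",
                      RuntimeWarning)
    r = r0 @ _rotation(best_theta, pairs, c)
    z = x @ r
    j, m2 = _cost(z)
    return RotationResult(z=z, rotation=r, row_maxima=np.sqrt(m2), cost=j,
                          n_clusters=c, converged=converged)


def select_and_cluster(la: np.ndarray, config: SpectralConfig | None = None) -> ClusterSolution:
    """Scan candidate cluster counts, align each, and pick the best.

    For c = 2..c_max the top-c eigenvectors are aligned; alignments are warm-
    started from the previous candidate's rotation (embedded block-diagonally)
    as well as the greedy initialization, keeping the cheaper result.  The
    selected count is the largest c whose cost is within ``tie_tol * N`` of
    the minimum; labels are the row-wise argmax of Z^2, compacted so every
    reported cluster is non-empty.
    """
    if config is None:
        config = SpectralConfig()
    la = np.asarray(la, dtype=float)
    n = la.shape[0]
    c_max = min(config.c_max, n - 1)
    if c_max < 2:
        raise ValueError("need at least 3 points to cluster")
    eigenvalues, u = top_eigenvectors(la, c_max)
    costs: dict[int, float] = {}
    rotations: dict[int, RotationResult] = {}
    prev_rot: np.ndarray | None = None
    for c in range(2, c_max + 1):
        x = u[:, :c]
        candidates: list[np.ndarray | None] = [None]
        if prev_rot is not None:
            candidates.append(block_diag(prev_rot, 1.0))
        best: RotationResult | None = None
        for r0 in candidates:
            res = align_rotation(x, r0=r0, step=config.step,
                                 max_sweeps=config.max_sweeps, tol=config.tol)
            if best is None or res.cost < best.cost:
                best = res
        costs[c] = best.cost
        rotations[c] = best
        prev_rot = best.rotation
    j_min = min(costs.values())
    c_best = max(c for c, j in costs.items() if j <= j_min + config.tie_tol * n)
    best = rotations[c_best]
    labels = np.argmax(best.z ** 2, axis=1)
    # compact labels so clusters are consecutively numbered and non-empty
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq)}
    labels = np.array([remap[v] for v in labels])
    if len(uniq) < c_best:
        c_best = len(uniq)
    return ClusterSolution(labels=labels, c_best=c_best, costs=costs,
                           rotation=best, eigenvalues=eigenvalues)


def cluster_distances(d: np.ndarray, config: SpectralConfig | None = None) -> ClusterSolution:
    """Distance matrix -> local scaling -> affinity -> Laplacian -> clustering."""
    if config is None:
        config = SpectralConfig()
    n = d.shape[0]
    k = min(config.k_neighbors, n - 1)
    sigma = local_scales(d, k)
    s = affinity(d, sigma)
    la = normalized_laplacian(s)
    return select_and_cluster(la, config)
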