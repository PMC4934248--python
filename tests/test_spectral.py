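"""Self-tuning spectral clustering tests."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import ortho_group
from sklearn.metrics import adjusted_rand_score

from pirwatch.spectral import (
    SpectralConfig,
    affinity,
    align_rotation,
    cluster_distances,
    local_scales,
    normalized_laplacian,
    select_and_cluster,
    top_eigenvectors,
)


def indicator_matrix(labels, c):
    n = len(labels)
    e = np.zeros((n, c))
    e[np.arange(n), labels] = 1.0
    return e / np.linalg.norm(e, axis=0)


def block_affinity(sizes, rng, strength=0.9, noise=0.01):
    n = sum(sizes)
    s = np.zeros((n, n))
    start = 0
    labels = []
    for b, sz in enumerate(sizes):
        s[start:start + sz, start:start + sz] = strength
        labels += [b] * sz
        start += sz
    s = s + rng.uniform(0, noise, (n, n))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    return s, np.array(labels)


class TestLocalScales:
    def test_collinear_hand_example(self):
        d = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
        np.testing.assert_allclose(local_scales(d, 1), [1.0, 1.0, 2.0])

    def test_duplicates_floored(self):
        d = np.zeros((4, 4))
        assert np.all(local_scales(d, 2) == 1e-12)

    def test_k_max_is_farthest_neighbor(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        d = cdist(pts, pts)
        sigma = local_scales(d, 7)
        np.testing.assert_allclose(sigma, d.max(axis=1))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            local_scales(np.zeros((3, 3)), 3)


class TestAffinity:
    def test_zero_distance_unit_affinity(self):
        d = np.zeros((3, 3))
        s = affinity(d, np.ones(3))
        assert np.all(s[~np.eye(3, dtype=bool)] == 1.0)
        assert np.all(np.diag(s) == 0.0)

    def test_reduces_to_single_scale_kernel(self, rng):
        """Equal local scales sigma recover the global Gaussian kernel
        exp(-d^2 / sigma^2) (single-scale form with 2*sigma'^2 = sigma^2)."""
        pts = rng.normal(0, 1, (6, 2))
        d = cdist(pts, pts)
        sigma = 0.7
        s = affinity(d, np.full(6, sigma))
        expected = np.exp(-d ** 2 / sigma ** 2)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_symmetry(self, rng):
        d = cdist(rng.normal(0, 1, (5, 3)), rng.normal(0, 1, (5, 3)))
        d = 0.5 * (d + d.T)
        s = affinity(d, rng.uniform(0.5, 2.0, 5))
        np.testing.assert_allclose(s, s.T, atol=1e-15)


class TestLaplacian:
    def test_perron_eigenvalue_is_one(self, rng):
        s = rng.uniform(0.05, 1.0, (15, 15))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 0.0)
        la = normalized_laplacian(s)
        w = np.linalg.eigvalsh(la)
        assert w.max() == pytest.approx(1.0, abs=1e-10)

    def test_block_diagonal_multiplicity(self, rng):
        s, _ = block_affinity([6, 5, 7], rng, noise=0.0)
        s[s == 0] = 0.0
        # three disconnected components -> eigenvalue 1 with multiplicity 3
        la = normalized_laplacian(s + 1e-12)  # keep degrees positive
        w = np.sort(np.linalg.eigvalsh(la))[::-1]
        np.testing.assert_allclose(w[:3], 1.0, atol=1e-6)
        assert w[3] < 1 - 1e-3

    def test_isolated_vertex_rejected(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            normalized_laplacian(s)


class TestRotationAlignment:
    def test_indicator_matrix_is_already_aligned(self, rng):
        labels = rng.integers(0, 3, 30)
        labels[:3] = [0, 1, 2]
        x = indicator_matrix(labels, 3)
        res = align_rotation(x)
        assert res.cost == pytest.approx(30.0, rel=1e-9)

    @pytest.mark.parametrize("c", [2, 3, 4, 5, 6])
    def test_recovers_random_rotation(self, c, rng):
        n = 60
        labels = rng.integers(0, c, n)
        labels[:c] = np.arange(c)  # every cluster non-empty
        x = indicator_matrix(labels, c) @ ortho_group.rvs(c, random_state=c)
        res = align_rotation(x)
        assert res.cost <= n * (1 + 1e-3)
        recovered = np.argmax(res.z ** 2, axis=1)
        assert adjusted_rand_score(labels, recovered) == 1.0
        # orthogonality of the recovered rotation
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(c),
                                   atol=1e-8)

    def test_cost_bounds(self, rng):
        for _ in range(10):
            c = int(rng.integers(2, 6))
            n = int(rng.integers(c + 2, 40))
            x = np.linalg.qr(rng.normal(0, 1, (n, c)))[0]
            res = align_rotation(x, max_sweeps=20)
            assert n - 1e-9 <= res.cost <= n * c + 1e-9


class TestSelection:
    def test_three_blocks_selects_three(self, rng):
        s, labels = block_affinity([10, 14, 8], rng)
        sol = select_and_cluster(normalized_laplacian(s), SpectralConfig(c_max=6))
        assert sol.c_best == 3
        assert adjusted_rand_score(labels, sol.labels) == 1.0

    def test_two_gaussian_clouds(self, rng):
        pts = np.vstack([rng.normal(0, 0.3, (15, 2)), rng.normal(5, 0.3, (15, 2))])
        sol = cluster_distances(cdist(pts, pts), SpectralConfig(c_max=6))
        assert sol.c_best == 2
        assert len(np.unique(sol.labels)) == 2

    def test_ties_resolve_to_largest_count(self):
        # the tie rule: among costs equal up to floating-point noise, the
        # largest candidate count wins
        sol_costs = {2: 10.0, 3: 10.0 + 1e-9, 4: 10.0 - 1e-12, 5: 12.0}
        n, tie_tol = 10, 1e-6
        j_min = min(sol_costs.values())
        c_best = max(c for c, j in sol_costs.items() if j <= j_min + tie_tol * n)
        assert c_best == 4

    def test_permutation_equivariance(self, rng):
        s, _ = block_affinity([8, 9, 7], rng)
        la = normalized_laplacian(s)
        sol = select_and_cluster(la, SpectralConfig(c_max=5))
        perm = rng.permutation(len(la))
        la_p = la[np.ix_(perm, perm)]
        sol_p = select_and_cluster(la_p, SpectralConfig(c_max=5))
        assert adjusted_rand_score(sol.labels[perm], sol_p.labels) == 1.0

    def test_every_cluster_non_empty(self, rng):
        s, _ = block_affinity([12, 12], rng, noise=0.05)
        sol = select_and_cluster(normalized_laplacian(s), SpectralConfig(c_max=6))
        counts = np.bincount(sol.labels, minlength=sol.c_best)
        assert np.all(counts > 0)
        assert sol.labels.max() == sol.c_best - 1
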