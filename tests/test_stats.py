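"""Group statistics: cluster permutation, NBS, correlation, effect size
and BIC — exact cases, planted effects, and seed reproducibility."""

import numpy as np
import pytest

from predgeom import stats
from predgeom.stats import (
    bic,
    cluster_permutation_paired,
    cohens_d_paired,
    correlate_bonferroni,
    nbs_paired,
    spatial_adjacency,
    temporal_adjacency,
)


class TestClusterPermutation:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(12, 30))
        with pytest.warns(UserWarning):  # zero-variance differences excluded
            res = cluster_permutation_paired(a, a.copy(), n_perm=200, seed=0)
        assert res.p_values.size == 0  # t = 0 everywhere, no clusters

    def test_planted_contiguous_effect_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 50))
        b = a + rng.normal(scale=0.5, size=a.shape)
        b[:, 20:30] += 1.0  # 1 SD shift over 10 adjacent elements
        res = cluster_permutation_paired(b, a, n_perm=1000, seed=0)
        sig = res.significant(0.01)
        assert sig and any(set(range(20, 30)) <= set(c.tolist()) for c in sig)

    def test_seed_reproducibility_and_label_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 25))
        b = rng.normal(size=(10, 25))
        r1 = cluster_permutation_paired(a, b, n_perm=300, seed=7)
        r2 = cluster_permutation_paired(a, b, n_perm=300, seed=7)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        r3 = cluster_permutation_paired(b, a, n_perm=300, seed=7)
        np.testing.assert_allclose(r3.t_obs, -r1.t_obs)
        np.testing.assert_array_equal(np.sort(r3.p_values), np.sort(r1.p_values))

    def test_spatial_adjacency_clusters_are_connected(self, atlas):
        rng = np.random.default_rng(3)
        adj = spatial_adjacency(atlas.centroids)
        a = rng.normal(size=(10, 72))
        b = a + rng.normal(scale=1.0, size=a.shape)
        res = cluster_permutation_paired(a, b, adjacency=adj, n_perm=100, seed=0)
        for cl in res.clusters:
            if len(cl) > 1:
                sub = adj[np.ix_(cl, cl)]
                from scipy.sparse.csgraph import connected_components

                assert connected_components(sub, directed=False)[0] == 1

    def test_p_value_bounds(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 10))
        b = a + 5.0 + 0.1 * rng.normal(size=a.shape)
        res = cluster_permutation_paired(a, b, n_perm=100, seed=0)
        assert res.p_values.min() >= 1 / 101


class TestNBS:
    @staticmethod
    def _sym(rng, n_sub, n):
        m = rng.normal(size=(n_sub, n, n))
        return (m + m.transpose(0, 2, 1)) / 2

    def test_identical_conditions(self):
        rng = np.random.default_rng(5)
        a = self._sym(rng, 10, 15)
        with pytest.warns(UserWarning):  # zero-variance differences excluded
            res = nbs_paired(a, a.copy(), n_perm=200, seed=0)
        assert res.p_values.size == 0  # no suprathreshold component

    def test_planted_clique_detected(self):
        rng = np.random.default_rng(6)
        a = self._sym(rng, 20, 20)
        b = a.copy()
        clique = np.arange(8)
        for i in clique:
            for j in clique:
                if i != j:
                    b[:, i, j] += 1.2
        res = nbs_paired(b, a, n_perm=500, seed=0)
        assert res.p_values.min() < 0.05
        comp = res.components[int(np.argmax(res.component_sizes))]
        assert set(np.unique(comp)) >= set(clique.tolist())

    def test_reproducibility(self):
        rng = np.random.default_rng(7)
        a = self._sym(rng, 10, 12)
        b = self._sym(rng, 10, 12)
        r1 = nbs_paired(a, b, n_perm=200, seed=3)
        r2 = nbs_paired(a, b, n_perm=200, seed=3)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)


class TestCorrelationAndEffectSize:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = correlate_bonferroni(x, x, m_tests=3)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_anticorrelation_right_tail(self):
        x = np.arange(10.0)
        r, p = correlate_bonferroni(x, -x, m_tests=1)
        assert r == pytest.approx(-1.0)
        assert p == 1.0

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(8)
        _, p = correlate_bonferroni(rng.normal(size=20), rng.normal(size=20), m_tests=50)
        assert p <= 1.0

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r, p = correlate_bonferroni(np.ones(5), np.arange(5.0))
        assert np.isnan(r)

    def test_right_tail_calibration(self):
        n_reps, hits = 2000, 0
        rng = np.random.default_rng(9)
        for _ in range(n_reps):
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            _, p = correlate_bonferroni(x, y, m_tests=1)
            hits += p < 0.05
        # ~0.05 +- 3 binomial SE
        assert abs(hits / n_reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_cohens_d(self):
        assert cohens_d_paired(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0])) == \
            pytest.approx(2.0)
        with pytest.warns(UserWarning):
            assert np.isnan(cohens_d_paired(np.array([2.0, 2.0]), np.array([1.0, 1.0])))
        rng = np.random.default_rng(10)
        b = rng.normal(size=20_000)
        a = b + 0.5 + rng.normal(size=b.size)  # 0.5 SD shift on unit-sd noise
        assert cohens_d_paired(a, b) == pytest.approx(0.5, abs=0.03)


class TestBIC:
    def test_closed_forms(self):
        assert bic(100.0, 100, 2) == pytest.approx(2 * np.log(100))
        assert bic(50.0, 50, 0) == pytest.approx(0.0)
        n = 200
        assert bic(10.0, n, 3) - bic(5.0, n, 3) == pytest.approx(n * np.log(2))

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            bic(0.0, 10, 2)
        with pytest.raises(ValueError):
            bic(1.0, 2, 2)


class TestAdjacency:
    def test_temporal_chain(self):
        adj = temporal_adjacency(5).toarray()
        assert adj[0, 1] == adj[1, 0] == 1
        assert adj[0, 2] == 0
        assert adj.sum() == 8

    def test_spatial_quantile(self, atlas):
        adj = spatial_adjacency(atlas.centroids, quantile=0.10)
        assert adj.shape == (72, 72)
        dense = adj.toarray()
        np.testing.assert_array_equal(dense, dense.T)
        assert np.all(np.diag(dense) == 0)
        assert 0 < dense.sum() < 72 * 71  # sparse but non-empty
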