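"""Partial information decomposition: the discrete Williams-Beer oracle,
the Gaussian estimator, the accounting identity, and the planted
network structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predgeom import pid
from predgeom.pid import (
    betweenness_centrality,
    node_strength,
    pid_discrete_imin,
    pid_gaussian,
    pid_network,
)


def _xor_pmf():
    p = np.zeros((2, 2, 2))
    for x1 in (0, 1):
        for x2 in (0, 1):
            p[x1, x2, x1 ^ x2] = 0.25
    return p


class TestDiscreteImin:
    def test_xor_is_purely_synergistic(self):
        atoms = pid_discrete_imin(_xor_pmf())
        assert atoms.synergy == pytest.approx(1.0, abs=1e-12)
        assert atoms.redundancy == pytest.approx(0.0, abs=1e-12)
        assert atoms.unique_1 == pytest.approx(0.0, abs=1e-12)
        assert atoms.unique_2 == pytest.approx(0.0, abs=1e-12)
        assert atoms.jmi == pytest.approx(1.0, abs=1e-12)

    def test_copy_is_purely_unique(self):
        # y = x1, x2 independent uniform
        p = np.zeros((2, 2, 2))
        for x1 in (0, 1):
            for x2 in (0, 1):
                p[x1, x2, x1] = 0.25
        atoms = pid_discrete_imin(p)
        assert atoms.unique_1 == pytest.approx(1.0, abs=1e-12)
        assert atoms.redundancy == pytest.approx(0.0, abs=1e-12)
        assert atoms.synergy == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_source_is_purely_redundant(self):
        # x1 = x2 = y uniform binary
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        atoms = pid_discrete_imin(p)
        assert atoms.redundancy == pytest.approx(1.0, abs=1e-12)
        assert atoms.unique_1 == pytest.approx(0.0, abs=1e-12)
        assert atoms.synergy == pytest.approx(0.0, abs=1e-12)

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            pid_discrete_imin(np.full((2, 2, 2), 0.5))
        with pytest.raises(ValueError):
            pid_discrete_imin(-_xor_pmf())


class TestGaussianPID:
    def test_additive_sources_closed_form(self):
        # y = x1 + x2 + eps: MI_each = 0.2925, JMI = 0.7925, S = 0.5 bits
        rng = np.random.default_rng(0)
        n = 100_000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + x2 + rng.normal(size=n)
        atoms = pid_gaussian(x1, x2, y)
        assert atoms.redundancy == pytest.approx(0.2925, abs=0.01)
        assert atoms.jmi == pytest.approx(0.7925, abs=0.02)
        assert atoms.synergy == pytest.approx(0.5, abs=0.02)
        assert atoms.unique_1 == pytest.approx(0.0, abs=0.01)

    def test_irrelevant_second_source(self):
        rng = np.random.default_rng(1)
        n = 50_000
        x1 = rng.normal(size=n)
        y = x1 + 0.5 * rng.normal(size=n)
        x2 = rng.normal(size=n)
        atoms = pid_gaussian(x1, x2, y)
        mi1 = atoms.redundancy + atoms.unique_1
        assert atoms.redundancy == pytest.approx(0.0, abs=0.01)
        assert atoms.synergy == pytest.approx(0.0, abs=0.02)
        assert mi1 > 0.5  # bulk of the information is unique to x1

    def test_duplicated_source_conditioning_error(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = x + rng.normal(size=1000)
        with pytest.raises(np.linalg.LinAlgError):
            pid_gaussian(x, x, y)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_accounting_identity_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        z = rng.normal(size=n)
        x1 = z + rng.normal(size=n)
        x2 = 0.5 * z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        a = pid_gaussian(x1, x2, y)
        assert a.residual() == pytest.approx(0.0, abs=1e-12)
        b = pid_gaussian(x2, x1, y)
        assert b.redundancy == pytest.approx(a.redundancy, abs=1e-12)
        assert b.synergy == pytest.approx(a.synergy, abs=1e-12)
        assert (b.unique_1, b.unique_2) == pytest.approx((a.unique_2, a.unique_1))
        assert a.synergy >= -1e-6  # JMI >= max single MI for Gaussian data

    def test_discrete_and_gaussian_orderings_agree(self):
        """Rank agreement of discretised I_min and Gaussian redundancy."""
        rng = np.random.default_rng(3)
        n = 50_000
        r_gauss, r_disc = [], []
        for w in (0.2, 0.5, 0.8, 1.2):
            z = rng.normal(size=n)
            x1 = w * z + rng.normal(size=n)
            x2 = w * z + rng.normal(size=n)
            y = z + rng.normal(size=n)
            r_gauss.append(pid_gaussian(x1, x2, y).redundancy)
            # discretise to 8 levels and evaluate the exact I_min
            bins = lambda v: np.clip(
                np.digitize(v, np.quantile(v, np.linspace(0, 1, 9)[1:-1])), 0, 7
            )
            d1, d2, dy = bins(x1), bins(x2), bins(y)
            pmf = np.zeros((8, 8, 8))
            np.add.at(pmf, (d1, d2, dy), 1.0)
            r_disc.append(pid_discrete_imin(pmf / n).redundancy)
        from scipy.stats import spearmanr

        assert spearmanr(r_gauss, r_disc).statistic > 0.9


class TestNetwork:
    def test_planted_synergy_pair_is_matrix_maximum(self, hr_epochs):
        net = pid_network(hr_epochs)
        i, j = np.unravel_index(np.argmax(net.synergy), net.synergy.shape)
        assert {int(i), int(j)} == {10, 46}
        assert net.synergy[10, 46] > net.redundancy[10, 46]

    def test_matrix_invariants(self, hr_epochs):
        net = pid_network(hr_epochs)
        for m in (net.redundancy, net.synergy):
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_array_equal(np.diag(m), 0.0)
        assert net.centrality_synergy.shape == (72,)
        assert net.strength_redundancy.shape == (72,)

    def test_same_signal_pair_tops_redundancy(self):
        """Two channels driven by the same PE-coupled signal dominate the
        redundancy matrix of a small constructed network."""
        from predgeom.synthetic_data import EpochArray

        rng = np.random.default_rng(4)
        n, n_p, n_t = 400, 8, 77
        times = -0.05 + np.arange(n_t) * 0.005
        pe = np.abs(rng.normal(size=n)) + 0.1
        kernel = np.exp(-0.5 * ((times - 0.1) / 0.02) ** 2)
        data = rng.normal(size=(n, n_p, n_t))
        for p in (2, 5):  # same PE-coupled signal in two channels
            data[:, p, :] += 2.0 * pe[:, None] * kernel[None, :]
        pe_meta = np.concatenate([[np.nan], pe[1:]])
        ep = EpochArray(
            data, times, np.zeros(n, dtype=int), np.zeros(n, dtype=int),
            np.ones(n, dtype=int), "high", pe_meta,
        )
        net = pid_network(ep)
        i, j = np.unravel_index(np.argmax(net.redundancy), net.redundancy.shape)
        assert {int(i), int(j)} == {2, 5}


class TestCentrality:
    def test_star_graph(self):
        n = 6
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        cent = betweenness_centrality(adj)
        assert cent[0] == pytest.approx(1.0)
        np.testing.assert_allclose(cent[1:], 0.0)

    def test_path_graph_matches_bruteforce(self):
        # path a-b-c-d-e: centre lies on 4 of the 6 non-trivial pairs
        n = 5
        adj = np.zeros((n, n))
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        cent = betweenness_centrality(adj)
        norm = (n - 1) * (n - 2) / 2
        assert cent[2] == pytest.approx(4 / norm)
        assert cent[1] == pytest.approx(3 / norm)
        assert cent[0] == pytest.approx(0.0)

    def test_complete_graph_all_zero(self):
        adj = 1.0 - np.eye(6)
        np.testing.assert_allclose(betweenness_centrality(adj), 0.0)

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            cent = betweenness_centrality(np.zeros((5, 5)))
        np.testing.assert_array_equal(cent, 0.0)

    def test_node_strength(self):
        adj = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        np.testing.assert_allclose(node_strength(adj), [3.0, 1.0, 2.0])
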