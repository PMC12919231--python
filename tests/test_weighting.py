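"""Hyperedge weighting: spectral oracles, closed forms, baselines."""

import numpy as np
import networkx as nx
import pytest

from hyperfc import (
    IncidenceMatrix,
    SimulationConfig,
    TimeSeriesPanel,
    algebraic_connectivity,
    coefficient_matrix,
    compute_weight_table,
    parse_network,
    simulate_panels,
    subgraph_fc,
    weight_algebraic,
    weight_fn_mean_corr,
    weight_gaussian,
    weight_lasso_l2,
    weight_mean_corr,
)
from hyperfc.panels import ContractError
from hyperfc.weighting import SubgraphFC


def graph_from_adjacency(A):
    g = nx.from_numpy_array(A)
    return g


def single_hyperedge(members, n):
    entries = np.zeros((n, 1), dtype=int)
    entries[members, 0] = 1
    return IncidenceMatrix(entries=entries, centroids=[members[0]])


def make_panel(data, subject_id="s"):
    return TimeSeriesPanel(subject_id=subject_id, data=np.asarray(data, float)).zscore()


class TestSubgraphFC:
    def test_identical_series_give_unit_offdiagonals(self, rng):
        base = rng.standard_normal(50)
        panel = make_panel(np.vstack([base, base, base, rng.standard_normal(50)]))
        g = subgraph_fc(panel, np.array([0, 1, 2]))
        off = g.adjacency[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_anticorrelated_series_absolute_value(self, rng):
        base = rng.standard_normal(50)
        panel = make_panel(np.vstack([base, -base, rng.standard_normal(50)]))
        g = subgraph_fc(panel, np.array([0, 1, 2]))
        assert g.adjacency[0, 1] == pytest.approx(1.0)

    def test_matches_explicit_pearson_formula(self, rng):
        data = rng.standard_normal((5, 60))
        panel = make_panel(data)
        g = subgraph_fc(panel, np.arange(5))
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = panel.data[i], panel.data[j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert g.adjacency[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_laplacian_rows_sum_to_zero_and_psd(self, rng):
        panel = make_panel(rng.standard_normal((6, 40)))
        g = subgraph_fc(panel, np.arange(6))
        assert np.abs(g.laplacian.sum(axis=1)).max() < 1e-12
        assert np.linalg.eigvalsh(g.laplacian).min() > -1e-10

    def test_too_few_members_rejected(self, random_panel):
        with pytest.raises(ContractError):
            subgraph_fc(random_panel, np.array([0, 1]))


def fc_from_adjacency(A):
    """Wrap a raw adjacency matrix as a SubgraphFC for spectral tests."""
    return SubgraphFC(member_indices=np.arange(A.shape[0]), adjacency=np.asarray(A, float))


class TestAlgebraicConnectivity:
    def test_complete_graph_equals_n(self):
        A = np.ones((4, 4)) - np.eye(4)
        assert algebraic_connectivity(fc_from_adjacency(A)) == pytest.approx(4.0)

    def test_path_graph_p3(self):
        # Laplacian spectrum of P3 is {0, 1, 3}
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert algebraic_connectivity(fc_from_adjacency(A)) == pytest.approx(1.0)

    def test_disconnected_graph_is_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        assert algebraic_connectivity(fc_from_adjacency(A)) == 0.0

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        """500 random weighted graphs, k in [3, 7], agreement to 1e-8."""
        for _ in range(500):
            k = int(rng.integers(3, 8))
            W = rng.uniform(0, 1, size=(k, k))
            A = (W + W.T) / 2
            np.fill_diagonal(A, 0.0)
            L = np.diag(A.sum(axis=1)) - A
            expected = np.sort(np.linalg.eigvalsh(L))[1]
            got = algebraic_connectivity(fc_from_adjacency(A))
            assert got == pytest.approx(max(expected, 0.0), abs=1e-8)

    def test_matches_networkx(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 8))
            W = rng.uniform(0.05, 1, size=(k, k))
            A = (W + W.T) / 2
            np.fill_diagonal(A, 0.0)
            expected = nx.algebraic_connectivity(graph_from_adjacency(A), method="tracemin_lu")
            got = algebraic_connectivity(fc_from_adjacency(A))
            assert got == pytest.approx(expected, abs=1e-7)

    def test_scale_bound_zero_to_k(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 8))
            W = rng.uniform(0, 1, size=(k, k))
            A = (W + W.T) / 2
            np.fill_diagonal(A, 0.0)
            a = algebraic_connectivity(fc_from_adjacency(A))
            assert 0.0 <= a <= k + 1e-12

    def test_edge_weight_monotonicity(self, rng):
        """Adding weight to one edge never decreases the Fiedler value."""
        for _ in range(100):
            k = int(rng.integers(3, 7))
            W = rng.uniform(0.1, 0.8, size=(k, k))
            A = (W + W.T) / 2
            np.fill_diagonal(A, 0.0)
            base = algebraic_connectivity(fc_from_adjacency(A))
            i, j = rng.choice(k, size=2, replace=False)
            A2 = A.copy()
            A2[i, j] = A2[j, i] = min(1.0, A2[i, j] + rng.uniform(0, 0.2))
            assert algebraic_connectivity(fc_from_adjacency(A2)) >= base - 1e-10

    def test_single_node_rejected(self):
        with pytest.raises(ContractError):
            algebraic_connectivity(fc_from_adjacency(np.zeros((1, 1))))


class TestWeightAlgebraic:
    def test_identical_triple_is_complete_k3(self, rng):
        base = rng.standard_normal(60)
        data = np.vstack([base, base, base, rng.standard_normal(60)])
        panel = make_panel(data)
        H = single_hyperedge([0, 1, 2], 4)
        w = weight_algebraic(panel, H)
        assert w[0] == pytest.approx(3.0, abs=1e-10)

    def test_matches_dense_eig_on_synthetic_hyperedges(self, rng):
        """Latent-factor hyperedges: package value equals the oracle to 1e-8."""
        H = single_hyperedge([0, 1, 2, 3], 5)
        for _ in range(100):
            rho = rng.uniform(0.2, 0.95)
            f = rng.standard_normal(80)
            data = np.vstack(
                [rho * f + np.sqrt(1 - rho**2) * rng.standard_normal(80) for _ in range(4)]
                + [rng.standard_normal(80)]
            )
            panel = make_panel(data)
            got = weight_algebraic(panel, H)[0]
            A = np.abs(np.corrcoef(panel.data[:4]))
            np.fill_diagonal(A, 0.0)
            L = np.diag(A.sum(axis=1)) - A
            expected = np.sort(np.linalg.eigvalsh(L))[1]
            assert got == pytest.approx(expected, abs=1e-8)

    def test_coupling_monotonicity(self):
        """Mean weight over 200 subjects strictly increases with coupling."""
        means = []
        for rho in (0.2, 0.4, 0.6, 0.8):
            cfg = SimulationConfig(
                n_regions=5,
                n_timepoints=96,
                n_subjects_per_group={"HC": 200},
                planted_hyperedges=[[0, 1, 2, 3]],
                coupling=rho,
                noise_sd=1.0,
                seed=99,
            )
            panels, _, _ = simulate_panels(cfg)
            H = single_hyperedge([0, 1, 2, 3], 5)
            means.append(np.mean([weight_algebraic(p, H)[0] for p in panels]))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_permutation_invariance(self, rng):
        data = rng.standard_normal((6, 50))
        panel = make_panel(data)
        a = weight_algebraic(panel, single_hyperedge([1, 3, 4], 6))[0]
        b = weight_algebraic(panel, single_hyperedge([4, 1, 3], 6))[0]
        assert a == pytest.approx(b, abs=1e-12)


class TestWeightGaussian:
    def test_identical_members_weight_one(self, rng):
        base = rng.standard_normal(40)
        panel = make_panel(np.vstack([base, base, base, rng.standard_normal(40)]))
        w = weight_gaussian(panel, single_hyperedge([0, 1, 2], 4))
        assert w[0] == pytest.approx(1.0)

    def test_kernel_value_at_median_distance(self, rng):
        """All pairs at the median distance give exp(-1/2) each."""
        data = rng.standard_normal((4, 60))
        panel = make_panel(data)
        H = single_hyperedge([0, 1, 2], 4)
        w = weight_gaussian(panel, H)
        from scipy.spatial.distance import pdist

        d = pdist(panel.data[[0, 1, 2]])
        sigma = np.median(d)
        expected = np.mean(np.exp(-(d**2) / (2 * sigma**2)))
        assert w[0] == pytest.approx(expected, abs=1e-12)
        # at the median distance itself the kernel is exactly exp(-1/2)
        assert np.exp(-(sigma**2) / (2 * sigma**2)) == pytest.approx(np.exp(-0.5))

    def test_weights_in_unit_interval(self, rng):
        panel = make_panel(rng.standard_normal((8, 40)))
        H = single_hyperedge([0, 2, 4, 6], 8)
        w = weight_gaussian(panel, H)
        assert 0.0 < w[0] <= 1.0


class TestWeightMeanCorr:
    def test_identical_members_give_one(self, rng):
        base = rng.standard_normal(40)
        panel = make_panel(np.vstack([base, base, base, rng.standard_normal(40)]))
        w = weight_mean_corr(panel, single_hyperedge([0, 1, 2], 4))
        assert w[0] == pytest.approx(1.0)

    def test_matches_pair_loop_oracle(self, rng):
        data = rng.standard_normal((6, 50))
        panel = make_panel(data)
        members = [1, 2, 4, 5]
        w = weight_mean_corr(panel, single_hyperedge(members, 6))[0]
        rs = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rs.append(np.corrcoef(panel.data[members[i]], panel.data[members[j]])[0, 1])
        assert w == pytest.approx(np.mean(rs), abs=1e-12)

    def test_mean_is_signed(self, rng):
        base = rng.standard_normal(60)
        noise = rng.standard_normal(60)
        panel = make_panel(np.vstack([base, -base, noise]))
        w = weight_mean_corr(panel, single_hyperedge([0, 1, 2], 3))[0]
        assert w < 0.5  # the -1 pair drags the signed mean down


class TestWeightLassoL2:
    def test_hand_computed_squared_norm(self, rng):
        panel = make_panel(rng.standard_normal((4, 40)))
        A = coefficient_matrix(panel, lam=0.05)
        A.entries[:] = 0.0
        A.entries[0, 1] = 0.3
        A.entries[0, 2] = 0.4
        A.entries[0, 3] = 9.9  # not a member; must be ignored
        H = single_hyperedge([0, 1, 2], 4)
        w = weight_lasso_l2(A, H)
        assert w[0] == pytest.approx(0.25)

    def test_zero_coefficients_zero_weight(self, rng):
        panel = make_panel(rng.standard_normal((4, 40)))
        A = coefficient_matrix(panel, lam=1e3)
        w = weight_lasso_l2(A, single_hyperedge([0, 1, 2], 4))
        assert w[0] == 0.0

    def test_matches_sum_loop_on_random_fits(self, planted_study):
        _, panels, _ = planted_study
        panel = panels[0]
        A = coefficient_matrix(panel, lam=0.05)
        H = single_hyperedge([0, 1, 2, 3, 4], 20)
        w = weight_lasso_l2(A, H)[0]
        expected = sum(A.entries[0, j] ** 2 for j in [1, 2, 3, 4])
        assert w == pytest.approx(expected, abs=1e-14)

    def test_missing_matrix_rejected(self):
        with pytest.raises(ContractError):
            weight_lasso_l2(None, single_hyperedge([0, 1, 2], 4))


class TestFunctionalNetworks:
    @pytest.mark.parametrize(
        "label,network",
        [
            ("LH Vis 1", "Vis"),
            ("RH SomMot 1", "SomMot"),
            ("7Networks_LH_Default_pCunPCC_1", "Default"),
            ("RH SalVentAttn 3", "SalVentAttn"),
        ],
    )
    def test_label_parsing(self, label, network):
        assert parse_network(label) == network

    def test_unparseable_label_rejected(self):
        with pytest.raises(ContractError):
            parse_network("region_42")

    def test_seven_networks_for_full_label_set(self, rng):
        from hyperfc.simulate import default_region_labels

        labels = default_region_labels(28)  # 2 per network per hemisphere
        panel = TimeSeriesPanel(
            subject_id="s", data=rng.standard_normal((28, 40)), region_labels=labels
        ).zscore()
        weights = weight_fn_mean_corr(panel)
        assert len(weights) == 7
        assert set(weights.index) == {
            "Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default",
        }

    def test_identical_series_within_network_weight_one(self, rng):
        base = rng.standard_normal(40)
        data = np.vstack([base, base, rng.standard_normal((2, 40))])
        labels = ["LH Vis 1", "LH Vis 2", "LH SomMot 1", "LH SomMot 2"]
        panel = TimeSeriesPanel(subject_id="s", data=data, region_labels=labels).zscore()
        weights = weight_fn_mean_corr(panel)
        assert weights["Vis"] == pytest.approx(1.0)

    def test_single_region_network_rejected(self, rng):
        labels = ["LH Vis 1", "LH SomMot 1", "LH SomMot 2"]
        panel = TimeSeriesPanel(
            subject_id="s", data=rng.standard_normal((3, 40)), region_labels=labels
        ).zscore()
        with pytest.raises(ContractError, match="fewer than 2"):
            weight_fn_mean_corr(panel)


class TestWeightTable:
    def test_compute_table_shapes_and_groups(self, planted_study):
        _, panels, _ = planted_study
        from hyperfc import build_backbone

        H = build_backbone(panels[:10], lam=0.05)
        groups = {p.subject_id: ("A" if i % 2 else "B") for i, p in enumerate(panels[:6])}
        for method in ("algebraic", "gaussian", "mean_corr"):
            table = compute_weight_table(panels[:6], H, method, groups)
            assert table.values.shape == (6, H.n_hyperedges)
            assert not table.values.isna().any().any()
        table = compute_weight_table(panels[:6], H, "lasso_l2", groups, lam=0.05)
        assert np.all(table.values.to_numpy() >= 0)
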