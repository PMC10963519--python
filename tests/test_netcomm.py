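import numpy as np
import pytest

from _oracles import brute_force_betweenness, random_connected_weights
from sheetnet import gen_correlated_ensemble
from sheetnet.netcomm import (
    betweenness_centrality,
    build_network,
    degree_centrality,
    generalized_correlation,
    knee_threshold,
    network_from_weights,
    shared_knee_threshold,
    top_edges,
)
from sheetnet.traj_io import select_nodes


def _gaussian_pair(rho, n, seed):
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    z = rng.standard_normal((n, 3, 2))
    xy = np.einsum("fak,nk->fna", z, chol)
    return xy[:, 0, :], xy[:, 1, :]


class TestGeneralizedCorrelation:
    def test_independent_series_map_to_zero(self):
        x, y = _gaussian_pair(0.0, 5000, seed=1)
        assert generalized_correlation(x, y) <= 0.1

    def test_identical_series_saturate(self):
        x, _ = _gaussian_pair(0.0, 2000, seed=2)
        assert generalized_correlation(x, x.copy()) >= 0.95

    @pytest.mark.parametrize("rho", [0.4, 0.8])
    def test_gaussian_identity_recovers_rho(self, rho):
        # for Gaussians I = -(3/2) ln(1 - rho^2), hence r = rho exactly
        x, y = _gaussian_pair(rho, 5000, seed=3)
        assert generalized_correlation(x, y) == pytest.approx(rho, abs=0.05)

    def test_zero_variance_series_warns_and_returns_zero(self):
        x, _ = _gaussian_pair(0.0, 500, seed=4)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert generalized_correlation(x, np.zeros_like(x)) == 0.0

    def test_too_few_frames_rejected(self):
        x, y = _gaussian_pair(0.0, 50, seed=5)
        with pytest.raises(ValueError, match="frames"):
            generalized_correlation(x, y)


class TestDegree:
    def test_triangle_equal_weights(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        dg = degree_centrality(network_from_weights(w))
        assert np.allclose(dg.to_numpy(), 1.0)

    def test_single_edge_and_isolated_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        dg = degree_centrality(network_from_weights(w)).to_numpy()
        assert dg[0] == dg[1] == pytest.approx(0.7)
        assert dg[2] == 0.0

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(6)
        w = random_connected_weights(rng, 10)
        dg = degree_centrality(network_from_weights(w)).to_numpy()
        assert np.allclose(dg, w.sum(axis=1))


class TestBetweenness:
    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        rep = betweenness_centrality(network_from_weights(w))
        assert rep.node_betweenness.to_numpy() == pytest.approx([0.0, 1.0, 0.0])

    def test_equal_weight_triangle(self):
        w = np.full((3, 3), 0.6)
        np.fill_diagonal(w, 0.0)
        rep = betweenness_centrality(network_from_weights(w))
        assert np.allclose(rep.node_betweenness.to_numpy(), 0.0)
        assert all(
            v == pytest.approx(1 / 3) for v in rep.edge_betweenness.values()
        )

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(3, 7))
            w = random_connected_weights(rng, n)
            rep = betweenness_centrality(network_from_weights(w))
            node_ref, edge_ref = brute_force_betweenness(w)
            assert np.allclose(rep.node_betweenness.to_numpy(), node_ref, atol=1e-12)
            for e, v in edge_ref.items():
                assert rep.edge_betweenness[e] == pytest.approx(v, abs=1e-12)

    def test_tied_paths_split_counts(self):
        # square with equal weights: two optimal routes per diagonal pair
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 0.5
        rep = betweenness_centrality(network_from_weights(w))
        node_ref, edge_ref = brute_force_betweenness(w)
        assert np.allclose(rep.node_betweenness.to_numpy(), node_ref)
        for e, v in edge_ref.items():
            assert rep.edge_betweenness[e] == pytest.approx(v)

    def test_agrees_with_networkx_on_distinct_weights(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        w = random_connected_weights(rng, 8)
        net = network_from_weights(w)
        rep = betweenness_centrality(net)
        g = nx.Graph()
        g.add_nodes_from(range(8))
        for i, j in net.edges():
            g.add_edge(i, j, length=-np.log(w[i, j]))
        ref = nx.betweenness_centrality(g, weight="length", normalized=True)
        for i in range(8):
            assert rep.node_betweenness.iloc[i] == pytest.approx(ref[i], abs=1e-9)

    def test_uniform_weight_scaling_preserves_direct_edge_betweenness(self):
        # complete graph with near-equal weights: every optimal path is the
        # direct edge, so a global weight rescale cannot change betweenness
        rng = np.random.default_rng(9)
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                # narrow range: the worst direct edge (-ln 0.90 = 0.105)
                # still beats the best two-hop route (2 x -ln 0.92 = 0.167)
                w[i, j] = w[j, i] = rng.uniform(0.90, 0.92)
        rep1 = betweenness_centrality(network_from_weights(w))
        rep2 = betweenness_centrality(network_from_weights(0.5 * w))
        assert np.allclose(
            rep1.node_betweenness.to_numpy(), rep2.node_betweenness.to_numpy()
        )
        for e in rep1.edge_betweenness:
            assert rep1.edge_betweenness[e] == pytest.approx(rep2.edge_betweenness[e])


class TestBuildNetwork:
    def test_edges_weights_and_exclusions_on_sheet(self, small_sheet):
        system, truth = small_sheet
        nodes = select_nodes(system, exclude_chains=set(truth.restrained_chains))
        net = build_network(system, nodes, min_frames=100)
        ids = nodes.labels
        # block-level edge set equals the ground-truth adjacency among
        # non-restrained blocks
        chain_of = ids["chain"].to_numpy()
        got = set()
        for i, j in net.edges():
            ci, cj = chain_of[i], chain_of[j]
            if ci != cj:
                got.add(tuple(sorted((ci, cj))))
        restr = set(truth.restrained_chains)
        expect = {
            tuple(sorted((truth.block_chains[a], truth.block_chains[b])))
            for a, b in truth.contact_pairs
            if truth.block_chains[a] not in restr and truth.block_chains[b] not in restr
        }
        assert got == expect
        # no node references a restrained chain
        assert not (set(chain_of) & restr)
        # symmetry and gating invariants
        assert np.allclose(net.weights, net.weights.T)
        assert ((net.weights > 0) <= net.adjacency).all()

    def test_empty_network_rejected(self):
        system = gen_correlated_ensemble(np.eye(3), 150, seed=1, spacing=5.0)
        nodes = select_nodes(system)
        with pytest.raises(ValueError, match="no edges"):
            build_network(system, nodes, min_frames=100)


class TestKnee:
    def test_elbow_curve_max_distance_point(self):
        # chord runs from (0, 10) to (5, 0.8); the point (3, 1) lies
        # farthest from it (|cross| = 17.4 vs 13.4 for (2, 9))
        vals = [10.0, 9.5, 9.0, 1.0, 0.9, 0.8]
        assert knee_threshold(vals) == 1.0

    def test_linear_curve_warns_and_returns_last(self):
        with pytest.warns(UserWarning, match="linear"):
            assert knee_threshold([5.0, 4.0, 3.0, 2.0, 1.0]) == 1.0

    def test_shared_threshold_is_minimum_knee(self):
        lists = [
            [10.0, 9.0, 5.0, 0.4, 0.3],
            [8.0, 7.0, 3.0, 0.2, 0.1],
            [9.0, 8.0, 4.0, 0.3, 0.2],
        ]
        assert shared_knee_threshold(lists) == min(knee_threshold(l) for l in lists)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            knee_threshold([2.0, 1.0])


class TestTopEdges:
    def _report(self):
        w = np.zeros((4, 4))
        for i, j, v in [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7)]:
            w[i, j] = w[j, i] = v
        net = network_from_weights(w, chains=["A", "A", "B", "B"])
        return net, betweenness_centrality(net)

    def test_threshold_above_max_empty(self):
        net, rep = self._report()
        assert top_edges(net, rep, threshold=10.0).empty

    def test_zero_threshold_returns_all_edges(self):
        net, rep = self._report()
        te = top_edges(net, rep, threshold=-1.0)
        assert len(te) == len(net.edges())

    def test_interface_annotation(self):
        net, rep = self._report()
        te = top_edges(net, rep, threshold=-1.0)
        cross = te[te["cross_interface"]]
        assert set(cross["interface"]) == {"A|B"}
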