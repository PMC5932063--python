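"""Generalized correlations, weighted residue graphs, and pathways."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from allokit import network as net
from allokit.dynamics import TrajectoryEnsemble
from allokit.structure import ContactMap


def _traj_from_cov(cov3n, n_frames, seed):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov3n + 1e-12 * np.eye(cov3n.shape[0]))
    flat = rng.standard_normal((n_frames, cov3n.shape[0])) @ L.T
    return TrajectoryEnsemble(frames=flat.reshape(n_frames, -1, 3),
                              source="synthetic")


class TestGeneralizedCorrelation:
    def test_independent_residues_near_zero(self):
        traj = _traj_from_cov(np.eye(9), 10_000, 0)
        rmi = net.generalized_correlation([traj], superpose=False)
        off = rmi.stack[0][~np.eye(3, dtype=bool)]
        assert np.nanmax(off) < 0.1

    def test_copied_residue_saturates_at_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((500, 1, 3))
        frames = np.concatenate([x, x, rng.standard_normal((500, 1, 3))],
                                axis=1)
        traj = TrajectoryEnsemble(frames=frames, source="synthetic")
        rmi = net.generalized_correlation([traj], superpose=False)
        assert rmi.stack[0][0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_pair_closed_form(self):
        """Jointly Gaussian coordinates with known correlation rho give
        R_MI = rho exactly in the d-dimensional closed form."""
        rho = 0.8
        mi = -0.5 * math.log(1 - rho ** 2)
        assert net.rmi_from_mi(mi, 1) == pytest.approx(rho, rel=1e-12)
        # estimator route: 3-d fluctuations correlated per coordinate
        n_frames = 60_000
        rng = np.random.default_rng(2)
        a = rng.standard_normal((n_frames, 3))
        b = rho * a + math.sqrt(1 - rho ** 2) * \
            rng.standard_normal((n_frames, 3))
        frames = np.stack([a, b], axis=1)
        traj = TrajectoryEnsemble(frames=frames, source="synthetic")
        rmi = net.generalized_correlation([traj], superpose=False)
        expect = math.sqrt(1 - (1 - rho ** 2))  # d=3, I = -3/2 ln(1-rho^2)
        assert rmi.stack[0][0, 1] == pytest.approx(rho, abs=0.01)

    def test_pmi_augmentation_adds_correlation(self):
        traj = _traj_from_cov(np.eye(9), 2000, 3)
        base = net.generalized_correlation([traj], superpose=False)
        pmi = np.array([5.0, 5.0, 0.0])
        aug = net.generalized_correlation([traj], pmi=pmi, superpose=False)
        assert aug.with_coevolution
        assert aug.stack[0][0, 1] > base.stack[0][0, 1]
        # residues without coevolution signal are unaffected upward only
        assert aug.stack[0][0, 2] == pytest.approx(base.stack[0][0, 2],
                                                   abs=0.05)


class TestBuildNetwork:
    def _rmi(self, mat):
        return net.GeneralizedCorrelationMatrix(stack=np.asarray([mat]))

    def test_threshold_is_strict(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.5 + 1e-6
        g = net.build_network(self._rmi(m))
        assert not g.has_edge(0, 1)
        assert g.has_edge(1, 2)

    def test_perfect_correlation_weight_zero(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 1.0
        g = net.build_network(self._rmi(m))
        assert g[0][1]["weight"] == pytest.approx(0.0, abs=1e-9)

    def test_weight_is_minus_log(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 0.5 + 1e-9
        g = net.build_network(self._rmi(m))
        assert g[0][1]["weight"] == pytest.approx(math.log(2), rel=1e-6)

    def test_max_over_simulations_rule(self):
        lo = np.eye(2)
        lo[0, 1] = lo[1, 0] = 0.3
        hi = np.eye(2)
        hi[0, 1] = hi[1, 0] = 0.7
        stack = net.GeneralizedCorrelationMatrix(stack=np.stack([lo, hi]))
        g = net.build_network(stack)
        assert g.has_edge(0, 1)
        assert g[0][1]["rmi"] == pytest.approx(0.7)

    def test_contact_gating(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 0.9
        contacts = ContactMap(n_residues=2,
                              contacts=np.zeros((2, 2), dtype=bool),
                              cutoff=5.0, metric="heavy-atom-min")
        g = net.build_network(self._rmi(m), contacts=contacts)
        assert not g.has_edge(0, 1)

    def test_raising_threshold_never_adds_edges_or_shortens_paths(self):
        rng = np.random.default_rng(4)
        m = np.eye(8)
        iu = np.triu_indices(8, 1)
        vals = rng.uniform(0.3, 0.99, iu[0].size)
        m[iu] = vals
        m.T[iu] = vals
        g_lo = net.build_network(self._rmi(m), threshold=0.5)
        g_hi = net.build_network(self._rmi(m), threshold=0.7)
        assert set(g_hi.edges) <= set(g_lo.edges)
        d_lo = net.all_shortest_paths(g_lo).distances
        d_hi = net.all_shortest_paths(g_hi).distances
        assert (d_hi >= d_lo - 1e-12).all()


class TestShortestPaths:
    def test_triangle_goes_through_middle(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(1, 2, weight=1.0)
        g.add_edge(0, 2, weight=3.0)
        sp = net.all_shortest_paths(g)
        assert sp.distances[0, 2] == pytest.approx(2.0)
        assert sp.path(0, 2) == [0, 1, 2]

    def test_disconnected_components_infinite(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        sp = net.all_shortest_paths(g)
        assert math.isinf(sp.distances[0, 2])
        assert sp.path(0, 2) is None

    def test_agreement_with_single_source_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            n = int(rng.integers(4, 41))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            sp = net.all_shortest_paths(g)
            dij = dict(nx.all_pairs_dijkstra_path_length(g,
                                                         weight="weight"))
            for i, u in enumerate(sp.node_list):
                for j, v in enumerate(sp.node_list):
                    expect = dij.get(u, {}).get(v, math.inf)
                    assert sp.distances[i, j] == pytest.approx(expect)

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=-1.0)
        with pytest.raises(ValueError):
            net.all_shortest_paths(g)


def brute_force_edge_betweenness(g):
    """Exhaustive shortest-path enumeration with equal tie splitting."""
    counts = {tuple(sorted(e)): 0.0 for e in g.edges}
    nodes = sorted(g.nodes)
    n_pairs = 0
    for a, b in itertools.combinations(nodes, 2):
        try:
            best = nx.shortest_path_length(g, a, b, weight="weight")
        except nx.NetworkXNoPath:
            continue
        n_pairs += 1
        paths = [p for p in nx.all_simple_paths(g, a, b)
                 if abs(sum(g[u][v]["weight"]
                            for u, v in zip(p, p[1:])) - best) < 1e-9]
        for p in paths:
            for u, v in zip(p, p[1:]):
                counts[tuple(sorted((u, v)))] += 1.0 / len(paths)
    total = g.number_of_nodes() * (g.number_of_nodes() - 1) / 2
    return {e: c / total for e, c in counts.items()}


class TestEdgeBetweenness:
    def test_path_graph_matches_enumeration(self):
        g = nx.path_graph(3)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        got = net.edge_betweenness(g)
        want = brute_force_edge_betweenness(g)
        for e, w in want.items():
            assert got[e] == pytest.approx(w)

    def test_barbell_bridge_has_maximum(self):
        g = nx.barbell_graph(4, 0)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        eb = net.edge_betweenness(g)
        bridge = max(eb, key=eb.get)
        assert set(bridge) == {3, 4}

    def test_automorphism_invariance_on_cycle(self):
        g = nx.cycle_graph(6)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        eb = net.edge_betweenness(g)
        assert np.ptp(list(eb.values())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
            got = net.edge_betweenness(g)
            want = brute_force_edge_betweenness(g)
            for e, w in want.items():
                assert got[tuple(sorted(e))] == pytest.approx(w, abs=1e-9)


class TestCommunicationPathways:
    def test_adjacent_pair_single_edge_path(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.7)
        ps = net.communication_pathways(g, [0], [1], k_paths=1)
        (p,) = ps.paths
        assert p.nodes == [0, 1]
        assert p.total_weight == pytest.approx(0.7)

    def test_planted_backbone_carries_all_top_paths(self):
        g = nx.Graph()
        backbone = [0, 1, 2, 3, 4]
        for u, v in zip(backbone, backbone[1:]):
            g.add_edge(u, v, weight=0.05)
        # expensive detours
        for u in range(5, 10):
            g.add_edge(0, u, weight=1.0)
            g.add_edge(u, 4, weight=1.0)
        ps = net.communication_pathways(g, [0], [4], k_paths=3)
        assert set(ps.paths[0].nodes) == set(backbone)
        counts = ps.node_traversal_counts
        for b in backbone[1:-1]:
            assert counts[b] >= 1

    def test_k1_reduces_to_predecessor_path(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(12, 0.4, seed=11)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        sp = net.all_shortest_paths(g)
        ps = net.communication_pathways(g, [0], [5], k_paths=1)
        if ps.paths:
            total = sum(g[u][v]["weight"] for u, v in
                        zip(ps.paths[0].nodes, ps.paths[0].nodes[1:]))
            i0 = sp.node_list.index(0)
            i5 = sp.node_list.index(5)
            assert total == pytest.approx(sp.distances[i0, i5])

    def test_unreachable_reported_not_raised(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        ps = net.communication_pathways(g, [0], [2])
        assert ps.paths == []
        assert (0, 2) in ps.unreachable
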