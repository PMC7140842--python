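import pytest

from netprops.network_io import Network
from netprops.setmetrics import (
    inter_set_distance,
    intra_set_distance,
    set_clustering_coefficient,
    shortest_paths,
)

from tests.conftest import er_network, mapped
from tests.oracles import (
    fill_disconnected,
    floyd_warshall,
    iad_bruteforce,
    ied_bruteforce,
    local_clustering_bruteforce,
)


def oracle_distances(net):
    d, fill = fill_disconnected(floyd_warshall(net.nodes, net.edges))
    return d, fill


class TestSPMatrix:
    def test_path_graph(self, path4):
        sp = shortest_paths(path4)
        assert sp.distance("a", "d") == 3
        assert sp.max_finite_sp == 3
        assert sp.distance("a", "a") == 0

    def test_disconnected_pair_uses_fill(self):
        net = Network.from_edges([("a", "b")], isolated=["c"])
        sp = shortest_paths(net)
        assert sp.max_finite_sp == 1
        assert sp.distance("a", "c") == 1

    def test_no_edges_rejected(self):
        net = Network(nodes=frozenset({"a", "b"}), edges=frozenset())
        with pytest.raises(ValueError):
            shortest_paths(net)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_floyd_warshall(self, seed):
        net = er_network(12, 0.25, seed=seed)
        if net.n_edges == 0:
            pytest.skip("empty draw")
        sp = shortest_paths(net)
        d, fill = oracle_distances(net)
        assert sp.max_finite_sp == fill
        for u in sorted(net.nodes):
            for v in sorted(net.nodes):
                assert sp.distance(u, v) == d[(u, v)]

    def test_symmetry(self, er20):
        sp = shortest_paths(er20)
        nodes = sorted(er20.nodes)
        for u in nodes[:10]:
            for v in nodes[10:]:
                assert sp.distance(u, v) == sp.distance(v, u)


class TestClusteringCoefficient:
    def test_triangle_both_modes(self, triangle):
        m = mapped(triangle, ["a", "b", "c"])
        assert set_clustering_coefficient(triangle, m, "node_average") == pytest.approx(1.0)
        assert set_clustering_coefficient(triangle, m, "induced_subgraph") == pytest.approx(1.0)

    def test_star_center_zero(self, star5):
        m = mapped(star5, ["c"])
        assert set_clustering_coefficient(star5, m) == 0.0

    def test_empty_set_rejected(self, star5):
        m = mapped(star5, ["nothere"])
        with pytest.raises(ValueError):
            set_clustering_coefficient(star5, m)

    def test_matches_triangle_counting_oracle(self):
        net = er_network(15, 0.3, seed=2)
        members = sorted(net.nodes)[:5]
        m = mapped(net, members)
        expect = sum(local_clustering_bruteforce(net.edges, v) for v in members) / 5
        assert set_clustering_coefficient(net, m) == pytest.approx(expect)


class TestIAD:
    def test_triangle_is_one(self, triangle):
        r = intra_set_distance(shortest_paths(triangle), mapped(triangle, ["a", "b", "c"]))
        assert r.iad == pytest.approx(1.0)
        assert r.n_used == 3

    def test_path_endpoints(self, path4):
        r = intra_set_distance(shortest_paths(path4), mapped(path4, ["a", "d"]))
        assert r.iad == pytest.approx(3.0)

    def test_single_gene_undefined(self, path4):
        with pytest.raises(ValueError, match="IAD undefined"):
            intra_set_distance(shortest_paths(path4), mapped(path4, ["a"]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        net = er_network(20, 0.2, seed=seed + 100)
        if net.n_edges == 0:
            pytest.skip("empty draw")
        sp = shortest_paths(net)
        genes = sorted(net.nodes)[seed : seed + 6]
        d, _ = oracle_distances(net)
        r = intra_set_distance(sp, mapped(net, genes))
        assert r.iad == pytest.approx(iad_bruteforce(d, genes))

    def test_clique_iad_is_one(self):
        nodes = [f"v{i}" for i in range(6)]
        net = Network.from_edges([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]])
        r = intra_set_distance(shortest_paths(net), mapped(net, nodes))
        assert r.iad == pytest.approx(1.0)

    def test_relabel_invariance(self):
        net = er_network(14, 0.3, seed=21)
        perm = {n: f"z{i:02d}" for i, n in enumerate(sorted(net.nodes, reverse=True))}
        relabeled = Network.from_edges([(perm[a], perm[b]) for a, b in net.edges])
        genes = sorted(net.nodes)[:5]
        r1 = intra_set_distance(shortest_paths(net), mapped(net, genes))
        r2 = intra_set_distance(shortest_paths(relabeled), mapped(relabeled, [perm[g] for g in genes]))
        assert r1.iad == pytest.approx(r2.iad)

    def test_adding_edge_never_increases_iad(self):
        net = er_network(15, 0.25, seed=31)
        genes = sorted(net.nodes)[:6]
        before = intra_set_distance(shortest_paths(net), mapped(net, genes)).iad
        nodes = sorted(net.nodes)
        missing = next(
            (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :] if (u, v) not in net.edges
        )
        denser = Network.from_edges(list(net.edges) + [missing])
        # guard: only valid when the fill value did not change (connected graph)
        if shortest_paths(net).max_finite_sp == shortest_paths(denser).max_finite_sp:
            after = intra_set_distance(shortest_paths(denser), mapped(denser, genes)).iad
            assert after <= before + 1e-12


class TestIED:
    def test_path_singletons(self, path4):
        sp = shortest_paths(path4)
        r = inter_set_distance(sp, mapped(path4, ["a"], "P"), mapped(path4, ["d"], "Q"))
        assert r.mean_p_to_q == pytest.approx(3.0)
        assert r.mean_q_to_p == pytest.approx(3.0)
        assert r.ied == pytest.approx(6.0)

    def test_self_ied_identity(self):
        # IED(S,S) = 2 (N-1)/N IAD(S): zero diagonal is included in the mean
        for seed in range(4):
            net = er_network(18, 0.25, seed=seed + 50)
            if net.n_edges == 0:
                continue
            sp = shortest_paths(net)
            genes = sorted(net.nodes)[:7]
            m = mapped(net, genes)
            iad = intra_set_distance(sp, m).iad
            ied = inter_set_distance(sp, m, m).ied
            n = len(genes)
            assert ied == pytest.approx(2 * (n - 1) / n * iad)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        net = er_network(20, 0.2, seed=seed + 200)
        if net.n_edges == 0:
            pytest.skip("empty draw")
        sp = shortest_paths(net)
        nodes = sorted(net.nodes)
        p_genes, q_genes = nodes[:5], nodes[8:13]
        d, _ = oracle_distances(net)
        r = inter_set_distance(sp, mapped(net, p_genes, "P"), mapped(net, q_genes, "Q"))
        assert r.ied == pytest.approx(ied_bruteforce(d, p_genes, q_genes))

    def test_symmetry(self, er20):
        sp = shortest_paths(er20)
        nodes = sorted(er20.nodes)
        a, b = mapped(er20, nodes[:6], "A"), mapped(er20, nodes[6:12], "B")
        assert inter_set_distance(sp, a, b).ied == inter_set_distance(sp, b, a).ied

    def test_empty_set_rejected(self, er20):
        sp = shortest_paths(er20)
        with pytest.raises(ValueError):
            inter_set_distance(sp, mapped(er20, ["nope"], "A"), mapped(er20, sorted(er20.nodes)[:3], "B"))

    def test_directional_means_equal_grand_mean(self, er20):
        sp = shortest_paths(er20)
        nodes = sorted(er20.nodes)
        r = inter_set_distance(sp, mapped(er20, nodes[:4], "A"), mapped(er20, nodes[2:9], "B"))
        assert r.mean_p_to_q == pytest.approx(r.mean_q_to_p)
        assert r.ied == pytest.approx(r.mean_p_to_q + r.mean_q_to_p)
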