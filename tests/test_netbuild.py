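"""Shortest-path search and signaling-network assembly vs brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

import moarank as mr
from moarank.io import Interactome, TFTargetMap

from helpers import all_shortest_paths_bruteforce, random_connected_graph


def graph_of(*edges) -> Interactome:
    g = nx.Graph()
    g.add_edges_from(edges)
    return Interactome(graph=g)


class TestMapToInteractome:
    def test_intersection_and_dropped(self):
        net = graph_of(("A", "B"), ("B", "C"))
        mapped, dropped = mr.map_to_interactome({"A", "B", "X"}, net)
        assert mapped == {"A", "B"} and dropped == {"X"}

    def test_empty_input(self):
        net = graph_of(("A", "B"))
        assert mr.map_to_interactome(set(), net) == (set(), set())


class TestShortestPath:
    diamond = graph_of(("a", "b"), ("b", "c"), ("a", "d"), ("d", "c"))

    def test_lexicographic_pick_among_equal_length_paths(self):
        # brute force: exactly two length-2 paths a-b-c and a-d-c; b < d
        oracle = all_shortest_paths_bruteforce(self.diamond.graph, "a", "c")
        assert sorted(oracle) == [["a", "b", "c"], ["a", "d", "c"]]
        assert mr.shortest_path(self.diamond, "a", "c") == [["a", "b", "c"]]

    def test_all_mode_returns_every_shortest_path(self):
        got = mr.shortest_path(self.diamond, "a", "c", tie_break="all")
        assert sorted(got) == [["a", "b", "c"], ["a", "d", "c"]]

    def test_identity_path(self):
        assert mr.shortest_path(self.diamond, "a", "a") == [["a"]]

    def test_disconnected_pair_is_empty_not_error(self):
        net = graph_of(("a", "b"), ("x", "y"))
        assert mr.shortest_path(net, "a", "x") == []

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            mr.shortest_path(self.diamond, "a", "zz")

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(4, 13)))
        net = Interactome(graph=g)
        nodes = sorted(g.nodes)
        src, dst = nodes[0], nodes[-1]
        oracle = sorted(all_shortest_paths_bruteforce(g, src, dst))
        assert sorted(mr.shortest_path(net, src, dst, tie_break="all")) == oracle
        assert mr.shortest_path(net, src, dst) == [min(oracle)]

    def test_adding_edge_never_lengthens_paths(self):
        rng = np.random.default_rng(5)
        g = random_connected_graph(rng, 10)
        net = Interactome(graph=g)
        nodes = sorted(g.nodes)
        non_edges = [e for e in nx.non_edges(g) ]
        lens = {
            (a, b): len(mr.shortest_path(net, a, b)[0])
            for a in nodes for b in nodes if a < b
        }
        g2 = g.copy()
        g2.add_edge(*non_edges[0])
        net2 = Interactome(graph=g2)
        for (a, b), old in lens.items():
            assert len(mr.shortest_path(net2, a, b)[0]) <= old


class TestBuildSignalingNetwork:
    def test_single_chain_with_regulatory_edge(self):
        net = graph_of(("s", "x"), ("x", "t"), ("t", "g"))
        tfmap = {"t": {"g"}}
        out = mr.build_signaling_network(net, {"s"}, {"t"}, {"g"}, tfmap=tfmap)
        assert out.roles("s") == {"source"}
        assert out.roles("x") == {"linker"}
        assert out.roles("t") == {"tf"}
        assert out.roles("g") == {"target"}
        assert out.edges_of_kind("ppi") == {frozenset(("s", "x")), frozenset(("x", "t"))}
        assert out.edges_of_kind("regulatory") == {frozenset(("t", "g"))}

    def test_source_that_is_a_tf_carries_both_roles_without_self_path(self):
        net = graph_of(("s", "x"))
        out = mr.build_signaling_network(net, {"s"}, {"s"}, set())
        assert out.roles("s") == {"source", "tf"}
        assert out.n_edges == 0

    def test_regulatory_edge_inserted_even_without_ppi_edge(self):
        net = graph_of(("s", "t"), ("g", "z"))  # g in interactome, not adjacent to t
        out = mr.build_signaling_network(net, {"s"}, {"t"}, {"g"}, tfmap={"t": {"g"}})
        assert frozenset(("t", "g")) in out.edges_of_kind("regulatory")

    def test_unmapped_regulated_target_excluded_entirely(self):
        net = graph_of(("s", "t"))
        out = mr.build_signaling_network(net, {"s"}, {"t"}, {"ghost"}, tfmap={"t": {"ghost"}})
        assert "ghost" not in out.nodes

    def test_no_connected_pair_is_fatal(self):
        net = graph_of(("s", "x"), ("t", "y"))
        with pytest.raises(ValueError, match="connected"):
            mr.build_signaling_network(net, {"s"}, {"t"}, set())

    @pytest.mark.parametrize("seed", range(15))
    def test_union_of_all_shortest_paths_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_connected_graph(rng, 12)
        net = Interactome(graph=g)
        nodes = sorted(g.nodes)
        sources = set(rng.choice(nodes, size=3, replace=False))
        tfs = set(rng.choice([n for n in nodes if n not in sources], size=2, replace=False))
        out = mr.build_signaling_network(net, sources, tfs, set(), tie_break="all")
        expect_nodes, expect_edges = set(), set()
        for s in sources:
            for t in tfs:
                for p in all_shortest_paths_bruteforce(g, s, t):
                    expect_nodes.update(p)
                    expect_edges.update(frozenset(e) for e in zip(p, p[1:]))
        assert out.nodes == expect_nodes
        assert out.edges_of_kind("ppi") == expect_edges

    def test_every_node_reachable_from_a_source_or_regulatory_target(self, pnet):
        sources = pnet.nodes_with_role("source")
        targets = pnet.nodes_with_role("target")
        ppi = nx.Graph(list(map(tuple, pnet.edges_of_kind("ppi"))))
        for n in pnet.nodes:
            if n in targets:
                continue
            assert any(nx.has_path(ppi, s, n) for s in sources if s in ppi and n in ppi)


class TestComposedBuilders:
    def test_pnet_contains_exactly_planted_backbone(self, universe, pnet):
        truth = universe["truth"]
        assert pnet.nodes == set(truth.pnet_nodes)
        assert pnet.nodes_with_role("tf") == set(truth.activated_tfs)
        assert pnet.nodes_with_role("target") == set(truth.upregulated_targets)
        assert pnet.provenance["label"] == "pnet"

    def test_pnet_fatal_when_no_tf_activated(self, universe):
        expr = universe["expr"]
        flat = mr.ExpressionMatrix(
            values=expr.values * 0 + 1.0, groups=dict(expr.groups)
        )
        with pytest.raises(ValueError, match="activated"):
            mr.build_pnet(flat, universe["interactome"], universe["tfmap"],
                          universe["disease"])

    def test_moanet_provenance_and_planted_overlap(self, universe, pnet):
        truth = universe["truth"]
        inst = universe["instances"]
        iid = inst.instance_ids[-1]  # an instance of the highest-overlap drug
        net = mr.build_moanet(inst, iid, universe["interactome"], universe["tfmap"],
                              universe["catalog"])
        assert net is not None
        assert net.provenance["label"] == "moanet"
        assert net.provenance["instance_id"] == iid
        drug = net.provenance["drug_id"]
        expected = round(truth.overlap_fraction[drug] * len(truth.pnet_nodes))
        assert len(net.nodes & set(truth.pnet_nodes)) == expected

    def test_moanet_skips_flat_instance(self, universe):
        inst = universe["instances"]
        iid = inst.instance_ids[0]
        flat = mr.InstanceProfileSet(
            metadata=inst.metadata.copy(), profiles=inst.profiles * 0.0
        )
        assert mr.build_moanet(flat, iid, universe["interactome"], universe["tfmap"],
                               universe["catalog"]) is None

    def test_lexicographic_build_is_byte_deterministic(self, universe, tmp_path):
        nets = [
            mr.build_pnet(universe["expr"], universe["interactome"], universe["tfmap"],
                          universe["disease"])
            for _ in range(2)
        ]
        paths = []
        for i, n in enumerate(nets):
            p = tmp_path / f"run{i}.tsv"
            mr.write_network(n, p, format="edge_tsv")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
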