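"""Module detection: cliques, cross-network census, permutation null."""

import networkx as nx
import numpy as np
import pytest

from mirsignet.exclusivity import (
    enumerate_candidate_modules,
    exclusivity_census,
    permutation_significance,
    restrict_candidates_to_unique,
    rewire_edge_set,
    select_signature_modules,
    unique_mirnas,
)
from mirsignet.networks import NeoplasmNetwork


def _net(group, edges, pruned=True, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return NeoplasmNetwork(group=group, graph=g, pruned=pruned)


def _clique_edges(nodes):
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


class TestUniqueMirnas:
    def test_single_network_all_unique(self):
        net = _net("G", [("a", "b")], extra_nodes=["c"])
        assert unique_mirnas([net]) == {"G": {"a", "b", "c"}}

    def test_mirna_in_all_networks_unique_nowhere(self):
        nets = [_net(f"G{i}", [("shared", f"x{i}")]) for i in range(3)]
        uniq = unique_mirnas(nets)
        assert all("shared" not in s for s in uniq.values())
        assert uniq["G0"] == {"x0"}

    def test_unique_filter_drops_candidates_with_shared_members(self):
        tri = ["u1", "u2", "shared"]
        nets = [
            _net("G1", _clique_edges(tri)),
            _net("G2", [("shared", "x")]),
        ]
        cands = {"G1": [frozenset(tri)], "G2": []}
        filtered = restrict_candidates_to_unique(cands, nets)
        assert filtered == {"G1": [], "G2": []}

    def test_three_toy_networks(self):
        nets = [
            _net("G1", [("a", "b")]),
            _net("G2", [("b", "c")]),
            _net("G3", [("c", "d")]),
        ]
        assert unique_mirnas(nets) == {"G1": {"a"}, "G2": set(), "G3": {"d"}}


class TestEnumerate:
    def test_triangle_single_module(self):
        net = _net("G", _clique_edges(["a", "b", "c"]))
        assert enumerate_candidate_modules(net) == [frozenset({"a", "b", "c"})]

    def test_k4_reports_only_the_maximal_clique(self):
        net = _net("G", _clique_edges(["a", "b", "c", "d"]))
        assert enumerate_candidate_modules(net) == [frozenset("abcd")]

    def test_two_triangles_sharing_an_edge(self):
        net = _net("G", _clique_edges(["a", "b", "c"]) + _clique_edges(["b", "c", "d"]))
        mods = enumerate_candidate_modules(net)
        assert mods == sorted(
            [frozenset({"a", "b", "c"}), frozenset({"b", "c", "d"})],
            key=lambda c: tuple(sorted(c)),
        )

    def test_matches_brute_force_on_random_graphs(self):
        from itertools import combinations

        rng = np.random.default_rng(2)
        for _ in range(20):
            g = nx.gnp_random_graph(9, 0.45, seed=int(rng.integers(10_000)))
            net = NeoplasmNetwork(group="G", graph=g, pruned=True)
            got = set(enumerate_candidate_modules(net, 3))
            brute = set()
            nodes = list(g.nodes)
            for k in range(3, 10):
                for sub in combinations(nodes, k):
                    if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                        if not any(
                            all(g.has_edge(x, o) for x in sub)
                            for o in nodes
                            if o not in sub
                        ):
                            brute.add(frozenset(sub))
            assert got == brute

    def test_unpruned_network_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_modules(_net("G", [("a", "b")], pruned=False))


class TestCensus:
    def test_clique_in_exactly_one_network(self):
        tri = ["a", "b", "c"]
        nets = [_net("G1", _clique_edges(tri)), _net("G2", [("a", "b"), ("b", "c")])]
        assert exclusivity_census(set(tri), nets) == 1

    def test_membership_without_connectivity_does_not_count(self):
        tri = ["a", "b", "c"]
        nets = [
            _net("G1", _clique_edges(tri)),
            _net("G2", [], extra_nodes=tri),  # members present, no edges
        ]
        assert exclusivity_census(set(tri), nets) == 1

    def test_clique_in_two_of_three(self):
        tri = ["a", "b", "c"]
        nets = [
            _net("G1", _clique_edges(tri)),
            _net("G2", _clique_edges(tri)),
            _net("G3", []),
        ]
        assert exclusivity_census(set(tri), nets) == 2


class TestRewiring:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        edges = list(g.edges)
        rewired = rewire_edge_set(edges, rng)

        def degs(es):
            d = {}
            for a, b in es:
                d[a] = d.get(a, 0) + 1
                d[b] = d.get(b, 0) + 1
            return d

        assert degs(edges) == degs(rewired)
        assert len(rewired) == len(edges)

    def test_rewiring_actually_shuffles(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        rewired = rewire_edge_set(list(g.edges), rng)
        orig = {tuple(sorted(e)) for e in g.edges}
        assert rewired != orig


class TestPermutation:
    def test_never_reappearing_module_gets_floor_p(self):
        tri = ["m1", "m2", "m3"]
        # module nodes absent from the other network: can never reappear
        nets = [
            _net("host", _clique_edges(tri) + [("x", "y")]),
            _net("other", _clique_edges(["p", "q", "r"]) + [("q", "s"), ("r", "s")]),
        ]
        p = permutation_significance(set(tri), nets, n_perm=99, seed=5)
        assert p == pytest.approx(1 / 100)

    def test_shared_dense_module_gets_large_p(self):
        # module of hubs present in both networks; exclusivity is broken only
        # by one missing edge in the second, which rewiring often restores
        tri = ["a", "b", "c"]
        host = _net("host", _clique_edges(tri) + [("a", "x"), ("b", "y")])
        g2 = nx.gnp_random_graph(12, 0.45, seed=2)
        g2 = nx.relabel_nodes(
            g2, {n: {0: "a", 1: "b", 2: "c"}.get(n, f"n{n}") for n in g2.nodes}
        )
        g2.add_edges_from([("a", "b"), ("a", "c")])
        if g2.has_edge("b", "c"):
            g2.remove_edge("b", "c")
        other = NeoplasmNetwork(group="other", graph=g2, pruned=True)
        p = permutation_significance(set(tri), [host, other], n_perm=199, seed=7)
        assert p > 0.15

    def test_identical_seed_identical_p(self):
        tri = ["m1", "m2", "m3"]
        nets = [
            _net("host", _clique_edges(tri)),
            _net("other", _clique_edges(["p", "q", "r"]) + [("p", "s")]),
        ]
        p1 = permutation_significance(set(tri), nets, n_perm=49, seed=3)
        p2 = permutation_significance(set(tri), nets, n_perm=49, seed=3)
        assert p1 == p2

    def test_non_exclusive_module_rejected(self):
        tri = ["a", "b", "c"]
        nets = [_net("G1", _clique_edges(tri)), _net("G2", _clique_edges(tri))]
        with pytest.raises(ValueError):
            permutation_significance(set(tri), nets, n_perm=9, seed=0)


class TestSelect:
    def test_size_two_candidates_rejected_before_scoring(self):
        nets = [_net("G", [("a", "b")]), _net("H", [("x", "y")])]
        mods = select_signature_modules({"G": [frozenset({"a", "b"})]}, nets, n_perm=9)
        assert mods == []

    def test_planted_exclusive_clique_reported_for_its_group_only(self):
        tri = ["m1", "m2", "m3"]
        quad = ["n1", "n2", "n3", "n4"]
        nets = [
            _net("G1", _clique_edges(tri) + [("f1", "f2")]),
            _net("G2", _clique_edges(quad) + [("f3", "f4")]),
        ]
        cands = {
            "G1": enumerate_candidate_modules(nets[0]),
            "G2": enumerate_candidate_modules(nets[1]),
        }
        mods = select_signature_modules(cands, nets, n_perm=99, seed=1)
        assert {(m.group, m.members) for m in mods} == {
            ("G1", frozenset(tri)),
            ("G2", frozenset(quad)),
        }
        for m in mods:
            assert m.host_count == 1 and m.density == 1.0 and m.q_value <= 0.05

    def test_reported_modules_are_cliques_in_exactly_one_network(self):
        tri = ["m1", "m2", "m3"]
        nets = [_net("G1", _clique_edges(tri)), _net("G2", [("a", "b"), ("b", "c")])]
        mods = select_signature_modules(
            {"G1": enumerate_candidate_modules(nets[0]), "G2": []}, nets, n_perm=99
        )
        for m in mods:
            assert exclusivity_census(m.members, nets) == 1

    def test_no_candidates_gives_empty_report(self):
        nets = [_net("G", [("a", "b")])]
        assert select_signature_modules({"G": []}, nets, n_perm=9) == []

    def test_pvalue_estimates_null_reappearance_probability(self):
        # the permutation p-value is a Monte-Carlo estimate of the chance
        # that a module reappears as a clique in a rewired other network;
        # two independent permutation streams must agree within binomial
        # error (the scheme's calibration guarantee)
        template = list(
            nx.relabel_nodes(
                nx.gnp_random_graph(18, 0.35, seed=8), lambda n: f"n{n}"
            ).edges
        )
        rng = np.random.default_rng(12)
        nets = []
        for i in range(3):
            g = nx.Graph()
            g.add_edges_from(rewire_edge_set(template, rng))
            nets.append(NeoplasmNetwork(group=f"G{i}", graph=g, pruned=True))
        checked = 0
        for net in nets:
            for mod in enumerate_candidate_modules(net):
                if exclusivity_census(mod, nets) != 1:
                    continue
                n_perm = 199
                p1 = permutation_significance(mod, nets, n_perm=n_perm, seed=100)
                p2 = permutation_significance(mod, nets, n_perm=n_perm, seed=200)
                se = np.sqrt(max(p1, p2) * (1 - max(p1, p2)) / n_perm)
                assert abs(p1 - p2) <= 4 * se + 2 / n_perm
                checked += 1
                if checked >= 8:
                    return
        assert checked > 0, "expected some exclusive candidate cliques"
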