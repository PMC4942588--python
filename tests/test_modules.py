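"""Seed ranking, module entropy, greedy expansion, refinement."""

import math

import networkx as nx
import numpy as np
import pytest

from dcnet import GeneModule, WeightedNetwork
from dcnet.modules import (binary_entropy, expand_module, jaccard,
                           module_entropy, refine_modules, seed_ranking)
from conftest import make_network


def entropy_oracle(network, members):
    """From-scratch boundary entropy, written independently of the library."""
    total = 0.0
    for v in members:
        deg = sum(network.graph[v][u]["weight"] for u in network.graph.neighbors(v))
        inside = sum(network.graph[v][u]["weight"]
                     for u in network.graph.neighbors(v) if u in members)
        p = inside / deg
        h = 0.0 if p in (0.0, 1.0) else -p * math.log2(p) - (1 - p) * math.log2(1 - p)
        total += h
    return total / len(members)


def clique_with_tail(clique=6, tail=3):
    """Unit-weight clique attached to a short path by one edge at node a0."""
    g = nx.Graph()
    cl = [f"a{i}" for i in range(clique)]
    g.add_edges_from((u, v) for i, u in enumerate(cl) for v in cl[i + 1:])
    tail_nodes = [f"x{i}" for i in range(tail)]
    g.add_edge("a0", tail_nodes[0])
    g.add_edges_from(zip(tail_nodes, tail_nodes[1:]))
    nx.set_edge_attributes(g, 1.0, "weight")
    return WeightedNetwork(g), set(cl)


class TestModuleEntropy:
    def test_whole_component_has_zero_entropy(self):
        net = make_network({("a", "b"): 0.5, ("b", "c"): 0.7, ("c", "a"): 0.2,
                            ("x", "y"): 1.0})
        assert module_entropy(net, {"a", "b", "c"}) == 0.0

    def test_binary_entropy_peak_is_one_bit(self):
        assert binary_entropy(0.5) == 1.0
        assert binary_entropy(0.0) == 0.0 and binary_entropy(1.0) == 0.0

    def test_triangle_with_one_external_edge(self):
        # p_a = 2/3, p_b = p_c = 1 -> H = h(2/3)/3
        net = make_network({("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0,
                            ("a", "z"): 1.0, ("z", "w"): 1.0})
        expected = binary_entropy(2 / 3) / 3
        assert module_entropy(net, {"a", "b", "c"}) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3061, abs=1e-4)

    def test_zero_degree_member_raises(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b", weight=1.0)
        net = WeightedNetwork(g)
        with pytest.raises(ValueError, match="zero total"):
            module_entropy(net, {"lonely"})

    def test_matches_oracle_on_random_graphs(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            nx.set_edge_attributes(
                g, {e: float(rng.uniform(0.1, 1.0)) for e in g.edges}, "weight")
            g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
            if g.number_of_edges() == 0:
                continue
            net = WeightedNetwork(g)
            nodes = [n for n in g.nodes]
            members = set(rng.choice(nodes, size=min(6, len(nodes)), replace=False).tolist())
            assert module_entropy(net, members) == pytest.approx(
                entropy_oracle(net, members), abs=1e-12)


class TestSeedRanking:
    def test_regular_graph_has_flat_scores(self):
        g = nx.cycle_graph(7)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(7)})
        nx.set_edge_attributes(g, 1.0, "weight")
        ranking = seed_ranking(WeightedNetwork(g))
        assert all(abs(z) < 1e-9 for z in ranking.zscores.values())
        assert ranking.seeds == ["n0"]  # lexicographic tie-break

    def test_zscores_standardized(self, rng):
        g = nx.gnm_random_graph(30, 90, seed=7)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(30)})
        nx.set_edge_attributes(g, {e: float(rng.uniform(0.2, 1)) for e in g.edges}, "weight")
        ranking = seed_ranking(WeightedNetwork(g))
        z = np.array(list(ranking.zscores.values()))
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1.0) < 1e-9

    def test_matches_dense_eigenvector_oracle(self, rng):
        for n in (10, 25, 50):
            g = nx.connected_watts_strogatz_graph(n, 4, 0.3, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
            nx.set_edge_attributes(
                g, {e: float(rng.uniform(0.1, 1.0)) for e in g.edges}, "weight")
            net = WeightedNetwork(g)
            ranking = seed_ranking(net)
            nodes = sorted(net.nodes)
            W = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
            dinv = 1 / np.sqrt(W.sum(axis=1))
            A = dinv[:, None] * W * dinv[None, :]
            evals, evecs = np.linalg.eigh(A)
            principal = evecs[:, np.argmax(evals)]
            principal *= np.sign(principal.sum())
            ours = np.array([ranking.scores[v] for v in nodes])
            cos = ours @ principal / (np.linalg.norm(ours) * np.linalg.norm(principal))
            assert cos > 1 - 1e-8

    def test_top_fraction_floor_with_minimum_one(self):
        g = nx.path_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
        nx.set_edge_attributes(g, 1.0, "weight")
        ranking = seed_ranking(WeightedNetwork(g), top_fraction=0.01)
        assert len(ranking.seeds) == 1

    def test_each_large_component_gets_a_seed(self):
        edges = {}
        for comp, size in (("a", 8), ("b", 6)):
            names = [f"{comp}{i}" for i in range(size)]
            for i, u in enumerate(names):
                for v in names[i + 1:]:
                    edges[(u, v)] = 1.0
        net = make_network(edges)
        ranking = seed_ranking(net, top_fraction=0.01)
        comps = {s[0] for s in ranking.seeds}
        assert comps == {"a", "b"}

    def test_permutation_equivariance(self, rng):
        n = 20
        g = nx.gnm_random_graph(n, 50, seed=11)
        weights = {e: float(rng.uniform(0.1, 1.0)) for e in g.edges}
        nx.set_edge_attributes(g, weights, "weight")
        g1 = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
        perm = rng.permutation(n)
        g2 = nx.relabel_nodes(g, {i: f"m{perm[i]:02d}" for i in range(n)})
        r1 = seed_ranking(WeightedNetwork(g1))
        r2 = seed_ranking(WeightedNetwork(g2))
        for i in range(n):
            assert r1.zscores[f"n{i:02d}"] == pytest.approx(
                r2.zscores[f"m{perm[i]:02d}"], abs=1e-8)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            seed_ranking(WeightedNetwork(nx.Graph()))


class TestExpandModule:
    def test_recovers_clique_attached_by_one_edge(self):
        net, clique = clique_with_tail()
        module = expand_module(net, "a3")
        assert module.members == clique

    def test_expansion_from_attachment_node_keeps_clique(self):
        net, clique = clique_with_tail()
        module = expand_module(net, "a0")
        # the closed neighborhood includes the tail gateway, so the pendant
        # tail may be absorbed too; the clique itself is always kept
        assert clique <= module.members

    def test_isolated_seed_degenerates(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("iso")
        module = expand_module(WeightedNetwork(g), "iso")
        assert module.members == {"iso"} and module.entropy == 0.0

    def test_missing_seed_raises(self):
        net, _ = clique_with_tail()
        with pytest.raises(ValueError, match="not in network"):
            expand_module(net, "nope")

    def test_trace_deltas_positive_and_entropy_consistent(self, rng):
        # incremental bookkeeping must equal from-scratch entropy at each step
        for trial in range(5):
            g = nx.gnm_random_graph(25, 60, seed=trial)
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(25)})
            nx.set_edge_attributes(
                g, {e: float(rng.uniform(0.2, 1.0)) for e in g.edges}, "weight")
            g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
            net = WeightedNetwork(g)
            seed = sorted(net.nodes)[0]
            module = expand_module(net, seed)
            assert all(dh > 0 for _, dh in module.trace)
            # replay the trace, recomputing entropy from scratch at each step
            members = {seed} | set(net.graph.neighbors(seed))
            h_prev = entropy_oracle(net, members)
            for gene, dh in module.trace:
                members.add(gene)
                h_new = entropy_oracle(net, members)
                assert h_prev - h_new == pytest.approx(dh, abs=1e-9)
                h_prev = h_new
            assert module.entropy == pytest.approx(h_prev, abs=1e-9)
            assert module.entropy == pytest.approx(
                module_entropy(net, module.members), abs=1e-12)

    def test_greedy_step_is_brute_force_optimal(self, rng):
        net, _ = clique_with_tail(clique=5, tail=4)
        module = expand_module(net, "a2")
        members = {"a2"} | set(net.graph.neighbors("a2"))
        for gene, dh in module.trace:
            h_here = entropy_oracle(net, members)
            candidates = {u for v in members for u in net.graph.neighbors(v)} - members
            best = max(h_here - entropy_oracle(net, members | {u}) for u in candidates)
            assert dh == pytest.approx(best, abs=1e-12)
            members.add(gene)

    def test_max_size_caps_growth(self):
        net, _ = clique_with_tail(clique=8, tail=2)
        module = expand_module(net, "a4", max_size=5)
        assert len(module.members) <= 5


class TestRefineModules:
    def _mk(self, mid, seed, members, entropy):
        return GeneModule(mid, seed, set(members), entropy)

    def test_small_modules_dropped(self):
        net = make_network({("a", "b"): 1.0})
        out = refine_modules(net, [self._mk("", "a", "abcd", 0.1)], min_size=5)
        assert out == []

    def test_merge_at_threshold_boundary(self):
        # Jaccard = 4/8 = 0.5 exactly -> merged
        edges = {}
        genes = list("abcdefgh")
        for i, u in enumerate(genes):
            for v in genes[i + 1:]:
                edges[(u, v)] = 1.0
        net = make_network(edges)
        m1 = self._mk("", "a", "abcdef", 0.2)
        m2 = self._mk("", "c", "cdefgh", 0.3)
        out = refine_modules(net, [m1, m2])
        assert len(out) == 1
        assert out[0].members == set(genes)
        assert out[0].seed == "a"  # canonically earlier (lower entropy) module
        assert out[0].entropy == pytest.approx(module_entropy(net, set(genes)))

    def test_low_overlap_not_merged(self):
        edges = {(u, v): 1.0 for i, u in enumerate("abcdefghij")
                 for v in "abcdefghij"[i + 1:]}
        net = make_network(edges)
        m1 = self._mk("", "a", "abcdef", 0.2)
        m2 = self._mk("", "e", "efghij", 0.3)
        out = refine_modules(net, [m1, m2])
        assert len(out) == 2

    def test_order_independent_and_ids_by_entropy(self):
        edges = {(u, v): 1.0 for i, u in enumerate("abcdefghijkl")
                 for v in "abcdefghijkl"[i + 1:]}
        net = make_network(edges)
        mods = [
            self._mk("", "a", "abcde", 0.5),
            self._mk("", "g", "ghijk", 0.1),
            self._mk("", "b", "bcdef", 0.4),
        ]
        out_fwd = refine_modules(net, mods)
        out_rev = refine_modules(net, mods[::-1])
        assert [(m.module_id, sorted(m.members)) for m in out_fwd] == [
            (m.module_id, sorted(m.members)) for m in out_rev]
        entropies = [m.entropy for m in out_fwd]
        assert entropies == sorted(entropies)
        assert [m.module_id for m in out_fwd] == [f"M{i+1}" for i in range(len(out_fwd))]


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        (set("abcdef"), set("cdefgh"), 0.5),
        (set("abcdef"), set("efghij"), 0.2),
        (set("ab"), set("ab"), 1.0),
        (set(), set(), 0.0),
    ])
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)
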