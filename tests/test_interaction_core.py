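"""Pair subgraphs, non-redundant shortest paths, scores and permutations."""
from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from pathxtalk import (
    CoreParams,
    PairResult,
    empirical_pvalues,
    find_nonredundant_shortest_paths,
    interaction_score,
    neighborhood_subgraph,
    pair_subgraph,
    randomize_pathway,
    run_all_pairs,
    sigmoid_weight,
)
from pathxtalk.interaction_core import _StrengthStrata, node_strengths
from pathxtalk.models import PathRecord
from conftest import random_tiny_instance, weighted_graph


def oracle_paths(sub, pn, pm, l_max):
    """Exhaustive reference: enumerate all simple paths and replay the
    delete-and-repeat procedure, picking the minimum-length path each round
    (lexical tie-break on the node sequence)."""
    g = sub.copy()
    out = []
    while True:
        best = None
        for path in nx.all_simple_paths(g, pn, pm):
            length = sum(g.edges[u, v]["weight"] for u, v in zip(path, path[1:]))
            if length > l_max:
                continue
            key = (length, path)
            if best is None or key < best:
                best = key
        if best is None:
            break
        length, path = best
        out.append((tuple(path[1:-1]), length))
        interior = [
            (u, v) for u, v in zip(path, path[1:]) if pn not in (u, v) and pm not in (u, v)
        ]
        g.remove_edges_from(interior)
    return out


class TestNeighborhoodSubgraph:
    def test_target_within_radius_included(self, chain_graph_factory):
        g = chain_graph_factory(4)  # Pn-x1-x2-x3-x4-Pm: 5 hops
        sub = neighborhood_subgraph(g, "PN", 5)
        assert "PM" in sub

    def test_target_beyond_radius_excluded(self, chain_graph_factory):
        g = chain_graph_factory(5)  # 6 hops
        sub = neighborhood_subgraph(g, "PN", 5)
        assert "PM" not in sub

    def test_radius_zero_is_the_pathway_alone(self, chain_graph_factory):
        g = chain_graph_factory(3)
        sub = neighborhood_subgraph(g, "PN", 0)
        assert set(sub.nodes) == {"PN"}

    def test_missing_pathway_rejected(self, chain_graph_factory):
        with pytest.raises(KeyError):
            neighborhood_subgraph(chain_graph_factory(3), "NOPE", 5)


class TestPairSubgraph:
    def test_third_pathway_xref_excluded(self):
        # only bridge between PN and PM runs through a member of P3
        g = weighted_graph(
            {"PN": {"a"}, "PM": {"b"}, "P3": {"m"}},
            [("a", "m", False), ("m", "b", False)],
            {"a": 6, "m": 6, "b": 6},
        )
        g_pn = neighborhood_subgraph(g, "PN", 5)
        sub = pair_subgraph(g_pn, "PN", "PM")
        assert "m" not in sub
        assert find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9) == []

    def test_overlap_with_distinct_partners_keeps_indirect_route(self):
        # shared protein A with distinct within-pathway partners B and E:
        # PN->B->A->E->PM survives, the direct PN->A->PM does not
        g = weighted_graph(
            {"PN": {"A", "B"}, "PM": {"A", "E"}},
            [("B", "A", False), ("A", "E", False)],
            {"A": 6, "B": 6, "E": 6},
        )
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        assert not sub.has_edge("A", "PM")
        paths = find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9)
        assert paths, "shared protein with distinct partners must still bridge"
        # overlap itself never counts: no path hops straight from A into PM
        assert ("A",) not in [p.nodes for p in paths]
        assert all(p.nodes[-1] == "E" for p in paths)

    def test_shared_chain_without_distinct_partners_yields_nothing(self):
        g = weighted_graph(
            {"PN": {"A", "B"}, "PM": {"A", "B"}},
            [("A", "B", False)],
            {"A": 6, "B": 6},
        )
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        assert find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9) == []

    def test_self_pair_rejected(self, chain_graph_factory):
        g = chain_graph_factory(3)
        with pytest.raises(ValueError):
            pair_subgraph(g, "PN", "PN")


class TestFindNonredundantShortestPaths:
    def test_single_chain_length(self):
        # weights: PN->x = f(Tx), x->y = f(Ty), y->PM = 0
        t_for = lambda w: 3.0 + np.log(1 / w - 1) / 2  # invert the sigmoid
        g = weighted_graph(
            {"PN": {"x"}, "PM": {"y"}},
            [("x", "y", True, "tf_target")],
            {"x": t_for(0.2), "y": t_for(0.3)},
        )
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        paths = find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9)
        assert len(paths) == 1
        assert paths[0].length == pytest.approx(0.5)
        assert paths[0].nodes == ("x", "y")

    def test_two_disjoint_bridges_ascending_order(self):
        t_for = lambda w: 3.0 + np.log(1 / w - 1) / 2
        g = weighted_graph(
            {"PN": {"a", "c"}, "PM": {"b", "d"}},
            [("a", "b", True, "tf_target"), ("c", "d", True, "tf_target")],
            # lengths: f(a)+f(b)=0.4 and f(c)+f(d)=0.7
            {"a": t_for(0.2), "b": t_for(0.2), "c": t_for(0.35), "d": t_for(0.35)},
        )
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        paths = find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9)
        assert [p.nodes for p in paths] == [("a", "b"), ("c", "d")]
        assert [p.length for p in paths] == pytest.approx([0.4, 0.7])

    def test_bridge_beyond_lmax_excluded(self):
        t_for = lambda w: 3.0 + np.log(1 / w - 1) / 2
        g = weighted_graph(
            {"PN": {"x"}, "PM": {"y"}},
            [("x", "y", True, "tf_target")],
            {"x": t_for(0.45), "y": t_for(0.5)},  # length 0.95
        )
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        assert find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9) == []

    def test_interior_edge_disjointness(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g, pc, pn, pm = random_tiny_instance(rng)
            g_pn = neighborhood_subgraph(g, pn, 5)
            if pm not in g_pn:
                continue
            sub = pair_subgraph(g_pn, pn, pm)
            paths = find_nonredundant_shortest_paths(sub, pn, pm, 1.5)
            seen = set()
            for p in paths:
                full = (pn, *p.nodes, pm)
                interior = {
                    (u, v)
                    for u, v in zip(full, full[1:])
                    if pn not in (u, v) and pm not in (u, v)
                }
                assert not (interior & seen)
                seen |= interior

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(30):
            g, pc, pn, pm = random_tiny_instance(rng)
            g_pn = neighborhood_subgraph(g, pn, 5)
            if pm not in g_pn:
                continue
            sub = pair_subgraph(g_pn, pn, pm)
            got = [
                (p.nodes, pytest.approx(p.length))
                for p in find_nonredundant_shortest_paths(sub, pn, pm, 1.5)
            ]
            assert got == oracle_paths(sub, pn, pm, 1.5)
            checked += 1
        assert checked >= 10

    def test_negative_weight_rejected(self, chain_graph_factory):
        g = chain_graph_factory(3, {"x1": 6, "x2": 6, "x3": 6})
        g.edges["x1", "x2"]["weight"] = -0.1
        sub = pair_subgraph(neighborhood_subgraph(g, "PN", 5), "PN", "PM")
        with pytest.raises(ValueError, match="negative"):
            find_nonredundant_shortest_paths(sub, "PN", "PM", 0.9)


class TestInteractionScore:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([0.5], 2.0), ([0.3, 0.6], 0.3**-1 + 0.6**-1), ([], 0.0)],
    )
    def test_sum_of_inverted_lengths(self, lengths, expected):
        paths = [PathRecord("A", "B", ("x",), l, 0) for l in lengths]
        assert interaction_score(paths) == pytest.approx(expected)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            interaction_score([PathRecord("A", "B", ("x",), 0.0, 0)])


class TestRandomizePathway:
    def _graph(self):
        # two strength strata: hub cluster (strength ~ 10) vs leaves (~1)
        sets = {"P": {"h0"}, "Q": {"l0"}}
        rows = []
        hubs = [f"h{i}" for i in range(5)]
        leaves = [f"l{i}" for i in range(10)]
        for a in hubs:
            for b in hubs:
                if a < b:
                    rows.append((a, b, False))
        for i, l in enumerate(leaves):
            rows.append((l, leaves[(i + 1) % len(leaves)], False))
        return weighted_graph(sets, rows, {})

    def test_member_count_preserved(self):
        g = weighted_graph(
            {"P": {"a", "b"}, "Q": {"c"}},
            [("a", "c", False), ("b", "c", False), ("c", "d", False), ("d", "e", False)],
            {},
        )
        rng = np.random.default_rng(0)
        g2 = randomize_pathway(g, "P", rng)
        members = [v for v in g2.successors("P")]
        assert len(members) == 2
        assert all(g2.nodes[m]["pathways"] >= {"P"} for m in members)

    def test_strength_stratum_respected(self):
        g = self._graph()
        strengths = node_strengths(g)
        strata = _StrengthStrata(strengths, 20)
        rng = np.random.default_rng(1)
        hub_strength = strengths["h0"]
        same = 0
        n = 1000
        for _ in range(n):
            g2 = randomize_pathway(g, "P", rng, strata)
            (repl,) = list(g2.successors("P"))
            if abs(strengths[repl] - hub_strength) < abs(strengths[repl] - strengths["l0"]):
                same += 1
        assert same / n >= 0.95

    def test_uniform_when_strengths_identical(self):
        g = weighted_graph(
            {"P": {"a"}},
            [("a", "b", False), ("b", "c", False), ("c", "a", False)],
            {},
        )
        rng = np.random.default_rng(2)
        drawn = {list(randomize_pathway(g, "P", rng).successors("P"))[0] for _ in range(50)}
        assert drawn == {"b", "c"}


class TestEmpiricalPvalues:
    def _planted(self):
        g = weighted_graph(
            {"PN": {"a"}, "PM": {"b"}},
            [("a", "b", True, "tf_target")]
            + [(f"u{i}", f"u{i+1}", False) for i in range(10)],
            {"a": 6, "b": 6},
        )
        return g

    def test_zero_score_is_p_one_without_permutation(self):
        g = self._planted()
        pairs = [PairResult("PM", "PN", 0.0, [])]
        out = empirical_pvalues(g, pairs, CoreParams(seed=0), np.random.default_rng(0))
        assert out[0].p_value == 1.0 and out[0].n_permutations == 0

    def test_significant_pair_extended_to_pooled_permutations(self):
        g = self._planted()
        params = CoreParams(n_perm_initial=20, n_perm_extra=80, seed=0)
        pairs = run_all_pairs(g, collection_of(g), params)
        planted = next(p for p in pairs if (p.source_pathway, p.target_pathway) == ("PN", "PM"))
        assert planted.p_value <= 0.05
        assert planted.n_permutations == 100  # 20 + 80 pooled

    def test_identical_seed_identical_pvalues(self):
        rng = np.random.default_rng(3)
        g, pc, pn, pm = random_tiny_instance(rng, n_proteins=14)
        params = CoreParams(n_perm_initial=30, n_perm_extra=30, l_max=1.5, seed=9)
        a = run_all_pairs(g, pc, params)
        b = run_all_pairs(g, pc, params)
        assert [(p.p_value, p.n_permutations) for p in a] == [
            (p.p_value, p.n_permutations) for p in b
        ]


def collection_of(g):
    """Rebuild a PathwayCollection from a unified graph's annotations."""
    from pathxtalk import Pathway, PathwayCollection

    sets: dict[str, set[str]] = {}
    for n, d in g.nodes(data=True):
        if d["kind"] == "xref":
            for p in d["pathways"]:
                sets.setdefault(p, set()).add(n)
    return PathwayCollection(
        [Pathway(p, p, "test", frozenset(m)) for p, m in sorted(sets.items())]
    )


class TestRunAllPairs:
    def test_directionality_of_planted_bridge(self):
        g = weighted_graph(
            {"PN": {"a"}, "PM": {"b"}},
            [("a", "b", True, "tf_target")],
            {"a": 6, "b": 6},
        )
        pairs = run_all_pairs(g, collection_of(g), CoreParams(seed=0),
                              compute_pvalues=False)
        by_key = {(p.source_pathway, p.target_pathway): p for p in pairs}
        assert by_key[("PN", "PM")].score > 0
        assert by_key[("PM", "PN")].score == 0.0

    def test_unregulated_data_yields_no_paths(self):
        # with all |T| = 0 every protein-protein path costs >= 2 * f(0) > l_max
        g = weighted_graph(
            {"PN": {"a"}, "PM": {"b"}},
            [("a", "b", False), ("b", "c", False)],
            {"a": 0.0, "b": 0.0, "c": 0.0},
        )
        assert 2 * sigmoid_weight(0.0) > 0.9
        pairs = run_all_pairs(g, collection_of(g), CoreParams(seed=0),
                              compute_pvalues=False)
        assert all(p.score == 0.0 for p in pairs)

    def test_all_ordered_pairs_evaluated(self):
        g = weighted_graph(
            {"P1": {"a"}, "P2": {"b"}, "P3": {"c"}},
            [("a", "b", False), ("b", "c", False), ("a", "c", False)],
            {"a": 6, "b": 6, "c": 6},
        )
        pairs = run_all_pairs(g, collection_of(g), CoreParams(seed=0),
                              compute_pvalues=False)
        assert len(pairs) == 6

    def test_score_monotone_under_new_bridge_and_weight_increase(self):
        base_sets = {"PN": {"a", "c"}, "PM": {"b", "d"}}
        rows = [("a", "b", True, "tf_target")]
        t = {"a": 6, "b": 6, "c": 6, "d": 6}
        g1 = weighted_graph(base_sets, rows, t)
        g2 = weighted_graph(base_sets, rows + [("c", "d", True, "tf_target")], t)
        s = lambda g: next(
            p.score
            for p in run_all_pairs(g, collection_of(g), CoreParams(seed=0),
                                   compute_pvalues=False)
            if (p.source_pathway, p.target_pathway) == ("PN", "PM")
        )
        assert s(g2) > s(g1)
        # weakening a gene on the path (raising its weight) lowers the score
        g3 = weighted_graph(base_sets, rows, {**t, "b": 2.0})
        assert s(g3) < s(g1)
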