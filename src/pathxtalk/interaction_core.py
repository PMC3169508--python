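"""Pairwise cross-talk detection: subgraphs, non-redundant shortest paths,
scores and permutation significance.

For an ordered pathway pair (Pn, Pm) the procedure is:

1. restrict the weighted unified graph to the nodes reachable from Pn
   within ``nb`` visited edges;
2. build the pair subgraph: Pn, Pm, their member proteins, and proteins
   annotated to no pathway — proteins of other pathways are excluded so an
   apparent Pn→Pm route through a third pathway is not counted; for a
   protein shared by Pn and Pm the membership edge into Pm is removed so
   mere overlap does not register as interaction, while the shared protein
   can still act as an intermediate between distinct partners;
3. repeatedly extract the weighted shortest Pn→Pm path, record it, and
   delete its interior (protein-protein) edges, until no path of summed
   weight <= ``l_max`` remains;
4. score the pair as the sum of inverted path lengths;
5. assess significance against a null in which Pm is rewired to random
   proteins of matched strength (weighted degree), re-running steps 1-4 per
   permutation.
"""
from __future__ import annotations

import heapq
import logging
from typing import Optional, Sequence

import numpy as np
import networkx as nx

from .graph_weighting import INTERACTION, MEMBERSHIP, PATHWAY, XREF
from .models import CoreParams, PairResult, PathRecord, PathwayCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# subgraph construction


def neighborhood_subgraph(g: nx.DiGraph, pn: str, nb: int) -> nx.DiGraph:
    """Induced subgraph on nodes at directed hop distance <= nb from ``pn``.

    Every edge traversal — membership or interaction — counts as one step,
    so nb = 5 admits paths with at most three protein-protein edges between
    the two pathway endpoints.
    """
    if pn not in g or g.nodes[pn]["kind"] != PATHWAY:
        raise KeyError(f"{pn!r} is not a pathway node of the graph")
    return nx.ego_graph(g, pn, radius=nb)


def pair_subgraph(g_pn: nx.DiGraph, pn: str, pm: str) -> nx.DiGraph:
    """Pair subgraph for the ordered pair (pn, pm).

    Keeps the two pathway nodes, their member xrefs, and xrefs annotated to
    no pathway in the full collection; every other node is removed.  For
    each xref that is a member of both pathways, the membership edge
    xref→pm is deleted.
    """
    if pn == pm:
        raise ValueError("self-interaction of a pathway is undefined")
    for p in (pn, pm):
        if p not in g_pn or g_pn.nodes[p]["kind"] != PATHWAY:
            raise KeyError(f"{p!r} is not a pathway node of the subgraph")
    keep = {pn, pm}
    shared: list[str] = []
    for n, data in g_pn.nodes(data=True):
        if data["kind"] != XREF:
            continue
        pws = data["pathways"]
        if pn in pws or pm in pws or not pws:
            keep.add(n)
            if pn in pws and pm in pws:
                shared.append(n)
    sub = g_pn.subgraph(keep).copy()
    for x in shared:
        if sub.has_edge(x, pm):
            sub.remove_edge(x, pm)
    return sub


# ---------------------------------------------------------------------------
# shortest paths


def _dijkstra(g: nx.DiGraph, source: str, target: str) -> tuple[Optional[list[str]], float]:
    """Deterministic Dijkstra; ties resolved by lexical node order in the queue."""
    dist: dict[str, float] = {source: 0.0}
    prev: dict[str, str] = {}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == target:
            path = [u]
            while path[-1] != source:
                path.append(prev[path[-1]])
            return path[::-1], d
        for v in sorted(g.successors(u)):
            if v in done:
                continue
            w = g.edges[u, v]["weight"]
            if w < 0:
                raise ValueError(f"negative edge weight on {u}->{v}")
            nd = d + w
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return None, float("inf")


def find_nonredundant_shortest_paths(
    sub: nx.DiGraph, pn: str, pm: str, l_max: float
) -> list[PathRecord]:
    """Iteratively extract edge-disjoint weighted shortest paths pn→pm.

    Each recorded path has its interior edges (those touching neither
    pathway node) deleted before the next search, so successive paths
    represent distinct routes.  The loop stops when no path of length
    <= ``l_max`` remains.  Returned paths are in ascending length order.
    """
    g = sub.copy()
    records: list[PathRecord] = []
    while True:
        path, length = _dijkstra(g, pn, pm)
        if path is None or length > l_max:
            break
        interior = [
            (u, v)
            for u, v in zip(path, path[1:])
            if pn not in (u, v) and pm not in (u, v)
        ]
        if not interior:
            raise RuntimeError(
                f"path {path} has no deletable interior edge; overlap-edge "
                "removal in pair_subgraph should make this impossible"
            )
        xrefs = tuple(path[1:-1])
        n_inter = sum(1 for x in xrefs if not g.nodes[x]["pathways"])
        records.append(PathRecord(pn, pm, xrefs, length, n_inter))
        g.remove_edges_from(interior)
    return records


def interaction_score(paths: Sequence[PathRecord]) -> float:
    """Pair score S = sum of inverted path lengths (0 for no paths)."""
    for p in paths:
        if p.length <= 0:
            raise ValueError(f"non-positive path length {p.length}")
    return float(sum(1.0 / p.length for p in paths))


# ---------------------------------------------------------------------------
# permutation null


def node_strengths(g: nx.DiGraph) -> dict[str, float]:
    """Strength (weighted degree) of every xref: summed weights of incident
    interaction edges, in and out."""
    s = {n: 0.0 for n, d in g.nodes(data=True) if d["kind"] == XREF}
    for u, v, data in g.edges(data=True):
        if data["kind"] != INTERACTION:
            continue
        s[u] += data["weight"]
        s[v] += data["weight"]
    return s


class _StrengthStrata:
    """Quantile strata of xref strengths for connectivity-matched rewiring."""

    def __init__(self, strengths: dict[str, float], n_strata: int = 20):
        self.nodes = sorted(strengths)
        self.strength = strengths
        vals = np.array([strengths[n] for n in self.nodes])
        edges = np.quantile(vals, np.linspace(0, 1, n_strata + 1))
        self.bin_of = {
            n: int(np.searchsorted(edges[1:-1], strengths[n], side="left"))
            for n in self.nodes
        }
        self.members: dict[int, list[str]] = {}
        for n in self.nodes:
            self.members.setdefault(self.bin_of[n], []).append(n)

    def draw(self, like: str, exclude: set[str], rng: np.random.Generator) -> str:
        """Draw a replacement for ``like`` from its stratum, excluding
        ``exclude``; falls back to the nearest-strength eligible node."""
        cand = [n for n in self.members[self.bin_of[like]] if n not in exclude]
        if not cand:
            logger.debug("empty stratum for %s; nearest-strength fallback", like)
            pool = [n for n in self.nodes if n not in exclude]
            if not pool:
                raise ValueError("no eligible replacement node in the graph")
            ref = self.strength[like]
            best = min(abs(self.strength[n] - ref) for n in pool)
            cand = [n for n in pool if abs(self.strength[n] - ref) == best]
        return cand[int(rng.integers(len(cand)))]


def randomize_pathway(
    g: nx.DiGraph,
    pm: str,
    rng: np.random.Generator,
    strata: Optional[_StrengthStrata] = None,
    n_strata: int = 20,
) -> nx.DiGraph:
    """Return a copy of ``g`` in which ``pm`` is rewired to random xrefs of
    matched strength.

    Each member is replaced by a distinct non-member drawn from the member's
    strength stratum; the member count is preserved and the rest of the
    graph is untouched.  Node ``pathways`` annotations are updated so that
    downstream pair subgraphs see the randomized membership.
    """
    if strata is None:
        strata = _StrengthStrata(node_strengths(g), n_strata)
    members = sorted(
        v for v in g.successors(pm) if g.edges[pm, v]["kind"] == MEMBERSHIP
    )
    exclude = set(members)
    replacements: dict[str, str] = {}
    for x in members:
        y = strata.draw(x, exclude, rng)
        exclude.add(y)
        replacements[x] = y

    out = g.copy()
    for x, y in replacements.items():
        out.remove_edge(pm, x)
        out.remove_edge(x, pm)
        out.nodes[x]["pathways"] = frozenset(out.nodes[x]["pathways"] - {pm})
        out.add_edge(pm, y, kind=MEMBERSHIP, weight=out.nodes[y]["in_weight"])
        out.add_edge(y, pm, kind=MEMBERSHIP, weight=0.0)
        out.nodes[y]["pathways"] = frozenset(out.nodes[y]["pathways"] | {pm})
    return out


def _pair_score(g: nx.DiGraph, pn: str, pm: str, params: CoreParams) -> float:
    """Steps 1-4 for a single ordered pair on an arbitrary (possibly
    randomized) weighted unified graph."""
    g_pn = neighborhood_subgraph(g, pn, params.nb)
    if pm not in g_pn:
        return 0.0
    sub = pair_subgraph(g_pn, pn, pm)
    paths = find_nonredundant_shortest_paths(sub, pn, pm, params.l_max)
    return interaction_score(paths)


def empirical_pvalues(
    g: nx.DiGraph,
    pairs: list[PairResult],
    params: CoreParams,
    rng: np.random.Generator,
    keep_null_scores: bool = False,
) -> list[PairResult]:
    """Two-stage empirical p-values against strength-matched rewiring of Pm.

    Stage 1 uses ``n_perm_initial`` permutations; pairs below ``p_extend``
    receive ``n_perm_extra`` additional permutations and a p-value pooled
    over all of them.  p = #(null score >= observed) / n_permutations.  A
    pair with observed score 0 is p = 1 exactly (every null score is >= 0),
    so no permutations are spent on it.
    """
    strata = _StrengthStrata(node_strengths(g), params.n_strata)
    out: list[PairResult] = []
    for pr in pairs:
        if pr.score <= 0.0:
            out.append(pr.with_pvalue(1.0, 0))
            continue
        nulls: list[float] = []
        for _ in range(params.n_perm_initial):
            g_r = randomize_pathway(g, pr.target_pathway, rng, strata)
            nulls.append(_pair_score(g_r, pr.source_pathway, pr.target_pathway, params))
        count = sum(1 for s in nulls if s >= pr.score)
        n = params.n_perm_initial
        if count / n < params.p_extend:
            for _ in range(params.n_perm_extra):
                g_r = randomize_pathway(g, pr.target_pathway, rng, strata)
                nulls.append(
                    _pair_score(g_r, pr.source_pathway, pr.target_pathway, params)
                )
            count = sum(1 for s in nulls if s >= pr.score)
            n += params.n_perm_extra
        out.append(
            pr.with_pvalue(count / n, n, nulls if keep_null_scores else None)
        )
    return out


# ---------------------------------------------------------------------------
# driver


def run_all_pairs(
    g: nx.DiGraph,
    pc: PathwayCollection,
    params: CoreParams = CoreParams(),
    compute_pvalues: bool = True,
) -> list[PairResult]:
    """Score every ordered pathway pair and attach empirical p-values.

    Pairs whose target pathway is unreachable within the ``nb``-radius
    neighborhood of the source get score 0 and p = 1 without permutation.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pids = sorted(pc.ids())
    results: list[PairResult] = []
    for pn in pids:
        g_pn = neighborhood_subgraph(g, pn, params.nb)
        for pm in pids:
            if pm == pn:
                continue
            if pm not in g_pn:
                results.append(PairResult(pn, pm, 0.0, [], p_value=1.0))
                continue
            sub = pair_subgraph(g_pn, pn, pm)
            paths = find_nonredundant_shortest_paths(sub, pn, pm, params.l_max)
            results.append(PairResult(pn, pm, interaction_score(paths), paths))
    if compute_pvalues:
        results = empirical_pvalues(g, results, params, rng)
    return results
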