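"""Assembly and summary of the two output network representations.

The *pathway interaction network* has one node per pathway and one directed
edge per significant ordered pair.  The *detailed network* additionally
shows the proteins and protein interactions that compose the recovered
paths.  Both are plain :class:`networkx.DiGraph` objects with node/edge
attributes ready for Cytoscape export.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .models import EnrichmentResult, GeneStatTable, PairResult, PathRecord

#: Enrichment p-value below which a pathway node is flagged as enriched.
ENRICH_P = 0.05
#: Gene q-value below which a protein node is flagged as significant.
GENE_Q = 0.05


def build_pathway_network(
    pairs: Sequence[PairResult],
    enrich: Optional[Sequence[EnrichmentResult]] = None,
    p_threshold: float = 0.001,
) -> nx.DiGraph:
    """Directed pathway network with edges for pairs at p < ``p_threshold``
    (strict).  Only pathways carrying at least one edge appear as nodes.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    enrich_p = {e.pathway_id: e.p for e in enrich} if enrich else {}
    net = nx.DiGraph()
    for pr in pairs:
        if pr.p_value is None or pr.p_value >= p_threshold:
            continue
        net.add_edge(
            pr.source_pathway,
            pr.target_pathway,
            kind="crosstalk",
            score=pr.score,
            n_paths=len(pr.paths),
            p_value=pr.p_value,
        )
    for n in net.nodes:
        ep = enrich_p.get(n)
        net.nodes[n]["kind"] = "pathway"
        net.nodes[n]["enriched"] = bool(ep is not None and ep < ENRICH_P)
        if ep is not None:
            net.nodes[n]["enrichment_p"] = ep
        net.nodes[n]["in_degree"] = net.in_degree(n)
        net.nodes[n]["out_degree"] = net.out_degree(n)
    return net


def extract_detailed_network(
    pairs: Sequence[PairResult], stats: Optional[GeneStatTable] = None
) -> nx.DiGraph:
    """Union of all recorded paths as a pathway+protein network.

    Each path contributes a membership edge from its source pathway to its
    first protein, directed interaction edges along the protein chain, and a
    membership edge from its last protein to the target pathway.  Protein
    nodes carry T and q attributes when a statistics table is supplied and
    are flagged significant at q < 0.05.
    """
    net = nx.DiGraph()
    for pr in pairs:
        for path in pr.paths:
            net.add_node(path.source_pathway, kind="pathway")
            net.add_node(path.target_pathway, kind="pathway")
            for x in path.nodes:
                net.add_node(x, kind="protein")
            net.add_edge(path.source_pathway, path.nodes[0], kind="membership")
            net.add_edge(path.nodes[-1], path.target_pathway, kind="membership")
            for u, v in zip(path.nodes, path.nodes[1:]):
                net.add_edge(u, v, kind="interaction")
    if stats is not None:
        for n, data in net.nodes(data=True):
            if data["kind"] != "protein" or n not in stats:
                continue
            row = stats.rows[n]
            data["t"] = row.t
            if row.q is not None:
                data["q"] = row.q
                data["significant"] = bool(row.q < GENE_Q)
    return net


@dataclass(frozen=True)
class PathClassSummary:
    n_direct: int
    n_indirect: int
    fraction_indirect: float
    by_intermediates: dict[int, int]


def classify_paths(paths: Sequence[PathRecord]) -> PathClassSummary:
    """Tabulate direct vs indirect paths and intermediate-protein counts."""
    by_inter = Counter(p.n_intermediates for p in paths)
    n_direct = by_inter.get(0, 0)
    n_indirect = len(paths) - n_direct
    frac = n_indirect / len(paths) if paths else 0.0
    return PathClassSummary(n_direct, n_indirect, frac, dict(by_inter))


def centrality_stats(net: nx.DiGraph, directed: bool = True) -> pd.DataFrame:
    """Per-pathway degree and normalized betweenness centrality.

    Betweenness is computed on the directed graph (or its undirected view
    with ``directed=False``) and normalized by (n-1)(n-2): the number of
    ordered node pairs excluding the focal node, i.e. the maximum possible
    centrality.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    graph = net if directed else net.to_undirected(as_view=True)
    n = net.number_of_nodes()
    raw = nx.betweenness_centrality(graph, normalized=False)
    if not directed:
        # undirected raw counts each unordered pair once; scale to ordered
        raw = {k: 2 * v for k, v in raw.items()}
    denom = (n - 1) * (n - 2) if n > 2 else 1
    rows = [
        {
            "pathway": node,
            "in_degree": net.in_degree(node),
            "out_degree": net.out_degree(node),
            "betweenness_normalized": raw[node] / denom,
        }
        for node in sorted(net.nodes)
    ]
    return pd.DataFrame(rows)


def top_crosstalk_proteins(pairs: Sequence[PairResult], k: int) -> pd.DataFrame:
    """Rank proteins by the number of distinct ordered pathway pairs whose
    paths contain them; ties broken by path count, then lexically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pair_sets: dict[str, set[tuple[str, str]]] = {}
    path_counts: Counter[str] = Counter()
    for pr in pairs:
        key = (pr.source_pathway, pr.target_pathway)
        for path in pr.paths:
            for x in path.nodes:
                pair_sets.setdefault(x, set()).add(key)
                path_counts[x] += 1
    rows = [
        {"protein": x, "n_pairs": len(s), "n_paths": path_counts[x]}
        for x, s in pair_sets.items()
    ]
    rows.sort(key=lambda r: (-r["n_pairs"], -r["n_paths"], r["protein"]))
    return pd.DataFrame(rows[:k], columns=["protein", "n_pairs", "n_paths"])
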