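"""Unified pathway/protein graph construction and data-driven edge weights.

The unified graph mixes two node kinds: *pathway* nodes and *xref* nodes
(genes/proteins in one unified identifier namespace).  Protein interactions
become directed edges between xref nodes (undirected rows expand to two
opposite directed edges); each pathway is connected to each member xref by
a reciprocal pair of membership edges so paths can both leave a source
pathway and enter a target pathway.

Edge weights encode differential expression: the weight of an edge is a
sigmoid transform of the |T| statistic of its *target* xref, so edges into
strongly regulated genes are cheap and paths through them short.  Edges into
pathway nodes are free (weight 0) and edges into unmeasured genes carry the
maximum weight 1.
"""
from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.special import expit

from .models import (
    EnrichmentResult,
    GeneStatTable,
    InteractionTable,
    PathwayCollection,
    WeightParams,
)

NODE_KIND = "kind"
EDGE_KIND = "kind"
PATHWAY = "pathway"
XREF = "xref"
MEMBERSHIP = "membership"
INTERACTION = "interaction"


def sigmoid_weight(t: float, wp: WeightParams = WeightParams()) -> float:
    """Soft-threshold transform f(T) = 1 / (1 + exp(alpha * (|T| - mu))).

    Strictly decreasing in |T| with f(mu) = 0.5 exactly; range (0, 1).
    """
    return float(expit(wp.alpha * (wp.mu - abs(t))))


def build_unified_graph(pc: PathwayCollection, it: InteractionTable) -> nx.DiGraph:
    """Assemble the mixed pathway/xref graph (weights not yet assigned).

    Every undirected interaction row contributes two directed edges, every
    directed row one.  Each (pathway, member) pair contributes reciprocal
    membership edges.  Each xref node carries a ``pathways`` attribute with
    the pathway ids it is annotated to (empty for pathway-free proteins).
    """
    gene_index = pc.gene_index()
    xrefs = pc.all_genes() | it.genes()
    clash = xrefs & set(pc.ids())
    if clash:
        raise ValueError(f"identifier(s) used both as pathway and gene id: {sorted(clash)[:5]}")

    g = nx.DiGraph()
    for x in sorted(xrefs):
        g.add_node(x, kind=XREF, pathways=gene_index.get(x, frozenset()))
    for p in pc:
        g.add_node(p.pathway_id, kind=PATHWAY)
        for x in sorted(p.members):
            g.add_edge(p.pathway_id, x, kind=MEMBERSHIP)
            g.add_edge(x, p.pathway_id, kind=MEMBERSHIP)
    for e in it.edges:
        g.add_edge(e.source, e.target, kind=INTERACTION, itype=e.itype)
        if not e.directed:
            g.add_edge(e.target, e.source, kind=INTERACTION, itype=e.itype)
    return g


def assign_edge_weights(
    g: nx.DiGraph, stats: GeneStatTable, wp: WeightParams = WeightParams()
) -> nx.DiGraph:
    """Assign the weight of every edge from its target node (in place).

    weight = 0 into a pathway node, f(T) into a measured xref, 1 into an
    unmeasured xref.  The per-xref incoming weight is cached as a node
    attribute ``in_weight`` (used when pathway membership is rewired during
    permutation).
    """
    for v, data in g.nodes(data=True):
        if data[NODE_KIND] == XREF:
            data["in_weight"] = sigmoid_weight(stats.t(v), wp) if v in stats else 1.0
    for u, v, data in g.edges(data=True):
        nd = g.nodes[v]
        data["weight"] = 0.0 if nd[NODE_KIND] == PATHWAY else nd["in_weight"]
    return g


def gene_set_enrichment(
    pc: PathwayCollection,
    stats: GeneStatTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Mean-|T| gene-set enrichment with an empirical permutation null.

    Each pathway's score is the mean absolute T over its measured members;
    the null is the score of ``n_perm`` random gene sets of the same measured
    size drawn without replacement from all measured genes, and
    p = #(null >= score) / n_perm.  Pathways with no measured member are
    reported without a score or p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(stats) == 0:
        raise ValueError("gene statistics table is empty")
    universe = sorted(stats.rows)
    abs_t = np.array([abs(stats.rows[g].t) for g in universe])
    index = {g: i for i, g in enumerate(universe)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    results: list[EnrichmentResult] = []
    for p in pc:
        measured = [index[g] for g in sorted(p.members) if g in index]
        k = len(measured)
        if k == 0:
            results.append(EnrichmentResult(p.pathway_id, None, None, 0))
            continue
        score = float(abs_t[measured].mean())
        if k not in null_cache:
            if k >= len(universe):
                null = np.full(n_perm, abs_t.mean())
            else:
                keys = rng.random((n_perm, len(universe)))
                idx = np.argpartition(keys, k, axis=1)[:, :k]
                null = abs_t[idx].mean(axis=1)
            null_cache[k] = null
        pval = float(np.count_nonzero(null_cache[k] >= score) / n_perm)
        results.append(EnrichmentResult(p.pathway_id, score, pval, k))
    return results
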