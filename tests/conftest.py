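"""Shared builders for small hand-constructed graphs and collections."""
from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from pathxtalk import (
    GeneStat,
    GeneStatTable,
    Interaction,
    InteractionTable,
    Pathway,
    PathwayCollection,
    WeightParams,
    assign_edge_weights,
    build_unified_graph,
)


def collection(sets: dict[str, set[str]]) -> PathwayCollection:
    """PathwayCollection from {pathway_id: member set}."""
    return PathwayCollection(
        [Pathway(pid, pid.lower(), "test", frozenset(m)) for pid, m in sets.items()]
    )


def interactions(rows: list[tuple]) -> InteractionTable:
    """InteractionTable from (source, target, directed[, itype]) tuples."""
    edges = []
    for row in rows:
        src, tgt, directed = row[0], row[1], row[2]
        itype = row[3] if len(row) > 3 else "binding"
        edges.append(Interaction(src, tgt, directed, itype, "test"))
    return InteractionTable(edges)


def stat_table(tvals: dict[str, float], q: dict[str, float] | None = None) -> GeneStatTable:
    q = q or {}
    return GeneStatTable(
        {g: GeneStat(t, q=q.get(g)) for g, t in tvals.items()}
    )


def weighted_graph(
    sets: dict[str, set[str]],
    rows: list[tuple],
    tvals: dict[str, float],
    wp: WeightParams = WeightParams(),
) -> nx.DiGraph:
    """Build and weight a unified graph in one call."""
    g = build_unified_graph(collection(sets), interactions(rows))
    return assign_edge_weights(g, stat_table(tvals), wp)


def random_tiny_instance(rng: np.random.Generator, n_proteins: int = 12):
    """A random small weighted instance with two disjoint pathways.

    Returns (graph, collection, "P1", "P2").  Edge density and T statistics
    are drawn so that multiple admissible paths of distinct lengths occur.
    """
    genes = [f"x{i:02d}" for i in range(n_proteins)]
    p1 = set(genes[:3])
    p2 = set(genes[3:6])
    sets = {"P1": p1, "P2": p2}
    rows = []
    for i in range(n_proteins):
        for j in range(n_proteins):
            if i != j and rng.random() < 0.18:
                rows.append((genes[i], genes[j], True, "tf_target"))
    tvals = {g: float(rng.uniform(0, 6)) for g in genes}
    g = weighted_graph(sets, rows, tvals)
    return g, collection(sets), "P1", "P2"


@pytest.fixture
def chain_graph_factory():
    """Factory for Pn—x1—...—xk—Pm chains with chosen T statistics.

    Intermediate proteins beyond the first and last belong to no pathway.
    """

    def build(k: int, tvals: dict[str, float] | None = None) -> nx.DiGraph:
        genes = [f"x{i}" for i in range(1, k + 1)]
        sets = {"PN": {genes[0]}, "PM": {genes[-1]}}
        rows = [(a, b, True, "tf_target") for a, b in zip(genes, genes[1:])]
        return weighted_graph(sets, rows, tvals or {})

    return build
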