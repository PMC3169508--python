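"""Synthetic inputs with planted cross-talk.

Generates the three inputs the pipeline consumes — an interaction network
with a heavy-tailed degree distribution, a pathway collection of connected
network modules, and a per-gene statistics table — plus a manifest of
planted bridges, so recovery of known signal can be tested end to end
without any database download.

A planted ordered pair (source, target) is wired with vertex-disjoint
*bridges*: directed interaction chains from a member of the source pathway
to a member of the target pathway, either direct (member→member) or
indirect (member→pathway-free protein→member).  All bridge genes receive
|T| = ``effect_t`` with random sign, so under the default sigmoid weighting
(mu=3, alpha=2) an effect of T=6 gives a bridge length of about 2·f(6) ≈
0.005, far below the l_max = 0.9 admissibility bound, while background
genes (T ~ Normal(0, 1)) give edge weights near 1 and almost never form an
admissible path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .models import (
    GeneStat,
    GeneStatTable,
    Interaction,
    InteractionTable,
    Pathway,
    PathwayCollection,
)


@dataclass(frozen=True)
class PlantedPair:
    """One planted cross-talk relation between two pathways."""

    source: str
    target: str
    n_bridges: int = 2
    bridge_indirect: bool = False
    effect_t: float = 6.0


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic dataset."""

    n_proteins: int = 300
    degree_exponent: float = 2.5
    mean_degree: float = 4.0
    directed_fraction: float = 0.1
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (8, 15)
    overlap_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    background_t_sd: float = 1.0
    seed: int = 0


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The default recovery benchmark: 300 proteins, 12 pathways, three
    planted ordered pairs (two direct, one indirect) with two bridges each
    at |T| = 6."""
    return FixtureSpec(
        planted_pairs=[
            PlantedPair("PW01", "PW05", n_bridges=2, bridge_indirect=False),
            PlantedPair("PW02", "PW08", n_bridges=2, bridge_indirect=False),
            PlantedPair("PW03", "PW11", n_bridges=2, bridge_indirect=True),
        ],
        seed=seed,
    )


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def generate_interaction_network(spec: FixtureSpec) -> InteractionTable:
    """Chung-Lu random graph with Pareto-distributed expected degrees.

    ``degree_exponent`` is the tail exponent of the expected-degree
    distribution (larger → closer to regular); expected degrees are rescaled
    to ``mean_degree``.  A ``directed_fraction`` of edges become directed
    tf_target rows with random orientation, the rest undirected
    binding/association rows.
    """
    if spec.n_proteins < 20:
        raise ValueError("need at least 20 proteins")
    if spec.degree_exponent <= 1:
        raise ValueError("degree_exponent must be > 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    u = rng.random(n)
    w = (1.0 - u) ** (-1.0 / (spec.degree_exponent - 1.0))
    w = np.minimum(w * spec.mean_degree / w.mean(), n - 1)
    g = nx.expected_degree_graph(
        w.tolist(), seed=int(rng.integers(2**31)), selfloops=False
    )
    ids = [_gene_id(i) for i in range(n)]
    edges: list[Interaction] = []
    for a, b in sorted(g.edges()):
        src, tgt = ids[a], ids[b]
        if rng.random() < spec.directed_fraction:
            if rng.random() < 0.5:
                src, tgt = tgt, src
            edges.append(Interaction(src, tgt, True, "tf_target", "synthetic"))
        else:
            itype = "binding" if rng.random() < 0.5 else "association"
            edges.append(Interaction(src, tgt, False, itype, "synthetic"))
    return InteractionTable(edges)


def generate_pathway_collection(
    spec: FixtureSpec, net: InteractionTable
) -> PathwayCollection:
    """Sample pathways as connected modules by seeded breadth-first growth.

    Modules are grown over nodes not yet assigned to a pathway, so pathways
    are disjoint unless an ``overlap_pairs`` entry (i, j, fraction) forces
    pathway j to share members with pathway i — used to exercise merging and
    the shared-protein edge-removal semantics.
    """
    lo, hi = spec.pathway_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid pathway_size_range")
    if spec.n_pathways * hi > spec.n_proteins:
        raise ValueError("pathway sizes infeasible for this many proteins")
    rng = np.random.default_rng(spec.seed + 1)
    ug = nx.Graph()
    ug.add_nodes_from(_gene_id(i) for i in range(spec.n_proteins))
    ug.add_edges_from((e.source, e.target) for e in net.edges)

    assigned: set[str] = set()
    entries: list[Pathway] = []
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        frontier: list[str] = []
        while len(members) < size:
            if not frontier:
                pool = sorted(set(ug.nodes) - assigned - members)
                frontier = [pool[int(rng.integers(len(pool)))]]
            node = frontier.pop(0)
            if node in members:
                continue
            members.add(node)
            nxt = sorted(
                v for v in ug.neighbors(node) if v not in assigned and v not in members
            )
            rng.shuffle(nxt)
            frontier.extend(nxt)
        assigned |= members
        entries.append(
            Pathway(f"PW{i + 1:02d}", f"Synthetic pathway {i + 1}", "synthetic",
                    frozenset(members))
        )

    for i, j, frac in spec.overlap_pairs:
        pi, pj = entries[i], entries[j]
        k = math.ceil(frac * min(len(pi.members), len(pj.members)))
        donors = sorted(pi.members - pj.members)
        take = [donors[t] for t in rng.choice(len(donors), size=k, replace=False)]
        own = sorted(pj.members - pi.members)
        drop = {own[t] for t in rng.choice(len(own), size=k, replace=False)}
        entries[j] = Pathway(
            pj.pathway_id, pj.name, pj.source,
            frozenset((pj.members - drop) | set(take)),
        )
    return PathwayCollection(entries)


@dataclass
class PlantedFixture:
    """A complete synthetic dataset: inputs plus the planted-truth manifest."""

    collection: PathwayCollection
    network: InteractionTable
    stats: GeneStatTable
    manifest: pd.DataFrame


def generate_gene_stats_with_planted_paths(
    spec: FixtureSpec, net: InteractionTable, pc: PathwayCollection
) -> PlantedFixture:
    """Draw background statistics and wire the planted bridges.

    Background T ~ Normal(0, background_t_sd) for every protein in the
    network.  Bridges are vertex-disjoint within and across planted pairs:
    endpoints are members exclusive to their pathway, intermediates are
    pathway-free, and each bridge gene gets |T| = effect_t with random sign.
    Bridge edges are added to the network as directed tf_target rows (so the
    reverse pair carries no planted signal).  p-values are two-sided normal
    tails of T and q-values Benjamini-Hochberg adjusted.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = sorted(net.genes() | pc.all_genes())
    t = rng.normal(0.0, spec.background_t_sd, len(genes))
    t_of = dict(zip(genes, t))
    gene_index = pc.gene_index()

    used: set[str] = set()
    new_edges: list[Interaction] = []
    manifest_rows: list[dict] = []
    for pp in spec.planted_pairs:
        src_members = pc.members_of(pp.source)
        tgt_members = pc.members_of(pp.target)
        src_pool = sorted(
            g for g in src_members if gene_index[g] == {pp.source} and g not in used
        )
        tgt_pool = sorted(
            g for g in tgt_members if gene_index[g] == {pp.target} and g not in used
        )
        free_pool = sorted(
            g for g in genes if not gene_index.get(g) and g not in used
        )
        need_free = pp.n_bridges if pp.bridge_indirect else 0
        if len(src_pool) < pp.n_bridges or len(tgt_pool) < pp.n_bridges or len(
            free_pool
        ) < need_free:
            raise ValueError(
                f"cannot place {pp.n_bridges} vertex-disjoint bridges for "
                f"{pp.source}->{pp.target}"
            )
        for b in range(pp.n_bridges):
            a = src_pool[int(rng.integers(len(src_pool)))]
            src_pool.remove(a)
            z = tgt_pool[int(rng.integers(len(tgt_pool)))]
            tgt_pool.remove(z)
            chain = [a, z]
            if pp.bridge_indirect:
                m = free_pool[int(rng.integers(len(free_pool)))]
                free_pool.remove(m)
                chain = [a, m, z]
            for gname in chain:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                t_of[gname] = sign * pp.effect_t
            for uu, vv in zip(chain, chain[1:]):
                new_edges.append(Interaction(uu, vv, True, "tf_target", "planted"))
            used.update(chain)
            manifest_rows.append(
                {
                    "source_pathway": pp.source,
                    "target_pathway": pp.target,
                    "bridge": b,
                    "nodes": "|".join(chain),
                    "indirect": pp.bridge_indirect,
                    "effect_t": pp.effect_t,
                }
            )

    tvals = np.array([t_of[g] for g in genes])
    pvals = 2.0 * norm.sf(np.abs(tvals))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    stats = GeneStatTable(
        {
            g: GeneStat(float(tv), float(pv), float(qv))
            for g, tv, pv, qv in zip(genes, tvals, pvals, qvals)
        }
    )

    # merge planted edges into the table, collapsing duplicates
    merged: dict[tuple[str, str, str], Interaction] = {
        (e.source, e.target, e.itype): e for e in net.edges
    }
    for e in new_edges:
        merged.setdefault((e.source, e.target, e.itype), e)
    network = InteractionTable(list(merged.values()))
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "source_pathway",
            "target_pathway",
            "bridge",
            "nodes",
            "indirect",
            "effect_t",
        ],
    )
    return PlantedFixture(pc, network, stats, manifest)


def make_fixture(spec: FixtureSpec) -> PlantedFixture:
    """Generate the full synthetic dataset for a spec."""
    net = generate_interaction_network(spec)
    pc = generate_pathway_collection(spec, net)
    return generate_gene_stats_with_planted_paths(spec, net, pc)
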