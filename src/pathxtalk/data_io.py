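"""Readers and writers for the pipeline's tabular formats.

Inputs are plain tab-separated text: a GMT gene-set file, an interaction
edge table and a per-gene statistics table, optionally passed through a
two-column identifier map at read time.  Outputs are TSV result tables plus
GraphML and SIF renderings of the pathway-level and detailed networks so
they can be loaded straight into Cytoscape.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .models import (
    GeneStat,
    GeneStatTable,
    Interaction,
    InteractionTable,
    ITYPES,
    PairResult,
    PathRecord,
    Pathway,
    PathwayCollection,
    EnrichmentResult,
)

logger = logging.getLogger(__name__)

#: STRING-style confidence cutoff: scored rows below this are dropped.
MIN_CONFIDENCE = 0.4


# ---------------------------------------------------------------------------
# identifier mapping


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping source identifiers to unified identifiers."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: identifier map needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _map_id(gene: str, id_map: Optional[dict[str, str]]) -> str:
    if id_map is None:
        return gene
    if gene in id_map:
        return id_map[gene]
    logger.debug("unmapped identifier kept verbatim: %s", gene)
    return gene


# ---------------------------------------------------------------------------
# readers


def read_pathways_gmt(
    path: str | Path,
    exclude_names: Sequence[str] = (),
    id_map: Optional[dict[str, str]] = None,
    source: str = "",
) -> PathwayCollection:
    """Parse a GMT gene-set file (id, description, member genes...).

    Duplicate genes within a line are collapsed; entries whose *name*
    (description field) matches any ``exclude_names`` entry case-insensitively
    are dropped — used e.g. to drop disease-category gene sets.
    """
    excluded = {e.lower() for e in exclude_names}
    entries: list[Pathway] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            pid, name = fields[0], fields[1]
            if name.lower() in excluded:
                continue
            members = frozenset(
                _map_id(g, id_map) for g in fields[2:] if g.strip()
            )
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            entries.append(Pathway(pid, name, source, members))
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return PathwayCollection(entries)


_INTERACTION_COLUMNS = ("source", "target", "directed", "type", "provenance")


def read_interaction_table(
    path: str | Path, id_map: Optional[dict[str, str]] = None
) -> InteractionTable:
    """Read an interaction edge table.

    Mandatory columns: source, target, directed, type, provenance; an
    optional ``score`` column carries STRING-style confidences, and rows with
    score < 0.4 are excluded.  Self-loops are dropped and duplicate
    (source, target, type) rows collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    has_score = "score" in df.columns

    seen: dict[tuple[str, str, str], Interaction] = {}
    for row in df.itertuples(index=False):
        if has_score:
            raw_score = getattr(row, "score")
            if raw_score is not None and str(raw_score) not in ("", "nan"):
                if float(raw_score) < MIN_CONFIDENCE:
                    continue
        src = _map_id(str(row.source), id_map)
        tgt = _map_id(str(row.target), id_map)
        if src == tgt:
            logger.debug("dropping self-loop on %s", src)
            continue
        itype = str(row.type)
        if itype not in ITYPES:
            raise ValueError(
                f"{path}: unknown interaction type {itype!r}; "
                f"allowed values: {sorted(ITYPES)}"
            )
        directed = str(row.directed).strip().lower() in ("1", "true", "yes")
        key = (src, tgt, itype)
        if key in seen:
            continue
        seen[key] = Interaction(src, tgt, directed, itype, str(row.provenance))
    return InteractionTable(list(seen.values()))


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    """Serialize an interaction table in the format read_interaction_table accepts."""
    df = pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "directed": int(e.directed),
                "type": e.itype,
                "provenance": e.provenance,
            }
            for e in table.edges
        ],
        columns=list(_INTERACTION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_stats(
    path: str | Path, id_map: Optional[dict[str, str]] = None
) -> GeneStatTable:
    """Read the per-gene statistics table (gene_id, t, optional p and q).

    Duplicate gene ids (e.g. several source ids mapping to one unified id)
    keep the row with the largest |T|, preserving its sign.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "t"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    rows: dict[str, GeneStat] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = _map_id(str(row.gene_id), id_map)
        try:
            t = float(row.t)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: non-numeric t value {row.t!r}") from exc
        p = _opt_float(getattr(row, "p", None))
        q = _opt_float(getattr(row, "q", None))
        stat = GeneStat(t, p, q)
        if gene in rows:
            logger.warning("duplicate gene id %s: keeping row with largest |T|", gene)
            if abs(t) <= abs(rows[gene].t):
                continue
        rows[gene] = stat
    return GeneStatTable(rows)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    s = str(value)
    if s in ("", "nan"):
        return None
    return float(s)


# ---------------------------------------------------------------------------
# result writers

PAIRS_COLUMNS = [
    "source_pathway",
    "target_pathway",
    "score",
    "n_paths",
    "p_value",
    "n_permutations",
]

PATHS_COLUMNS = [
    "source_pathway",
    "target_pathway",
    "nodes",
    "length",
    "n_intermediates",
    "classification",
]


def pairs_frame(pairs: Iterable[PairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_pathway": pr.source_pathway,
                "target_pathway": pr.target_pathway,
                "score": pr.score,
                "n_paths": len(pr.paths),
                "p_value": pr.p_value,
                "n_permutations": pr.n_permutations,
            }
            for pr in pairs
        ],
        columns=PAIRS_COLUMNS,
    )


def paths_frame(paths: Iterable[PathRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_pathway": p.source_pathway,
                "target_pathway": p.target_pathway,
                "nodes": "|".join(p.nodes),
                "length": p.length,
                "n_intermediates": p.n_intermediates,
                "classification": p.classification,
            }
            for p in paths
        ],
        columns=PATHS_COLUMNS,
    )


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    """Read back a pairs TSV written by :func:`write_network_files`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _sanitize_graph_attrs(g: nx.DiGraph) -> nx.DiGraph:
    """GraphML supports scalar attributes only: drop Nones, stringify sets."""
    out = g.copy()
    for _, data in out.nodes(data=True):
        for k in list(data):
            v = data[k]
            if v is None:
                del data[k]
            elif isinstance(v, (set, frozenset)):
                data[k] = "|".join(sorted(v))
            elif isinstance(v, bool):
                data[k] = bool(v)
            elif hasattr(v, "item"):
                data[k] = v.item()
    for _, _, data in out.edges(data=True):
        for k in list(data):
            v = data[k]
            if v is None:
                del data[k]
            elif hasattr(v, "item"):
                data[k] = v.item()
    return out


def _write_sif(g: nx.DiGraph, path: Path, relation_attr: str = "kind") -> None:
    with open(path, "w") as fh:
        for u, v, data in g.edges(data=True):
            rel = data.get(relation_attr, "interacts")
            fh.write(f"{u}\t{rel}\t{v}\n")
        # isolated nodes still appear in Cytoscape when listed alone
        connected = {n for e in g.edges() for n in e}
        for n in g.nodes():
            if n not in connected:
                fh.write(f"{n}\n")


def write_network_files(
    pairs: Sequence[PairResult],
    paths: Sequence[PathRecord],
    out_prefix: str | Path,
    enrich: Optional[Sequence[EnrichmentResult]] = None,
    stats: Optional[GeneStatTable] = None,
    p_threshold: float = 0.001,
) -> dict[str, Path]:
    """Write all result files for one analysis.

    Emits the pairs and paths TSVs for *all* supplied results, then the
    pathway-level network (edges = pairs with p < ``p_threshold``) and the
    detailed pathway+protein network, each as GraphML and SIF with a node
    attribute TSV accompanying the SIF files.
    """
    from .network_analysis import build_pathway_network, extract_detailed_network

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    pairs_path = Path(f"{prefix}.pairs.tsv")
    # %.17g round-trips doubles exactly
    pairs_frame(pairs).to_csv(pairs_path, sep="\t", index=False, float_format="%.17g")
    written["pairs"] = pairs_path

    paths_path = Path(f"{prefix}.paths.tsv")
    paths_frame(paths).to_csv(paths_path, sep="\t", index=False, float_format="%.17g")
    written["paths"] = paths_path

    pw_net = build_pathway_network(pairs, enrich=enrich, p_threshold=p_threshold)
    significant = [
        pr
        for pr in pairs
        if pr.p_value is not None and pr.p_value < p_threshold and pr.paths
    ]
    detailed = extract_detailed_network(significant, stats=stats)

    for name, graph in (("pathways", pw_net), ("detailed", detailed)):
        gml = Path(f"{prefix}.{name}.graphml")
        nx.write_graphml(_sanitize_graph_attrs(graph), gml)
        written[f"{name}_graphml"] = gml
        sif = Path(f"{prefix}.{name}.sif")
        _write_sif(graph, sif)
        written[f"{name}_sif"] = sif
        attrs = Path(f"{prefix}.{name}.nodes.tsv")
        node_rows = []
        for n, data in graph.nodes(data=True):
            row = {"node": n}
            for k, v in data.items():
                row[k] = "|".join(sorted(v)) if isinstance(v, (set, frozenset)) else v
            node_rows.append(row)
        pd.DataFrame(node_rows).to_csv(attrs, sep="\t", index=False)
        written[f"{name}_nodes"] = attrs

    return written
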