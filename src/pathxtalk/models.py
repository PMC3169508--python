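"""Shared data containers for the cross-talk pipeline.

The containers are deliberately thin: pathway collections and interaction
tables are plain records, the unified graph itself is a
:class:`networkx.DiGraph` (see :mod:`pathxtalk.graph_weighting`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

#: Allowed interaction types in an interaction table.
ITYPES = frozenset({"reaction", "association", "binding", "tf_target"})


@dataclass(frozen=True)
class Pathway:
    """A named gene set: one pathway from a collection such as WikiPathways or KEGG."""

    pathway_id: str
    name: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass
class PathwayCollection:
    """An ordered collection of pathways with unique identifiers."""

    entries: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [p.pathway_id for p in self.entries]

    def get(self, pathway_id: str) -> Pathway:
        for p in self.entries:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def members_of(self, pathway_id: str) -> frozenset[str]:
        return self.get(pathway_id).members

    def gene_index(self) -> dict[str, frozenset[str]]:
        """Map each gene to the set of pathway ids it is annotated to."""
        idx: dict[str, set[str]] = {}
        for p in self.entries:
            for g in p.members:
                idx.setdefault(g, set()).add(p.pathway_id)
        return {g: frozenset(s) for g, s in idx.items()}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.entries:
            out |= p.members
        return out


@dataclass(frozen=True)
class Interaction:
    """One edge of the protein interaction network.

    ``directed`` distinguishes e.g. transcription factor → target rows from
    symmetric binding/association rows; undirected rows expand to two
    directed edges when the unified graph is built.
    """

    source: str
    target: str
    directed: bool
    itype: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(
                f"unknown interaction type {self.itype!r}; allowed: {sorted(ITYPES)}"
            )
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r} is not allowed")


@dataclass
class InteractionTable:
    """A deduplicated list of interactions."""

    edges: list[Interaction]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class GeneStat:
    """Per-gene signed moderated t statistic with optional p and q values."""

    t: float
    p: Optional[float] = None
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("T statistic must be finite")


@dataclass
class GeneStatTable:
    """One signed T statistic per gene; the data context that defines edge weights."""

    rows: dict[str, GeneStat]

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, gene: str) -> bool:
        return gene in self.rows

    def t(self, gene: str) -> float:
        return self.rows[gene].t


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the sigmoid transform mapping |T| to an edge weight.

    ``mu`` is the |T| value that receives weight 0.5 and ``alpha`` the
    steepness of the soft threshold.
    """

    mu: float = 3.0
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class CoreParams:
    """Parameters of the pairwise cross-talk search.

    nb: neighborhood radius in visited edges around the source pathway.
    l_max: maximum summed edge weight for a path to contribute to a score.
    n_perm_initial / n_perm_extra / p_extend: two-stage permutation scheme —
    every scored pair gets ``n_perm_initial`` permutations, pairs below
    ``p_extend`` get ``n_perm_extra`` more and a pooled p-value.
    n_strata: quantile strata used for strength-matched pathway rewiring.
    """

    nb: int = 5
    l_max: float = 0.9
    n_perm_initial: int = 100
    n_perm_extra: int = 1000
    p_extend: float = 0.1
    seed: int = 0
    n_strata: int = 20

    def __post_init__(self) -> None:
        if self.nb < 3:
            raise ValueError("nb must be >= 3 (shorter radii cannot span two pathways)")
        if self.l_max <= 0:
            raise ValueError("l_max must be > 0")
        if not (0 < self.p_extend <= 1):
            raise ValueError("p_extend must be in (0, 1]")


@dataclass(frozen=True)
class PathRecord:
    """One non-redundant weighted shortest path between an ordered pathway pair.

    ``nodes`` lists the protein (xref) nodes only; the pathway endpoints are
    implicit.  ``length`` is the sum of edge weights.  ``n_intermediates``
    counts proteins on the path that are annotated to no pathway; a path is
    *direct* iff there are none.
    """

    source_pathway: str
    target_pathway: str
    nodes: tuple[str, ...]
    length: float
    n_intermediates: int

    @property
    def classification(self) -> str:
        return "direct" if self.n_intermediates == 0 else "indirect"


@dataclass
class PairResult:
    """Score and significance of one ordered pathway pair."""

    source_pathway: str
    target_pathway: str
    score: float
    paths: list[PathRecord] = field(default_factory=list)
    p_value: Optional[float] = None
    n_permutations: int = 0
    null_scores: Optional[list[float]] = None

    def with_pvalue(
        self, p: float, n_perm: int, nulls: Optional[list[float]] = None
    ) -> "PairResult":
        return replace(self, p_value=p, n_permutations=n_perm, null_scores=nulls)


@dataclass(frozen=True)
class EnrichmentResult:
    """Gene-set enrichment of a pathway: mean |T| of measured members and an
    empirical permutation p-value.  Pathways without measured members carry
    ``score=None, p=None``."""

    pathway_id: str
    score: Optional[float]
    p: Optional[float]
    n_genes_measured: int


@dataclass
class MergeReport:
    """Outcome of iterative merging of overlapping pathways.

    ``lineage`` maps each id in the merged collection to the original ids it
    absorbed (a singleton list for untouched pathways)."""

    merged_collection: PathwayCollection
    lineage: dict[str, list[str]]
    rounds: int
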