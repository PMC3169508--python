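"""Merging of strongly overlapping pathways.

Gene-set collections combined from several databases contain near-duplicate
pathways describing the same mechanism.  Before cross-talk analysis those
are collapsed: any pair with at least 75% member overlap is merged, and the
scan repeats until no such pair remains.
"""
from __future__ import annotations

from .models import MergeReport, Pathway, PathwayCollection

#: Supported overlap denominators.
DENOMINATORS = ("min", "union", "mean")


def pairwise_overlap(a: frozenset[str], b: frozenset[str], denominator: str = "min") -> float:
    """Overlap of two member sets in [0, 1].

    The default denominator is the smaller set (|A∩B| / min(|A|,|B|)), the
    most inclusive reading; ``union`` gives the Jaccard index and ``mean``
    divides by the average size.
    """
    if not a or not b:
        raise ValueError("overlap of an empty member set is undefined")
    inter = len(a & b)
    if denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "union":
        denom = len(a | b)
    elif denominator == "mean":
        denom = (len(a) + len(b)) / 2
    else:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    return inter / denom


def merge_overlapping_pathways(
    pc: PathwayCollection, threshold: float = 0.75, denominator: str = "min"
) -> MergeReport:
    """Iteratively merge pathway pairs whose overlap reaches ``threshold``.

    Within a round, pathways are visited in lexical id order; each pathway
    still present is merged (member union) with its most-overlapping partner
    at or above the threshold, ties broken toward the lexically smaller
    partner id.  A pathway consumed earlier in the round is skipped.  Rounds
    repeat until no pair reaches the threshold.  The merged id is the
    lexically sorted concatenation of the constituent ids.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")

    # working state: id -> (members, original ids, display name, source)
    state: dict[str, tuple[frozenset[str], list[str], str, str]] = {
        p.pathway_id: (p.members, [p.pathway_id], p.name, p.source) for p in pc
    }
    rounds = 0
    while True:
        rounds += 1
        merged_this_round = False
        consumed: set[str] = set()
        for pid in sorted(state):
            if pid in consumed or pid not in state:
                continue
            members = state[pid][0]
            best: tuple[float, str] | None = None
            for other in sorted(state):
                if other == pid or other in consumed:
                    continue
                ov = pairwise_overlap(members, state[other][0], denominator)
                if ov >= threshold and (best is None or ov > best[0]):
                    best = (ov, other)
            if best is None:
                continue
            other = best[1]
            om, oorig, oname, osrc = state.pop(other)
            m, orig, name, src = state.pop(pid)
            new_orig = orig + oorig
            new_id = "+".join(sorted(new_orig))
            state[new_id] = (
                m | om,
                new_orig,
                f"{name} + {oname}",
                src if src == osrc else f"{src};{osrc}",
            )
            consumed.update({pid, other, new_id})
            merged_this_round = True
        if not merged_this_round:
            break

    entries = [
        Pathway(pid, name, src, members)
        for pid, (members, _, name, src) in sorted(state.items())
    ]
    lineage = {pid: sorted(orig) for pid, (_, orig, _, _) in state.items()}
    merged = PathwayCollection(entries)

    # fixed-point guarantee
    for i, a in enumerate(merged.entries):
        for b in merged.entries[i + 1 :]:
            assert pairwise_overlap(a.members, b.members, denominator) < threshold
    return MergeReport(merged, lineage, rounds)
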