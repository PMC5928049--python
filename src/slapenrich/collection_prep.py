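"""Pathway-collection preprocessing: size filtering and redundancy merging.

Curated pathway resources aggregate the same biological process from several
databases, so a raw collection carries heavily overlapping gene sets.  The
compression step links gene sets whose Jaccard similarity exceeds a strict
threshold (0.8 by default), merges each connected component into the
*intersection* of its members under a joint label, discards the members, and
drops merged sets that fall below the minimum size.  A single compression
round is applied; any residual over-threshold pairs among the outputs are
reported rather than re-merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .datamodel import GeneSet, PathwayCollection

__all__ = ["jaccard", "filter_by_size", "merge_redundant", "MergeReport"]


def jaccard(set_a: GeneSet | frozenset, set_b: GeneSet | frozenset) -> float:
    """Jaccard similarity |A & B| / |A | B| between two gene sets."""
    a = set_a.genes if isinstance(set_a, GeneSet) else frozenset(set_a)
    b = set_b.genes if isinstance(set_b, GeneSet) else frozenset(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def filter_by_size(
    collection: PathwayCollection, min_size: int = 4, max_size: int = 1000
) -> tuple[PathwayCollection, list[dict]]:
    """Retain gene sets with ``min_size <= |P| <= max_size`` (bounds kept)."""
    kept, dropped = [], []
    for s in collection:
        if s.size < min_size:
            dropped.append({"pathway_id": s.id, "reason": f"size {s.size} < {min_size}"})
        elif s.size > max_size:
            dropped.append({"pathway_id": s.id, "reason": f"size {s.size} > {max_size}"})
        else:
            kept.append(s)
    return PathwayCollection(kept), dropped


@dataclass
class MergeReport:
    """Accounting of one redundancy-compression round."""

    merged_groups: list[dict] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)
    residual_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def merge_redundant(
    collection: PathwayCollection,
    j_threshold: float = 0.8,
    min_size: int = 4,
) -> tuple[PathwayCollection, MergeReport]:
    """Merge near-duplicate gene sets by intersection.

    Sets are linked when their pairwise Jaccard similarity is *strictly*
    greater than ``j_threshold``; each connected component is replaced by the
    intersection of its members, labelled by the member names joined with
    ``" // "``.  Merged intersections smaller than ``min_size`` (including
    empty ones, possible for loosely chained components) are dropped with an
    explicit report entry.  Untouched sets pass through in input order;
    merged sets are appended in order of their first member.
    """
    if not 0.0 < j_threshold <= 1.0:
        raise ValueError("j_threshold must be in (0, 1]")
    sets = list(collection)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(sets)))
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            score = jaccard(sets[i], sets[j])
            # strict threshold; exact duplicates (J = 1) always qualify
            if score > j_threshold or score == 1.0:
                graph.add_edge(i, j)

    report = MergeReport()
    out: list[GeneSet] = []
    merged_out: list[GeneSet] = []
    for comp in sorted(nx.connected_components(graph), key=min):
        members = sorted(comp)
        if len(members) == 1:
            out.append(sets[members[0]])
            continue
        member_sets = [sets[i] for i in members]
        inter = frozenset.intersection(*(s.genes for s in member_sets))
        joint_id = "//".join(s.id for s in member_sets)
        joint_name = " // ".join(s.name for s in member_sets)
        report.merged_groups.append(
            {
                "member_ids": [s.id for s in member_sets],
                "joint_id": joint_id,
                "joint_label": joint_name,
                "intersection_size": len(inter),
            }
        )
        if len(inter) < min_size:
            report.dropped.append(
                {
                    "pathway_id": joint_id,
                    "reason": f"merged intersection size {len(inter)} < {min_size}",
                }
            )
            continue
        merged_out.append(GeneSet(id=joint_id, name=joint_name, genes=inter, source="merged"))

    result = PathwayCollection(out + merged_out)
    final = list(result)
    for i in range(len(final)):
        for j in range(i + 1, len(final)):
            score = jaccard(final[i], final[j])
            if score > j_threshold:
                report.residual_pairs.append((final[i].id, final[j].id, score))
    return result, report
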