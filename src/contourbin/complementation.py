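"""Pathway complementation ratios across genome bins.

The complementation ratio of a pathway in a group is the number of the
pathway's required genes present in the group divided by the total number
of genes the pathway requires. Ratios of group unions reveal metabolic
complementation: a pathway no single genome completes may be completed by
the union of two or more genomes' gene sets (e.g., aerobic vitamin B12
biosynthesis split across two community members).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    required_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no required genes")


@dataclass(frozen=True)
class GroupGeneSet:
    group_id: str
    present_genes: frozenset[str]


def read_pathways(path: str) -> list[PathwayDefinition]:
    """Read a pathway TSV with columns (pathway_id, gene_id), one gene per row."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip() for c in df.columns]
    out = []
    for pid, sub in df.groupby("pathway_id", sort=True):
        out.append(PathwayDefinition(str(pid), frozenset(sub["gene_id"])))
    return out


def read_presence(path: str) -> list[GroupGeneSet]:
    """Read a gene-presence TSV with columns (group_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip() for c in df.columns]
    out = []
    for gid, sub in df.groupby("group_id", sort=True):
        out.append(GroupGeneSet(str(gid), frozenset(sub["gene_id"])))
    return out


def complementation_ratio(group: GroupGeneSet, pathway: PathwayDefinition) -> float:
    """|present ∩ required| / |required| for one group."""
    req = pathway.required_genes
    return len(group.present_genes & req) / len(req)


def union_complementation(
    groups: Sequence[GroupGeneSet],
    subset: Iterable[str],
    pathway: PathwayDefinition,
) -> float:
    """Complementation ratio of the pooled gene set of the named groups."""
    by_id = {g.group_id: g for g in groups}
    pooled: set[str] = set()
    for gid in subset:
        if gid not in by_id:
            raise ValueError(f"unknown group id {gid!r}")
        pooled |= by_id[gid].present_genes
    return len(pooled & pathway.required_genes) / len(pathway.required_genes)


def minimal_completing_subsets(
    groups: Sequence[GroupGeneSet],
    pathway: PathwayDefinition,
    max_size: int = 3,
) -> list[frozenset[str]]:
    """All inclusion-minimal group combinations (size <= max_size) whose
    pooled gene set completes the pathway (union ratio = 1).

    Ordered by size, then lexicographically by sorted member ids. The empty
    list means no combination within the cap completes the pathway.
    """
    if not groups:
        raise ValueError("need at least one group")
    ids = sorted(g.group_id for g in groups)
    found: list[frozenset[str]] = []
    for size in range(1, max_size + 1):
        for combo in combinations(ids, size):
            s = frozenset(combo)
            if any(prev <= s for prev in found):
                continue  # a subset already completes: not minimal
            if union_complementation(groups, combo, pathway) == 1.0:
                found.append(s)
    return sorted(found, key=lambda s: (len(s), sorted(s)))


def complementation_report(
    groups: Sequence[GroupGeneSet],
    pathways: Sequence[PathwayDefinition],
    max_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group ratio table and minimal-completing-subset table.

    Returns (ratios, minimal_subsets): ratios has one row per (pathway,
    group) with the complementation ratio; minimal_subsets has one row per
    (pathway, subset) listing the minimal combinations that complete it.
    """
    rows = [
        {"pathway_id": p.pathway_id, "group_id": g.group_id,
         "ratio": complementation_ratio(g, p)}
        for p in pathways for g in groups
    ]
    subsets = [
        {"pathway_id": p.pathway_id, "n_groups": len(s), "groups": "+".join(sorted(s))}
        for p in pathways
        for s in minimal_completing_subsets(groups, p, max_size=max_size)
    ]
    return pd.DataFrame(rows), pd.DataFrame(
        subsets, columns=["pathway_id", "n_groups", "groups"]
    )
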