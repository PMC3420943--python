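"""Assign alleles to allele groups from a supported UPGMA dendrogram."""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from .distance import p_distance_matrix
from .merge import DEFAULT_D_MERGE, merge_clones
from .types import Allele, AlleleGroup, CloneRead
from .upgma import TreeNode, bootstrap_support, upgma

DEFAULT_MIN_SUPPORT = 0.70
DEFAULT_MAX_WITHIN_DISTANCE = 0.03


def _labels(n: int):
    """'A', 'B', ..., 'Z', 'AA', 'AB', ... — spreadsheet-style labels."""
    for k in range(n):
        label = ""
        k += 1
        while k:
            k, rem = divmod(k - 1, 26)
            label = chr(ord("A") + rem) + label
        yield label


def assign_allele_groups(
    tree: TreeNode,
    supports: Mapping[frozenset[str], float],
    min_support: float = DEFAULT_MIN_SUPPORT,
    max_within_distance: float = DEFAULT_MAX_WITHIN_DISTANCE,
    locus: str = "",
) -> list[AlleleGroup]:
    """Cut the dendrogram into allele groups.

    Groups are the maximal clades whose bipartition support is at least
    ``min_support`` and whose node height (half the maximum within-clade
    distance on an ultrametric tree) is at most ``max_within_distance``.
    Alleles in no qualifying clade become singleton groups.  Labels run
    "A", "B", ... in order of decreasing group size, ties broken by the
    smallest member allele id.
    """

    member_sets: list[frozenset[str]] = []

    def visit(node: TreeNode) -> None:
        if node.is_leaf:
            member_sets.append(node.leaves())
            return
        leafset = node.leaves()
        support = supports.get(leafset, 0.0)
        if support >= min_support and node.height <= max_within_distance:
            member_sets.append(leafset)
            return
        for child in node.children:
            visit(child)

    visit(tree)
    member_sets.sort(key=lambda s: (-len(s), min(s)))
    groups = []
    for label, members in zip(_labels(len(member_sets)), member_sets):
        support = (
            supports.get(members, 0.0) if len(members) >= 2 else math.nan
        )
        groups.append(
            AlleleGroup(
                label=label,
                locus=locus,
                member_allele_ids=tuple(sorted(members)),
                support=support,
            )
        )
    return groups


def call_alleles(
    reads: Sequence[CloneRead],
    d_merge: int = DEFAULT_D_MERGE,
    gap_policy: str = "indel_as_diff",
    n_boot: int = 1000,
    seed: int = 0,
    min_support: float = DEFAULT_MIN_SUPPORT,
    max_within_distance: float = DEFAULT_MAX_WITHIN_DISTANCE,
):
    """Run merge -> UPGMA -> bootstrap -> group assignment for one locus.

    Returns ``(alleles, tree, supports, groups)``.  With fewer than two
    distinct alleles the tree and supports are ``None`` and every allele is
    its own group.
    """
    alleles = merge_clones(reads, d_merge=d_merge, gap_policy=gap_policy)
    locus = alleles[0].locus if alleles else ""
    if len(alleles) < 2:
        groups = [
            AlleleGroup("A", locus, (a.id,), math.nan) for a in alleles
        ]
        return alleles, None, {}, groups
    alignment = [(a.id, a.consensus) for a in alleles]
    tree = upgma(p_distance_matrix(alignment))
    supports = bootstrap_support(alignment, n_reps=n_boot, seed=seed)
    groups = assign_allele_groups(
        tree,
        supports,
        min_support=min_support,
        max_within_distance=max_within_distance,
        locus=locus,
    )
    return alleles, tree, supports, groups
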