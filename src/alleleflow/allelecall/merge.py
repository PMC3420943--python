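"""Merge clone reads into consensus alleles.

Reads within ``d_merge`` nucleotide differences of each other are treated
as the same allele observed with PCR/sequencing errors.  Merging uses
single-linkage semantics (connected components of the <=d_merge graph) so
the result does not depend on input order.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from .distance import pairwise_nt_diff
from .types import Allele, AlignmentError, CloneRead, check_aligned

DEFAULT_D_MERGE = 1  # literal "fewer than two differences" merge rule


def build_consensus(cluster_reads: Sequence[CloneRead]) -> str:
    """Per-column majority consensus of >=2 aligned reads.

    Ties are broken deterministically by taking the character of the member
    read with the lexicographically smallest id.
    """
    if len(cluster_reads) < 2:
        raise ValueError("consensus requires at least two reads")
    reads = sorted(cluster_reads, key=lambda r: r.id)
    check_aligned([r.sequence for r in reads])
    seqs = [r.sequence.upper() for r in reads]
    out = []
    for column in zip(*seqs):
        counts = Counter(column)
        best = counts.most_common()
        top_n = best[0][1]
        tied = {ch for ch, n in best if n == top_n}
        if len(tied) == 1:
            out.append(best[0][0])
        else:
            # smallest-id read whose character is among the tied majority
            out.append(next(ch for ch in column if ch in tied))
    return "".join(out)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_clones(
    reads: Sequence[CloneRead],
    d_merge: int = DEFAULT_D_MERGE,
    gap_policy: str = "indel_as_diff",
) -> list[Allele]:
    """Collapse clone reads of one locus into consensus/singleton alleles.

    Parameters
    ----------
    reads
        Aligned clone reads of a single locus.
    d_merge
        Reads at <= ``d_merge`` differences fall in the same cluster.
        The default of 1 merges reads with fewer than two differences.

    Returns
    -------
    list of Allele
        Clusters of >=2 reads yield majority-rule consensus alleles;
        singleton clusters keep their read sequence.  Allele ids are
        assigned in order of decreasing cluster size, ties by smallest
        member read id.
    """
    if not reads:
        return []
    loci = {r.locus for r in reads}
    if len(loci) > 1:
        raise ValueError(f"reads span multiple loci: {sorted(loci)}")
    locus = loci.pop()
    ordered = sorted(reads, key=lambda r: r.id)
    if len({r.id for r in ordered}) != len(ordered):
        raise ValueError("duplicate read ids")
    check_aligned([r.sequence for r in ordered])

    n = len(ordered)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            d = pairwise_nt_diff(
                ordered[i].sequence, ordered[j].sequence, gap_policy
            )
            if d <= d_merge:
                uf.union(i, j)

    clusters: dict[int, list[CloneRead]] = {}
    for i, read in enumerate(ordered):
        clusters.setdefault(uf.find(i), []).append(read)

    members = sorted(
        clusters.values(), key=lambda c: (-len(c), c[0].id)
    )
    alleles = []
    for k, cluster in enumerate(members, start=1):
        if len(cluster) >= 2:
            consensus = build_consensus(cluster)
            singleton = False
        else:
            consensus = cluster[0].sequence.upper()
            singleton = True
        alleles.append(
            Allele(
                id=f"{locus}_al{k:02d}",
                locus=locus,
                consensus=consensus,
                member_read_ids=tuple(r.id for r in cluster),
                is_singleton=singleton,
            )
        )
    return alleles
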