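"""Nucleotide difference counting and p-distance matrices.

Counting conventions
--------------------
A column is a *substitution* when both sequences carry an unambiguous base
(``A/C/G/T``) and the bases differ.  Columns where both sequences have a
gap are transparent (skipped without interrupting a gap run).  Under
``gap_policy="indel_as_diff"`` a maximal run of contiguous gap-vs-base
columns counts as a single difference event; under ``gap_policy="ignore"``
such columns do not count at all.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .types import AlignmentError, DistanceMatrix

GAP = ord("-")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GAP_POLICIES = ("indel_as_diff", "ignore")


def encode(sequence: str) -> np.ndarray:
    """Encode an aligned sequence as a uint8 array."""
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


def _valid_mask(codes: np.ndarray) -> np.ndarray:
    return np.isin(codes, _BASES)


def pairwise_nt_diff(
    seq_a: str, seq_b: str, gap_policy: str = "indel_as_diff"
) -> int:
    """Count nucleotide differences between two aligned sequences.

    Parameters
    ----------
    seq_a, seq_b
        Equal-length aligned sequences over ``{A,C,G,T,N,-}``.
    gap_policy
        ``"indel_as_diff"`` counts each contiguous gap-vs-base run as one
        difference event; ``"ignore"`` scores substitutions only.
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = encode(seq_a)
    b = encode(seq_b)
    a_gap = a == GAP
    b_gap = b == GAP
    keep = ~(a_gap & b_gap)  # both-gap columns are transparent
    if not np.all(keep):
        a, b = a[keep], b[keep]
        a_gap, b_gap = a_gap[keep], b_gap[keep]
    subs = int(np.count_nonzero(_valid_mask(a) & _valid_mask(b) & (a != b)))
    if gap_policy == "ignore":
        return subs
    indel = a_gap ^ b_gap
    if not indel.any():
        return subs
    # one event per maximal run of contiguous indel columns
    starts = int(np.count_nonzero(indel & ~np.concatenate(([False], indel[:-1]))))
    return subs + starts


def _as_items(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    if isinstance(alignment, Mapping):
        return list(alignment.items())
    return list(alignment)


def pdist_arrays(
    labels: Sequence[str], codes: np.ndarray, valid: np.ndarray
) -> DistanceMatrix:
    """p-distance matrix from pre-encoded sequences (pairwise deletion)."""
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        overlap[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            ov = valid[i] & valid[j]
            n_ov = int(np.count_nonzero(ov))
            if n_ov == 0:
                raise AlignmentError(
                    f"no co-scored sites between {labels[i]!r} and {labels[j]!r}"
                )
            d = np.count_nonzero(ov & (codes[i] != codes[j])) / n_ov
            values[i, j] = values[j, i] = d
            overlap[i, j] = overlap[j, i] = n_ov
    return DistanceMatrix(list(labels), values, overlap)


def p_distance_matrix(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]]
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gaps/ambiguities.

    A site contributes to a pair only when both sequences carry an
    unambiguous base there; the distance is (differing sites) / (co-scored
    sites).  A pair with zero co-scored sites raises
    :class:`~alleleflow.allelecall.types.AlignmentError` naming the pair.
    """
    items = _as_items(alignment)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    lengths = {len(seq) for _, seq in items}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
    codes = np.stack([encode(seq) for _, seq in items])
    valid = _valid_mask(codes)
    return pdist_arrays(labels, codes, valid)
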