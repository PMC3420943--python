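"""Domain types for allele calling."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Raised when sequences are not aligned to a common length."""


@dataclass(frozen=True)
class CloneRead:
    """One cloned amplicon sequence with its sampling provenance."""

    id: str
    locus: str
    individual: str
    population: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_CHARS
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)}"
            )

    def header(self) -> str:
        """Pipe-separated FASTA header used by the on-disk dialect."""
        return f"{self.id}|{self.individual}|{self.population}|{self.species}|{self.locus}"


@dataclass(frozen=True)
class Allele:
    """Consensus coding sequence for a cluster of clone reads."""

    id: str
    locus: str
    consensus: str
    member_read_ids: tuple[str, ...]
    is_singleton: bool

    def __post_init__(self) -> None:
        if not self.member_read_ids:
            raise ValueError(f"allele {self.id!r}: no member reads")


@dataclass(frozen=True)
class AlleleGroup:
    """Cluster of alleles treated as one segregating unit."""

    label: str
    locus: str
    member_allele_ids: tuple[str, ...]
    support: float  # NaN for singleton groups

    @property
    def size(self) -> int:
        return len(self.member_allele_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with co-scored site counts."""

    labels: list[str]
    values: np.ndarray
    overlap_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if self.overlap_counts is None:
            self.overlap_counts = np.zeros((n, n), dtype=int)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def check_aligned(sequences: Sequence[str]) -> int:
    """Return the common alignment length or raise :class:`AlignmentError`."""
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise AlignmentError(
            f"sequences are not aligned to a common length: {sorted(lengths)}"
        )
    return lengths.pop() if lengths else 0
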