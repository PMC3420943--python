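"""Simulate per-locus allele pools by mutation from an ancestral CDS.

Each allele receives a fixed number of substitutions at distinct sites
drawn uniformly from the internal sites of the ancestor (first and last
codon are never touched).  Functional alleles are rejection-sampled to an
intact ORF; loss-of-function alleles additionally receive either an
internal stop substitution or a frame-shifting deletion (represented as
inline ``-`` gaps so the pool stays aligned to ancestral coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..allelecall.distance import pairwise_nt_diff
from ..annotate.orf import STOP_CODONS, scan_orf
from .config import LocusSpec

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SimAllele:
    id: str
    locus: str
    sequence: str  # aligned to the ancestral CDS ('-' marks deletions)
    functional: bool


def ancestral_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random intact ORF: ATG, n_codons-2 non-stop codons, TAA."""
    internal = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    body = "".join(_NONSTOP_CODONS[i] for i in internal)
    return "ATG" + body + "TAA"


def _is_intact_orf(seq: str) -> bool:
    if "-" in seq or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG"):
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        return False
    return all(c not in STOP_CODONS for c in codons[:-1])


def _substitute(
    ancestor: str, positions: np.ndarray, rng: np.random.Generator
) -> str:
    seq = list(ancestor)
    for pos in positions:
        current = seq[pos]
        choices = [b for b in "ACGT" if b != current]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _mutate_functional(
    ancestor: str, m: int, rng: np.random.Generator
) -> str:
    """m distinct internal substitutions, conditioned on an intact ORF.

    Positions are drawn once and kept; only the substituted bases are
    redrawn on rejection, so the positional process stays uniform.
    """
    length = len(ancestor)
    for _ in range(1000):
        positions = 3 + rng.choice(length - 6, size=m, replace=False)
        for _ in range(100):
            cand = _substitute(ancestor, positions, rng)
            if _is_intact_orf(cand):
                return cand
    raise RuntimeError("could not generate an intact functional allele")


def _inject_lof(seq: str, rng: np.random.Generator) -> str:
    n_codons = len(seq) // 3
    chars = list(seq)
    if rng.random() < 0.5:
        # premature stop in an internal codon
        codon_idx = int(rng.integers(1, n_codons - 1))
        stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        chars[3 * codon_idx : 3 * codon_idx + 3] = list(stop)
    else:
        # frame-shifting deletion of 1 or 2 bases, away from start/stop
        del_len = int(rng.integers(1, 3))
        pos = int(rng.integers(3, len(seq) - 3 - del_len))
        for k in range(del_len):
            chars[pos + k] = "-"
    return "".join(chars)


def simulate_allele_pool(
    locus_spec: LocusSpec, seed
) -> tuple[str, list[SimAllele]]:
    """Generate ``(ancestral_cds, alleles)`` for one locus.

    Functionality flags are set by construction and double-checked with
    the ORF scanner against the ancestor.
    """
    rng = np.random.default_rng(seed)
    ancestor = ancestral_cds(locus_spec.n_codons, rng)
    alleles: list[SimAllele] = []
    for i in range(locus_spec.n_alleles):
        for _ in range(200):
            functional = bool(rng.random() >= locus_spec.lof_rate)
            if functional:
                seq = _mutate_functional(
                    ancestor, locus_spec.mutation_count, rng
                )
            else:
                positions = 3 + rng.choice(
                    len(ancestor) - 6,
                    size=locus_spec.mutation_count,
                    replace=False,
                )
                seq = _inject_lof(
                    _substitute(ancestor, positions, rng), rng
                )
            if locus_spec.min_pairwise_diff > 0:
                too_close = any(
                    pairwise_nt_diff(seq, other.sequence)
                    < locus_spec.min_pairwise_diff
                    for other in alleles
                )
                if too_close or any(a.sequence == seq for a in alleles):
                    continue
            break
        else:
            raise RuntimeError(
                f"locus {locus_spec.name!r}: could not place allele {i} "
                f"at min_pairwise_diff={locus_spec.min_pairwise_diff}"
            )
        annotation = scan_orf(seq, ancestor)
        if annotation.is_functional_cds != functional:
            raise AssertionError(
                "generator functionality flag disagrees with ORF scan"
            )
        alleles.append(
            SimAllele(
                id=f"{locus_spec.name}-h{i + 1:02d}",
                locus=locus_spec.name,
                sequence=seq,
                functional=functional,
            )
        )
    return ancestor, alleles


def expected_pairwise_diff(m: int, n_codons: int) -> float:
    """Nominal expected pairwise difference between two alleles.

    Each allele mutates ``m`` distinct internal sites (of ``L = 3*n_codons
    - 6``) to a uniformly chosen different base.  Sites hit in exactly one
    allele always differ; sites hit in both differ with probability 2/3.
    """
    length = 3 * n_codons - 6
    return 2.0 * m * (1.0 - m / length) + (m * m / length) * (2.0 / 3.0)
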