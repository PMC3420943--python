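"""Scan aligned coding sequences for loss-of-function lesions.

An allele is compared against a designated intact reference CDS of the
same locus.  Three lesion kinds are recorded:

``frameshift_indel``
    a gap run (in either sequence) whose length is not a multiple of 3;
    position is the 1-based alignment column where the run starts.
``premature_stop``
    an in-frame stop codon — frame taken from the allele's own ungapped
    sequence, so it tracks through prior indels — lying strictly upstream
    of the reference stop codon; position is the 1-based codon index.
``start_loss``
    the allele's first codon is not ATG; position 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

LofKind = Literal["premature_stop", "frameshift_indel", "start_loss"]


@dataclass(frozen=True)
class LofEvent:
    kind: LofKind
    position: int  # 1-based codon index (stops/start) or alignment column (indels)


@dataclass(frozen=True)
class LofAnnotation:
    allele_id: str
    events: tuple[LofEvent, ...]

    @property
    def is_functional_cds(self) -> bool:
        return not self.events


def _ungap(seq: str) -> str:
    return seq.replace("-", "")


def validate_reference(reference_cds: str) -> None:
    """Reference must be an intact ORF: ATG start, terminal stop, no
    internal stop, length a multiple of 3."""
    ref = _ungap(reference_cds).upper()
    if len(ref) % 3 != 0:
        raise ValueError("reference CDS length is not a multiple of 3")
    if not ref.startswith(START_CODON):
        raise ValueError("reference CDS does not start with ATG")
    codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    if codons[-1] not in STOP_CODONS:
        raise ValueError("reference CDS does not end with a stop codon")
    for i, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS:
            raise ValueError(f"reference CDS has internal stop at codon {i + 1}")


def scan_orf(
    allele_cds: str, reference_cds: str, allele_id: str = ""
) -> LofAnnotation:
    """Annotate loss-of-function lesions in ``allele_cds``.

    Both sequences must be aligned to the same length; the reference must
    be an intact ORF (otherwise a configuration ``ValueError`` is raised).
    """
    if len(allele_cds) != len(reference_cds):
        raise ValueError("allele and reference are not aligned to equal length")
    validate_reference(reference_cds)
    allele = allele_cds.upper()
    ref = reference_cds.upper()

    events: list[LofEvent] = []

    # --- gap runs (deletions in the allele, insertions via gaps in the ref)
    run_kind: str | None = None
    run_start = 0
    run_len = 0

    def flush() -> None:
        nonlocal run_kind, run_len
        if run_kind is not None and run_len % 3 != 0:
            events.append(LofEvent("frameshift_indel", run_start + 1))
        run_kind = None
        run_len = 0

    for col, (ca, cr) in enumerate(zip(allele, ref)):
        a_gap, r_gap = ca == "-", cr == "-"
        if a_gap and r_gap:
            flush()
            continue
        kind = "del" if a_gap else "ins" if r_gap else None
        if kind is None:
            flush()
            continue
        if kind != run_kind:
            flush()
            run_kind = kind
            run_start = col
        run_len += 1
    flush()

    # --- allele bases with their alignment columns; reference stop column
    allele_bases: list[str] = []
    allele_cols: list[int] = []
    ref_index = 0
    ref_len = len(_ungap(ref))
    ref_stop_start_col = len(ref)  # fallback: past the end
    for col, (ca, cr) in enumerate(zip(allele, ref)):
        if ca != "-":
            allele_bases.append(ca)
            allele_cols.append(col)
        if cr != "-":
            if ref_index == ref_len - 3:
                ref_stop_start_col = col
            ref_index += 1

    # --- start codon
    first_codon = "".join(allele_bases[:3])
    if first_codon != START_CODON:
        events.append(LofEvent("start_loss", 1))

    # --- premature in-frame stops (allele's own reading frame)
    for i in range(len(allele_bases) // 3):
        codon = "".join(allele_bases[3 * i : 3 * i + 3])
        if codon in STOP_CODONS and allele_cols[3 * i + 2] < ref_stop_start_col:
            events.append(LofEvent("premature_stop", i + 1))

    events.sort(key=lambda e: (e.position, e.kind))
    return LofAnnotation(allele_id=allele_id, events=tuple(events))
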