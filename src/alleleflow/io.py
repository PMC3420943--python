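"""Readers and writers for the on-disk dialect (FASTA, TSV, newick, JSON).

Clone FASTA headers are pipe-separated:
``>cloneID|individual|population|species|locus``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .allelecall.types import Allele, AlleleGroup, CloneRead


def read_clone_fasta(path) -> list[CloneRead]:
    """Parse a clone FASTA with pipe-separated provenance headers."""
    reads = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        if len(fields) != 5:
            raise ValueError(
                f"{path}: header {record.description!r} does not have 5 "
                "pipe-separated fields (cloneID|individual|population|species|locus)"
            )
        clone_id, individual, population, species, locus = fields
        reads.append(
            CloneRead(
                id=clone_id,
                locus=locus,
                individual=individual,
                population=population,
                species=species,
                sequence=str(record.seq).upper(),
            )
        )
    return reads


def write_alleles_fasta(alleles: Iterable[Allele], path) -> None:
    with Path(path).open("w") as fh:
        for allele in alleles:
            fh.write(f">{allele.id}\n{allele.consensus}\n")


def write_allele_groups_tsv(
    alleles: Sequence[Allele], groups: Sequence[AlleleGroup], path
) -> None:
    singleton = {a.id: a.is_singleton for a in alleles}
    rows = []
    for group in groups:
        for allele_id in group.member_allele_ids:
            rows.append(
                {
                    "locus": group.locus,
                    "allele_id": allele_id,
                    "group_label": group.label,
                    "support": group.support,
                    "is_singleton": singleton.get(allele_id, False),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
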