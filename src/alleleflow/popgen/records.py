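"""Per-individual records of expressed allele groups and phenotypes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd


@dataclass
class IndividualRecord:
    """Expression-inferred genotype information for one individual."""

    id: str
    species: str
    population: str
    expressed: dict[str, frozenset[str]] = field(default_factory=dict)
    intensity: dict[tuple[str, str], float] = field(default_factory=dict)
    phenotype: dict[str, float] = field(default_factory=dict)

    def expressed_at(self, locus: str) -> frozenset[str]:
        return self.expressed.get(locus, frozenset())


def records_from_tables(
    expression: pd.DataFrame,
    phenotype: pd.DataFrame | None = None,
    detection_floor: float = 0.0,
) -> list[IndividualRecord]:
    """Build :class:`IndividualRecord` objects from long-format tables.

    ``expression`` needs columns ``individual, species, population, locus,
    allele_group, normalized_intensity``; rows at or below
    ``detection_floor`` do not enter the expressed set.  ``phenotype``
    (optional) needs ``individual, compound, amount_ug``.
    """
    required = {
        "individual",
        "species",
        "population",
        "locus",
        "allele_group",
        "normalized_intensity",
    }
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if (expression["normalized_intensity"] < 0).any():
        raise ValueError("negative expression intensity")

    records: dict[str, IndividualRecord] = {}
    for row in expression.itertuples(index=False):
        rec = records.get(row.individual)
        if rec is None:
            rec = IndividualRecord(
                id=row.individual,
                species=row.species,
                population=row.population,
            )
            records[row.individual] = rec
        elif rec.species != row.species or rec.population != row.population:
            raise ValueError(
                f"inconsistent provenance for individual {row.individual!r}"
            )
        rec.intensity[(row.locus, row.allele_group)] = float(
            row.normalized_intensity
        )
        if row.normalized_intensity > detection_floor:
            rec.expressed[row.locus] = rec.expressed.get(
                row.locus, frozenset()
            ) | {row.allele_group}

    if phenotype is not None:
        for row in phenotype.itertuples(index=False):
            if row.individual in records:
                records[row.individual].phenotype[row.compound] = float(
                    row.amount_ug
                )
    return [records[k] for k in sorted(records)]


def group_records(
    records: list[IndividualRecord], grouping: str
) -> Mapping[str, list[IndividualRecord]]:
    """Partition records by ``"species"`` or ``"population"``."""
    if grouping not in ("species", "population"):
        raise ValueError(f"unknown grouping {grouping!r}")
    out: dict[str, list[IndividualRecord]] = {}
    for rec in records:
        key = rec.species if grouping == "species" else rec.population
        out.setdefault(key, []).append(rec)
    return out
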