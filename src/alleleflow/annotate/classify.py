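"""Classify allele groups per species into expression/functionality categories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import pandas as pd

from ..allelecall.types import AlleleGroup
from .orf import LofAnnotation

DEFAULT_DETECTION_FLOOR = 0.05

CATEGORIES = (
    "functional_expressed",
    "nonfunctional_expressed",
    "non_expressed",
)


@dataclass(frozen=True)
class AlleleCategory:
    group_label: str
    locus: str
    species: str
    category: str


def _group_functionality(
    group: AlleleGroup, annotations: Mapping[str, LofAnnotation]
) -> bool:
    """Majority functionality of member alleles; ties are nonfunctional."""
    flags = []
    for allele_id in group.member_allele_ids:
        if allele_id not in annotations:
            raise KeyError(f"no LoF annotation for allele {allele_id!r}")
        flags.append(annotations[allele_id].is_functional_cds)
    n_func = sum(flags)
    return n_func > len(flags) - n_func


def classify_alleles(
    groups: Sequence[AlleleGroup],
    annotations: Mapping[str, LofAnnotation],
    expression: pd.DataFrame,
    species: Sequence[str] | None = None,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
    force_nonfunctional: Collection[tuple[str, str]] = (),
) -> list[AlleleCategory]:
    """Assign each (allele group, species) pair to one of three categories.

    Parameters
    ----------
    expression
        Long table with columns ``individual``, ``species``, ``locus``,
        ``allele_group``, ``normalized_intensity``.
    species
        Species to classify for; defaults to those present in the table.
    detection_floor
        A group counts as expressed in a species when any individual of
        that species shows intensity strictly above this floor.
    force_nonfunctional
        ``(locus, group_label)`` pairs with external evidence of
        nonfunctionality (e.g. a biochemical assay); when expressed these
        are categorised nonfunctional regardless of the ORF scan.
    """
    required = {"individual", "species", "locus", "allele_group", "normalized_intensity"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")

    by_locus: dict[str, dict[str, AlleleGroup]] = {}
    for group in groups:
        by_locus.setdefault(group.locus, {})[group.label] = group

    for (locus, label), _ in expression.groupby(["locus", "allele_group"]):
        if locus not in by_locus or label not in by_locus[locus]:
            raise ValueError(
                f"expression table references unknown group {label!r} at locus {locus!r}"
            )

    if species is None:
        species = sorted(expression["species"].unique())
    forced = set(force_nonfunctional)

    expressed = expression[expression["normalized_intensity"] > detection_floor]
    seen = set(
        map(tuple, expressed[["species", "locus", "allele_group"]].drop_duplicates().to_numpy())
    )

    out: list[AlleleCategory] = []
    for group in groups:
        functional = _group_functionality(group, annotations)
        for sp in species:
            if (sp, group.locus, group.label) not in seen:
                category = "non_expressed"
            elif (group.locus, group.label) in forced:
                category = "nonfunctional_expressed"
            elif functional:
                category = "functional_expressed"
            else:
                category = "nonfunctional_expressed"
            out.append(
                AlleleCategory(
                    group_label=group.label,
                    locus=group.locus,
                    species=sp,
                    category=category,
                )
            )
    return out
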