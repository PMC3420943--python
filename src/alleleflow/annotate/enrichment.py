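"""Per-group enrichment of nonfunctional alleles (one-sided Fisher test).

Each allele group is compared against the pool of all other groups in a
2x2 table {this group, other groups} x {nonfunctional, functional}; the
reported p-value is the one-sided (greater) hypergeometric tail, i.e. the
probability of seeing at least as many nonfunctional alleles in the group
under random assortment.
"""

from __future__ import annotations

import warnings
from typing import Mapping

from scipy import stats


def lof_enrichment(
    group_counts: Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """One-sided Fisher exact p per group.

    Parameters
    ----------
    group_counts
        Mapping group label -> ``(nonfunctional, total)`` allele counts.
        Groups with a total of 0 are skipped with a warning.
    """
    totals = {}
    for label, (bad, total) in group_counts.items():
        if bad < 0 or total < 0 or bad > total:
            raise ValueError(f"group {label!r}: invalid counts ({bad}, {total})")
        totals[label] = (bad, total)
    pooled_bad = sum(b for b, _ in totals.values())
    pooled_total = sum(t for _, t in totals.values())
    if pooled_total < 1:
        raise ValueError("no alleles in any group")

    pvalues: dict[str, float] = {}
    for label, (bad, total) in totals.items():
        if total == 0:
            warnings.warn(f"group {label!r} has no alleles; skipped")
            continue
        other_bad = pooled_bad - bad
        other_total = pooled_total - total
        table = [
            [bad, total - bad],
            [other_bad, other_total - other_bad],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        pvalues[label] = float(p)
    return pvalues
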