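"""Multiallelic Weir & Cockerham (1984) theta from diploid genotypes.

Per allele, three variance components are computed — a (among
populations), b (among individuals within populations), c (within
individuals) — and theta is the ratio of summed a to summed a+b+c over
alleles.  Estimates are not truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

Genotype = tuple[Hashable, Hashable]


@dataclass(frozen=True)
class Theta:
    """A theta estimate with an optional degeneracy flag."""

    value: float
    flag: str | None = None

    def __float__(self) -> float:
        return self.value


def wc_fst(genotypes_by_pop: Mapping[str, Sequence[Genotype]]) -> Theta:
    """Weir-Cockerham theta over >=2 populations of diploid genotypes.

    Parameters
    ----------
    genotypes_by_pop
        Mapping population -> sequence of unordered diploid genotypes
        (pairs of allele labels).

    Returns
    -------
    Theta
        ``value`` is NaN with flag ``"monomorphic"`` when fewer than two
        distinct alleles are present, and NaN with flag
        ``"insufficient_sample"`` when the mean sample size does not allow
        the within-population components to be estimated.
    """
    pops = [p for p in genotypes_by_pop if len(genotypes_by_pop[p]) > 0]
    if len(pops) < 2:
        raise ValueError("need at least two populations with genotypes")
    counts = np.array([len(genotypes_by_pop[p]) for p in pops], dtype=float)
    r = len(pops)
    n_tot = counts.sum()
    n_bar = n_tot / r

    alleles = sorted(
        {a for p in pops for g in genotypes_by_pop[p] for a in g}, key=str
    )
    if len(alleles) < 2:
        return Theta(math.nan, "monomorphic")
    if n_bar <= 1:
        return Theta(math.nan, "insufficient_sample")

    n_c = (n_tot - float(np.sum(counts**2)) / n_tot) / (r - 1)

    index = {a: k for k, a in enumerate(alleles)}
    # per-pop allele frequencies and heterozygote frequencies
    p_mat = np.zeros((r, len(alleles)))
    h_mat = np.zeros((r, len(alleles)))
    for i, pop in enumerate(pops):
        for g in genotypes_by_pop[pop]:
            a1, a2 = g
            p_mat[i, index[a1]] += 1
            p_mat[i, index[a2]] += 1
            if a1 != a2:
                h_mat[i, index[a1]] += 1
                h_mat[i, index[a2]] += 1
        p_mat[i] /= 2 * counts[i]
        h_mat[i] /= counts[i]

    w = counts / n_tot
    p_bar = w @ p_mat
    h_bar = w @ h_mat
    s2 = (counts[:, None] * (p_mat - p_bar) ** 2).sum(axis=0) / (
        (r - 1) * n_bar
    )

    pq = p_bar * (1.0 - p_bar)
    inner = pq - (r - 1) / r * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (
        inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0

    denom = float((a + b + c).sum())
    if denom == 0.0:
        return Theta(math.nan, "monomorphic")
    return Theta(float(a.sum()) / denom, None)
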