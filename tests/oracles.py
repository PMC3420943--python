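"""Independent brute-force oracles used to cross-check the implementations.

Each oracle recomputes a quantity from first principles along a different
route than the package code (sums of squares instead of closed forms,
explicit pathway enumeration instead of per-codon formulas, character
loops instead of vectorised counting) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


# --------------------------------------------------------------------------
# Weir-Cockerham theta via the ANOVA sums-of-squares decomposition
# --------------------------------------------------------------------------
def wc_theta_oracle(genotypes_by_pop) -> float:
    """theta from MSP/MSI/MSG mean squares computed per allele."""
    pops = sorted(genotypes_by_pop)
    r = len(pops)
    n_i = np.array([len(genotypes_by_pop[p]) for p in pops], dtype=float)
    n_tot = n_i.sum()
    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    alleles = sorted(
        {a for p in pops for g in genotypes_by_pop[p] for a in g}, key=str
    )
    a_t = b_t = c_t = 0.0
    for allele in alleles:
        copies = [
            1.0 * (x == allele)
            for p in pops
            for g in genotypes_by_pop[p]
            for x in g
        ]
        grand = float(np.mean(copies))
        ssg = ssi = ssp = 0.0
        for p in pops:
            ind_means = []
            for g in genotypes_by_pop[p]:
                vals = [1.0 * (x == allele) for x in g]
                m = float(np.mean(vals))
                ssg += sum((v - m) ** 2 for v in vals)
                ind_means.append(m)
            pm = float(np.mean(ind_means))
            ssi += 2.0 * sum((m - pm) ** 2 for m in ind_means)
            ssp += 2.0 * len(ind_means) * (pm - grand) ** 2
        msp = ssp / (r - 1)
        msi = ssi / (n_tot - r)
        msg = ssg / n_tot
        a_t += (msp - msi) / (2.0 * n_c)
        b_t += (msi - msg) / 2.0
        c_t += msg
    return a_t / (a_t + b_t + c_t)


# --------------------------------------------------------------------------
# UPGMA by recomputing every cluster distance from the original matrix
# --------------------------------------------------------------------------
def upgma_oracle(labels, matrix) -> set[tuple[frozenset, float]]:
    """Return {(leafset, height)} for all internal nodes.

    Cluster distances are recomputed at every step as the plain average of
    the original leaf-pair distances (the textbook UPGMA definition),
    rather than by the iterative weighted-average update.
    """
    matrix = np.asarray(matrix, dtype=float)
    index = {lab: i for i, lab in enumerate(labels)}

    def cluster_dist(a: frozenset, b: frozenset) -> float:
        return float(
            np.mean([matrix[index[x], index[y]] for x in a for y in b])
        )

    clusters = {min(frozenset([lab])): frozenset([lab]) for lab in labels}
    nodes: set[tuple[frozenset, float]] = set()
    while len(clusters) > 1:
        best = None
        for ka, kb in itertools.combinations(sorted(clusters), 2):
            cand = (cluster_dist(clusters[ka], clusters[kb]), ka, kb)
            if best is None or cand < best:
                best = cand
        d, ka, kb = best
        merged = clusters.pop(ka) | clusters.pop(kb)
        nodes.add((merged, d / 2.0))
        clusters[min(ka, kb)] = merged
    return nodes


# --------------------------------------------------------------------------
# Nei-Gojobori counts by explicit recursive pathway enumeration
# --------------------------------------------------------------------------
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def codon_syn_sites_oracle(codon: str) -> float:
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            if _translate(codon[:pos] + alt + codon[pos + 1 :]) == _translate(
                codon
            ):
                syn += 1
    return syn / 3.0


def codon_pathway_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over every mutational pathway,
    enumerated recursively one substitution at a time."""
    results = []

    def walk(current: str, syn: int, nonsyn: int) -> None:
        remaining = [i for i in range(3) if current[i] != codon_b[i]]
        if not remaining:
            results.append((syn, nonsyn))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _translate(current) == _translate(nxt):
                walk(nxt, syn + 1, nonsyn)
            else:
                walk(nxt, syn, nonsyn + 1)

    walk(codon_a, 0, 0)
    syn = sum(s for s, _ in results) / len(results)
    nonsyn = sum(n for _, n in results) / len(results)
    return syn, nonsyn


# --------------------------------------------------------------------------
# Nucleotide difference counting by a character loop with run-length logic
# --------------------------------------------------------------------------
def nt_diff_oracle(seq_a: str, seq_b: str, gap_policy: str = "indel_as_diff") -> int:
    diffs = 0
    in_run = False
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        a_gap, b_gap = ca == "-", cb == "-"
        if a_gap and b_gap:
            continue
        if a_gap != b_gap:
            if gap_policy == "indel_as_diff" and not in_run:
                diffs += 1
            in_run = True
            continue
        in_run = False
        if ca in "ACGT" and cb in "ACGT" and ca != cb:
            diffs += 1
    return diffs


# --------------------------------------------------------------------------
# Exact chi-square null distribution for 2x2 tables with fixed margins
# --------------------------------------------------------------------------
def chi2_2x2_exact_p(table) -> float:
    """P(chi2 >= observed) by enumerating all tables with the margins."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n

    def chi2_of(a: float) -> float:
        t = np.array(
            [[a, row[0] - a], [col[0] - a, row[1] - col[0] + a]], dtype=float
        )
        return float(((t - expected) ** 2 / expected).sum())

    obs = chi2_of(table[0, 0])
    lo = int(max(0, col[0] - row[1]))
    hi = int(min(row[0], col[0]))
    total_p = 0.0
    for a in range(lo, hi + 1):
        prob = (
            math.comb(int(row[0]), a)
            * math.comb(int(row[1]), int(col[0]) - a)
            / math.comb(int(n), int(col[0]))
        )
        if chi2_of(a) >= obs - 1e-12:
            total_p += prob
    return total_p
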