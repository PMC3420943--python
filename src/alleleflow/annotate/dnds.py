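"""Pairwise Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

Synonymous/nonsynonymous site counts are computed per codon (a position
contributes the fraction of its three possible changes that are
synonymous; changes creating a stop codon count as nonsynonymous) and
averaged over the two sequences.  Observed differences in codons hit at
multiple positions are averaged over all orderings of the mutational
pathway.  Proportions are corrected with d = -3/4 ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_AA.update({codon: "*" for codon in _TABLE.stop_codons})
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    ratio: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    flags: tuple[str, ...] = field(default=())


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3)."""
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _AA[mutant] == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over all mutational pathways."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_syn = total_nonsyn = 0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _AA[cur] == _AA[nxt]:
                total_syn += 1
            else:
                total_nonsyn += 1
            cur = nxt
        n_paths += 1
    return total_syn / n_paths, total_nonsyn / n_paths


def _usable_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences are not aligned to equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned length is not a multiple of 3")
    pairs = []
    for i in range(0, len(cds_a), 3):
        ca = cds_a[i : i + 3].upper()
        cb = cds_b[i : i + 3].upper()
        if "-" in ca or "-" in cb:
            continue  # pairwise deletion of gap-containing codons
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue  # stop codons excluded from the counting frame
        pairs.append((ca, cb))
    return pairs


def ng86_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float, int]:
    """Raw NG86 quantities ``(S, N, Sd, Nd, n_codons)`` for an aligned pair."""
    pairs = _usable_codons(cds_a, cds_b)
    syn_sites = 0.0
    syn_diffs = 0.0
    nonsyn_diffs = 0.0
    for ca, cb in pairs:
        syn_sites += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
    nonsyn_sites = 3.0 * len(pairs) - syn_sites
    return syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs, len(pairs)


def _jc_correct(p: float, label: str, flags: list[str]) -> float:
    if p >= 0.75:
        flags.append(f"jc_undefined_{label}")
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei-Gojobori dN, dS and their ratio for one aligned CDS pair.

    The ratio is NaN (flag ``ratio_undefined``) when dS = 0; proportions
    at or beyond the Jukes-Cantor saturation point 3/4 are flagged.
    """
    syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs, n_codons = ng86_counts(
        cds_a, cds_b
    )
    flags: list[str] = []
    if n_codons == 0:
        flags.append("no_usable_codons")
        return DnDsResult(
            math.nan, math.nan, math.nan, 0.0, 0.0, 0.0, 0.0, 0, tuple(flags)
        )
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ds = _jc_correct(ps, "synonymous", flags)
    dn = _jc_correct(pn, "nonsynonymous", flags)
    if not (ds > 0):  # catches ds == 0 and ds NaN
        flags.append("ratio_undefined")
        ratio = math.nan
    else:
        ratio = dn / ds
    return DnDsResult(
        dn=dn,
        ds=ds,
        ratio=ratio,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        n_codons=n_codons,
        flags=tuple(flags),
    )
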