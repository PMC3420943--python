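"""Simulate a diploid island-model metapopulation end to end.

Population allele frequencies are Dirichlet draws around base frequencies
(Balding-Nichols device) with F = 1/(1 + 4*N*m), which gives a
closed-form handle on the expected differentiation.  Under divergent
selection the species lineages use different base frequencies weighted
toward (or away from) the functional alleles.  Individuals draw two
allele copies per locus; expression emulates housekeeping-normalized
band intensities with multiplicative lognormal noise; the compound
phenotype is linear in summed functional expression at the causal locus
plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..allelecall.types import CloneRead
from .config import LocusSpec, SimulationConfig
from .pool import SimAllele, simulate_allele_pool

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def parametric_theta(
    freqs: np.ndarray, weights: Sequence[float] | np.ndarray
) -> float:
    """Large-sample theta implied by realized group allele frequencies.

    ``freqs`` is an (r groups x k alleles) frequency matrix, ``weights``
    the group sample sizes.  Returns
    sum_a s2_a / sum_a (pbar_a(1-pbar_a) + s2_a/r), the limit of the
    Weir-Cockerham estimator as within-group sample sizes grow.
    """
    p = np.asarray(freqs, dtype=float)
    n = np.asarray(weights, dtype=float)
    r = p.shape[0]
    if r < 2:
        raise ValueError("need at least two groups")
    n_bar = n.mean()
    w = n / n.sum()
    p_bar = w @ p
    s2 = (n[:, None] * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    denom = float((p_bar * (1 - p_bar) + s2 / r).sum())
    if denom == 0.0:
        return float("nan")
    return float(s2.sum() / denom)


def island_fixation_index(migration_rate: float, pop_size: int) -> float:
    """F = 1/(1 + 4*N*m); 1 when migration is zero."""
    if migration_rate == 0.0:
        return 1.0
    return 1.0 / (1.0 + 4.0 * pop_size * migration_rate)


@dataclass(frozen=True)
class IndividualTruth:
    id: str
    species: str
    population: str
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class TruthLedger:
    """Ground truth emitted alongside every synthetic dataset."""

    genotypes: dict[str, dict[str, tuple[str, str]]]
    functional: dict[str, bool]
    parametric_fst: dict[str, dict[str, float]]
    expression_effect: float
    causal_locus: str
    causal_compound: str
    species_of: dict[str, str]
    population_of: dict[str, str]
    ancestors: dict[str, str]
    allele_sequences: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "genotypes": {
                ind: {locus: list(pair) for locus, pair in loci.items()}
                for ind, loci in self.genotypes.items()
            },
            "functional": self.functional,
            "parametric_fst": self.parametric_fst,
            "expression_effect": self.expression_effect,
            "causal_locus": self.causal_locus,
            "causal_compound": self.causal_compound,
            "species_of": self.species_of,
            "population_of": self.population_of,
            "ancestors": self.ancestors,
            "allele_sequences": self.allele_sequences,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_clone_reads(
    individual: IndividualTruth,
    locus: str,
    allele_sequences: Mapping[str, str],
    clones_per_allele: int,
    error_rate: float,
    seed,
) -> list[CloneRead]:
    """Emit ``2 * clones_per_allele`` reads for one individual and locus.

    Each of the two true allele copies yields ``clones_per_allele`` reads
    carrying independent per-base substitution errors at ``error_rate``
    (gap positions are never perturbed).  Read ids encode the source
    allele and copy so that every read maps to exactly one true allele.
    """
    if locus not in individual.genotypes:
        raise ValueError(
            f"individual {individual.id!r} has no genotype at {locus!r}"
        )
    rng = np.random.default_rng(seed)
    reads: list[CloneRead] = []
    for copy_idx, allele_id in enumerate(individual.genotypes[locus], start=1):
        template = allele_sequences[allele_id]
        codes = np.array([_BASE_INDEX.get(ch, -1) for ch in template])
        mutable = codes >= 0
        for k in range(1, clones_per_allele + 1):
            hit = (rng.random(len(template)) < error_rate) & mutable
            seq = template
            if hit.any():
                chars = list(template)
                for pos in np.flatnonzero(hit):
                    shift = int(rng.integers(1, 4))
                    chars[pos] = _BASES[(codes[pos] + shift) % 4]
                seq = "".join(chars)
            reads.append(
                CloneRead(
                    id=f"{individual.id}.{allele_id}.{copy_idx}.{k}",
                    locus=locus,
                    individual=individual.id,
                    population=individual.population,
                    species=individual.species,
                    sequence=seq,
                )
            )
    return reads


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reads: dict[str, list[CloneRead]]
    expression: pd.DataFrame
    phenotype: pd.DataFrame
    pools: dict[str, list[SimAllele]]
    ancestors: dict[str, str]
    truth: TruthLedger

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA/TSV/JSON artifacts; returns emitted paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for locus, reads in self.reads.items():
            fasta = outdir / f"clones_{locus}.fasta"
            with fasta.open("w") as fh:
                for read in reads:
                    fh.write(f">{read.header()}\n{read.sequence}\n")
            paths[f"clones_{locus}"] = str(fasta)
        for name, frame in (
            ("expression", self.expression),
            ("phenotype", self.phenotype),
        ):
            path = outdir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
            paths[name] = str(path)
        truth_path = outdir / "truth.json"
        self.truth.to_json(truth_path)
        paths["truth"] = str(truth_path)
        return paths


def _base_frequencies(
    spec: LocusSpec,
    alleles: list[SimAllele],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Per-species base frequency vectors for one locus."""
    k = len(alleles)
    ancestral = rng.dirichlet(np.ones(k))
    if spec.selection == "neutral":
        return [ancestral] * config.n_species
    favored = np.array([a.functional for a in alleles], dtype=bool)
    if favored.all() or not favored.any():
        favored = np.zeros(k, dtype=bool)
        favored[: max(1, k // 2)] = True  # fall back to a disjoint split
    w = config.divergent_favored_weight
    bases = []
    for s in range(config.n_species):
        weight_favored = w if s == 0 else 1.0 - w
        base = np.where(
            favored,
            weight_favored / favored.sum(),
            (1.0 - weight_favored) / (~favored).sum(),
        )
        bases.append(base / base.sum())
    return bases


def _population_frequencies(
    bases: list[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    fix = island_fixation_index(
        config.migration_rate, config.individuals_per_population
    )
    freqs: dict[str, np.ndarray] = {}
    species_names = config.species_names()
    for sp, pop in config.population_names():
        base = bases[species_names.index(sp)]
        if fix >= 0.999:
            one_hot = np.zeros(len(base))
            one_hot[rng.choice(len(base), p=base)] = 1.0
            freqs[pop] = one_hot
        else:
            alpha = base * (1.0 - fix) / fix
            freqs[pop] = rng.dirichlet(np.maximum(alpha, 1e-9))
    return freqs


def simulate_metapopulation(
    config: SimulationConfig, with_reads: bool = True
) -> tuple[SyntheticDataset, TruthLedger]:
    """Generate the full synthetic dataset plus its truth ledger.

    All randomness derives from ``config.seed`` through fixed-offset
    substreams, so identical configs yield byte-identical outputs.
    ``with_reads=False`` skips clone-read generation (frequency- and
    phenotype-level studies only).
    """
    pools: dict[str, list[SimAllele]] = {}
    ancestors: dict[str, str] = {}
    functional: dict[str, bool] = {}
    allele_sequences: dict[str, str] = {}
    for li, spec in enumerate(config.loci):
        ancestor, alleles = simulate_allele_pool(spec, [config.seed, 0, li])
        pools[spec.name] = alleles
        ancestors[spec.name] = ancestor
        for allele in alleles:
            functional[allele.id] = allele.functional
            allele_sequences[allele.id] = allele.sequence

    individuals: list[IndividualTruth] = []
    for sp, pop in config.population_names():
        for k in range(config.individuals_per_population):
            individuals.append(
                IndividualTruth(
                    id=f"{pop}_i{k + 1:03d}", species=sp, population=pop
                )
            )

    parametric: dict[str, dict[str, float]] = {}
    for li, spec in enumerate(config.loci):
        alleles = pools[spec.name]
        ids = [a.id for a in alleles]
        rng_f = np.random.default_rng([config.seed, 1, li])
        bases = _base_frequencies(spec, alleles, config, rng_f)
        pop_freqs = _population_frequencies(bases, config, rng_f)

        rng_g = np.random.default_rng([config.seed, 2, li])
        pop_order = [pop for _, pop in config.population_names()]
        for ind in individuals:
            draw = rng_g.choice(len(ids), size=2, p=pop_freqs[ind.population])
            pair = tuple(sorted(ids[i] for i in draw))
            ind.genotypes[spec.name] = pair  # type: ignore[index]

        # parametric theta from the drawn island frequencies (the quantity
        # the Weir-Cockerham estimator is unbiased for)
        n_per_pop = float(config.individuals_per_population)
        pop_matrix = np.stack([pop_freqs[p] for p in pop_order])
        pop_theta = parametric_theta(
            pop_matrix, np.full(len(pop_order), n_per_pop)
        )
        species_names = config.species_names()
        sp_matrix = np.stack(
            [
                np.mean(
                    [
                        pop_freqs[pop]
                        for sp2, pop in config.population_names()
                        if sp2 == sp
                    ],
                    axis=0,
                )
                for sp in species_names
            ]
        )
        sp_theta = (
            parametric_theta(
                sp_matrix,
                np.full(
                    len(species_names),
                    n_per_pop * config.populations_per_species,
                ),
            )
            if len(species_names) >= 2
            else float("nan")
        )
        parametric[spec.name] = {"population": pop_theta, "species": sp_theta}

    # --- expression
    rng_e = np.random.default_rng([config.seed, 3])
    expr_rows = []
    for ind in individuals:
        for spec in config.loci:
            pair = ind.genotypes[spec.name]
            copies: dict[str, int] = {}
            for allele_id in pair:
                copies[allele_id] = copies.get(allele_id, 0) + 1
            for allele_id in sorted(copies):
                mult = config.regulation_multiplier(ind.species, spec.name)
                if mult > 0:
                    intensity = (
                        mult
                        * copies[allele_id]
                        * float(
                            np.exp(
                                rng_e.normal(0.0, config.expression_noise_sd)
                            )
                        )
                    )
                else:
                    intensity = 0.0
                expr_rows.append(
                    {
                        "individual": ind.id,
                        "species": ind.species,
                        "population": ind.population,
                        "locus": spec.name,
                        "allele_group": allele_id,
                        "normalized_intensity": intensity,
                    }
                )
    expression = pd.DataFrame(expr_rows)

    # --- phenotype
    rng_p = np.random.default_rng([config.seed, 4])
    causal = config.resolved_causal_locus()
    signal_of = {}
    for ind in individuals:
        rows = expression[
            (expression["individual"] == ind.id)
            & (expression["locus"] == causal)
        ]
        signal = sum(
            row.normalized_intensity
            for row in rows.itertuples()
            if functional[row.allele_group]
        )
        signal_of[ind.id] = signal
    pheno_rows = []
    for ind in individuals:
        amount = config.expression_effect * signal_of[ind.id]
        if config.noise_sd > 0:
            amount += float(rng_p.normal(0.0, config.noise_sd))
        amount = max(amount, 0.0)
        background = float(np.exp(rng_p.normal(1.0, 0.3)))
        total = amount + background
        for compound, value in (
            (config.causal_compound, amount),
            (config.background_compound, background),
        ):
            pheno_rows.append(
                {
                    "individual": ind.id,
                    "compound": compound,
                    "amount_ug": value,
                    "relative_proportion": value / total if total > 0 else 0.0,
                }
            )
    phenotype = pd.DataFrame(pheno_rows)

    # --- clone reads
    reads: dict[str, list[CloneRead]] = {}
    if with_reads:
        for li, spec in enumerate(config.loci):
            locus_reads: list[CloneRead] = []
            for ii, ind in enumerate(individuals):
                locus_reads.extend(
                    generate_clone_reads(
                        ind,
                        spec.name,
                        allele_sequences,
                        config.clones_per_allele,
                        config.clone_error_rate,
                        [config.seed, 5, li, ii],
                    )
                )
            reads[spec.name] = locus_reads

    truth = TruthLedger(
        genotypes={ind.id: dict(ind.genotypes) for ind in individuals},
        functional=functional,
        parametric_fst=parametric,
        expression_effect=config.expression_effect,
        causal_locus=causal,
        causal_compound=config.causal_compound,
        species_of={ind.id: ind.species for ind in individuals},
        population_of={ind.id: ind.population for ind in individuals},
        ancestors=ancestors,
        allele_sequences=allele_sequences,
    )
    dataset = SyntheticDataset(
        config=config,
        reads=reads,
        expression=expression,
        phenotype=phenotype,
        pools=pools,
        ancestors=ancestors,
        truth=truth,
    )
    return dataset, truth
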