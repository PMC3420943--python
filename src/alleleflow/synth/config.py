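"""Simulation configuration for the synthetic-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LocusSpec:
    """Specification for one simulated locus.

    ``mutation_count`` substitutions are applied per allele relative to
    the ancestral CDS; ``lof_rate`` is the probability that an allele
    carries an injected loss-of-function lesion (internal stop or
    frame-shifting deletion).  ``selection`` is ``"neutral"`` (island
    model around one ancestral frequency vector) or ``"divergent"``
    (functional-allele frequency differs between species lineages).
    ``min_pairwise_diff`` > 0 rejection-samples alleles until all pairs
    differ by at least that many nucleotides.
    """

    name: str
    n_codons: int = 100
    mutation_count: int = 5
    n_alleles: int = 6
    lof_rate: float = 0.0
    selection: str = "neutral"
    min_pairwise_diff: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 30:
            raise ValueError(
                f"locus {self.name!r}: CDS must be at least 30 codons"
            )
        if self.n_alleles < 1 or self.mutation_count < 0:
            raise ValueError(f"locus {self.name!r}: counts must be >= 1")
        if not 0.0 <= self.lof_rate <= 1.0:
            raise ValueError(f"locus {self.name!r}: lof_rate outside [0,1]")
        if self.selection not in ("neutral", "divergent"):
            raise ValueError(
                f"locus {self.name!r}: unknown selection mode {self.selection!r}"
            )
        if self.min_pairwise_diff < 0:
            raise ValueError(f"locus {self.name!r}: min_pairwise_diff < 0")

    @property
    def cds_length(self) -> int:
        return 3 * self.n_codons


@dataclass(frozen=True)
class SimulationConfig:
    """Full design of a synthetic metapopulation run.

    ``migration_rate`` controls differentiation through a
    Balding-Nichols-style island model: population allele frequencies are
    Dirichlet draws around the base frequencies with F =
    1 / (1 + 4*N*m), N being individuals per population.
    ``regulation`` maps ``(species, locus)`` to an expression on/off
    multiplier (default on); ``expression_effect`` is the slope of
    compound amount (ug) per unit summed functional expression at the
    causal locus.
    """

    loci: tuple[LocusSpec, ...]
    n_species: int = 2
    populations_per_species: int = 2
    individuals_per_population: int = 10
    migration_rate: float = 0.1
    clones_per_allele: int = 3
    clone_error_rate: float = 0.0
    expression_effect: float = 2.0
    noise_sd: float = 0.1
    expression_noise_sd: float = 0.25
    causal_locus: str | None = None
    causal_compound: str = "alkene_9"
    background_compound: str = "alkane_bg"
    divergent_favored_weight: float = 0.9
    regulation: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("at least one locus is required")
        names = [spec.name for spec in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for attr in (
            "n_species",
            "populations_per_species",
            "individuals_per_population",
            "clones_per_allele",
        ):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        for attr in ("migration_rate", "clone_error_rate"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ValueError(f"{attr} outside [0,1]")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.5 <= self.divergent_favored_weight <= 1.0:
            raise ValueError("divergent_favored_weight outside [0.5, 1]")
        if self.causal_locus is not None and self.causal_locus not in names:
            raise ValueError(f"causal_locus {self.causal_locus!r} not in loci")

    @property
    def locus_names(self) -> list[str]:
        return [spec.name for spec in self.loci]

    def resolved_causal_locus(self) -> str:
        if self.causal_locus is not None:
            return self.causal_locus
        for spec in self.loci:
            if spec.selection == "divergent":
                return spec.name
        return self.loci[0].name

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def population_names(self) -> list[tuple[str, str]]:
        """(species, population) pairs in deterministic order."""
        out = []
        for sp in self.species_names():
            for j in range(self.populations_per_species):
                out.append((sp, f"{sp}_pop{j + 1}"))
        return out

    def regulation_multiplier(self, species: str, locus: str) -> float:
        return self.regulation.get((species, locus), 1.0)
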