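import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from alleleflow.allelecall.types import CloneRead
from alleleflow.synth import LocusSpec, SimulationConfig


def make_read(
    rid: str,
    sequence: str,
    locus: str = "L1",
    individual: str = "ind1",
    population: str = "pop1",
    species: str = "sp1",
) -> CloneRead:
    return CloneRead(
        id=rid,
        locus=locus,
        individual=individual,
        population=population,
        species=species,
        sequence=sequence,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Two loci, 2 species x 2 populations x 5 individuals."""
    return SimulationConfig(
        loci=(
            LocusSpec(
                name="L1",
                n_codons=60,
                mutation_count=6,
                n_alleles=4,
                lof_rate=0.3,
                selection="divergent",
                min_pairwise_diff=5,
            ),
            LocusSpec(
                name="L2",
                n_codons=60,
                mutation_count=6,
                n_alleles=4,
                min_pairwise_diff=5,
            ),
        ),
        n_species=2,
        populations_per_species=2,
        individuals_per_population=5,
        migration_rate=0.05,
        clones_per_allele=3,
        clone_error_rate=5e-4,
        expression_effect=2.0,
        noise_sd=0.1,
        seed=11,
    )
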