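import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from alleleflow.allelecall.distance import pairwise_nt_diff
from alleleflow.synth import (
    LocusSpec,
    SimulationConfig,
    expected_pairwise_diff,
    generate_clone_reads,
    parametric_theta,
    simulate_allele_pool,
    simulate_metapopulation,
)
from alleleflow.synth.metapop import IndividualTruth, island_fixation_index
from alleleflow.synth.pool import _is_intact_orf


def _pool_spec(**kwargs):
    defaults = dict(name="P", n_codons=60, mutation_count=4, n_alleles=6)
    defaults.update(kwargs)
    return LocusSpec(**defaults)


class TestSimulateAllelePool:
    def test_lof_rate_zero_all_functional(self):
        _, alleles = simulate_allele_pool(_pool_spec(lof_rate=0.0), seed=1)
        assert all(a.functional for a in alleles)
        assert all(_is_intact_orf(a.sequence) for a in alleles)

    def test_lof_rate_one_all_nonfunctional(self):
        _, alleles = simulate_allele_pool(
            _pool_spec(lof_rate=1.0, n_alleles=10), seed=2
        )
        assert len(alleles) == 10
        assert not any(a.functional for a in alleles)
        for a in alleles:
            has_gap_run = "-" in a.sequence
            has_internal_stop = not _is_intact_orf(a.sequence.replace("-", ""))
            assert has_gap_run or has_internal_stop

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError, match="30 codons"):
            LocusSpec(name="tiny", n_codons=20)

    def test_ancestor_is_intact_orf(self):
        ancestor, _ = simulate_allele_pool(_pool_spec(), seed=3)
        assert _is_intact_orf(ancestor)

    def test_min_pairwise_diff_enforced(self):
        _, alleles = simulate_allele_pool(
            _pool_spec(min_pairwise_diff=5, mutation_count=8), seed=4
        )
        for i, a in enumerate(alleles):
            for b in alleles[i + 1 :]:
                assert pairwise_nt_diff(a.sequence, b.sequence) >= 5

    def test_deterministic(self):
        _, a1 = simulate_allele_pool(_pool_spec(lof_rate=0.3), seed=9)
        _, a2 = simulate_allele_pool(_pool_spec(lof_rate=0.3), seed=9)
        assert [x.sequence for x in a1] == [x.sequence for x in a2]

    def test_mean_pairwise_diff_matches_nominal_expectation(self):
        # Monte-Carlo check against the generator's closed-form expectation
        spec = _pool_spec(n_codons=100, mutation_count=5, n_alleles=8)
        means = []
        for seed in range(200):
            _, alleles = simulate_allele_pool(spec, seed=seed)
            seqs = [a.sequence for a in alleles]
            diffs = [
                pairwise_nt_diff(seqs[i], seqs[j])
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
            ]
            means.append(np.mean(diffs))
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        nominal = expected_pairwise_diff(5, 100)
        assert abs(np.mean(means) - nominal) < 3 * se


class TestParametricTheta:
    def test_disjoint_fixed_alleles(self):
        freqs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert parametric_theta(freqs, [10, 10]) == pytest.approx(1.0)

    def test_identical_frequencies(self):
        freqs = np.array([[0.4, 0.6], [0.4, 0.6]])
        assert parametric_theta(freqs, [10, 10]) == pytest.approx(0.0)

    def test_in_unit_interval(self, rng):
        for _ in range(50):
            freqs = rng.dirichlet(np.ones(4), size=3)
            value = parametric_theta(freqs, rng.integers(5, 50, size=3))
            assert -1e-12 <= value <= 1.0 + 1e-12


class TestGenerateCloneReads:
    TEMPLATE = {"A1": "ATG" + "GCT" * 50 + "TAA", "A2": "ATG" + "GCA" * 50 + "TAA"}

    def _individual(self, genotype=("A1", "A2")):
        return IndividualTruth(
            id="i1", species="sp1", population="p1", genotypes={"L1": genotype}
        )

    def test_error_free_reads_identical_to_source(self):
        reads = generate_clone_reads(
            self._individual(), "L1", self.TEMPLATE, 3, 0.0, seed=1
        )
        for read in reads:
            source = read.id.split(".")[1]
            assert read.sequence == self.TEMPLATE[source]

    def test_heterozygote_read_count(self):
        reads = generate_clone_reads(
            self._individual(), "L1", self.TEMPLATE, 3, 0.0, seed=1
        )
        assert len(reads) == 6

    def test_homozygote_also_two_copies(self):
        reads = generate_clone_reads(
            self._individual(("A1", "A1")), "L1", self.TEMPLATE, 4, 0.0, seed=1
        )
        assert len(reads) == 8

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValueError, match="no genotype"):
            generate_clone_reads(
                self._individual(), "L2", self.TEMPLATE, 3, 0.0, seed=1
            )

    def test_empirical_error_rate_binomial(self):
        # ~10^4 reads of ~800 bp: empirical per-base error within 3 SE
        template = {"A1": "ATG" + "GCT" * 265 + "TAA"}
        ind = self._individual(("A1", "A1"))
        reads = generate_clone_reads(ind, "L1", template, 5000, 1e-3, seed=7)
        n_bases = sum(len(r.sequence) for r in reads)
        n_errors = sum(
            sum(a != b for a, b in zip(r.sequence, template["A1"]))
            for r in reads
        )
        rate = n_errors / n_bases
        se = math.sqrt(1e-3 * (1 - 1e-3) / n_bases)
        assert abs(rate - 1e-3) < 3 * se


class TestSimulateMetapopulation:
    def test_conservation_of_read_counts(self, small_config):
        dataset, _ = simulate_metapopulation(small_config)
        n_ind = (
            small_config.n_species
            * small_config.populations_per_species
            * small_config.individuals_per_population
        )
        for locus in small_config.locus_names:
            assert (
                len(dataset.reads[locus])
                == n_ind * 2 * small_config.clones_per_allele
            )

    def test_every_read_maps_to_one_true_allele(self, small_config):
        dataset, truth = simulate_metapopulation(small_config)
        for locus, reads in dataset.reads.items():
            for read in reads:
                allele_id = read.id.split(".")[1]
                assert allele_id in truth.allele_sequences
                assert allele_id in truth.genotypes[read.individual][locus]

    def test_deterministic_byte_identical(self, small_config, tmp_path):
        d1, _ = simulate_metapopulation(small_config)
        d2, _ = simulate_metapopulation(small_config)
        p1 = d1.write(tmp_path / "run1")
        p2 = d2.write(tmp_path / "run2")
        for key in p1:
            assert (
                open(p1[key], "rb").read() == open(p2[key], "rb").read()
            ), key

    def test_diploid_genotypes_everywhere(self, small_config):
        _, truth = simulate_metapopulation(small_config, with_reads=False)
        for loci in truth.genotypes.values():
            for locus in ("L1", "L2"):
                assert len(loci[locus]) == 2

    def test_noiseless_phenotype_exactly_linear(self, small_config):
        config = replace(small_config, noise_sd=0.0, clone_error_rate=0.0)
        dataset, truth = simulate_metapopulation(config, with_reads=False)
        causal = truth.causal_locus
        expr = dataset.expression
        signals, amounts = [], []
        for ind in truth.genotypes:
            rows = expr[(expr.individual == ind) & (expr.locus == causal)]
            signal = sum(
                r.normalized_intensity
                for r in rows.itertuples()
                if truth.functional[r.allele_group]
            )
            amount = dataset.phenotype[
                (dataset.phenotype.individual == ind)
                & (dataset.phenotype.compound == truth.causal_compound)
            ].amount_ug.iloc[0]
            signals.append(signal)
            amounts.append(amount)
        slope = np.polyfit(signals, amounts, 1)[0]
        assert slope == pytest.approx(config.expression_effect, rel=1e-6)

    def test_panmixia_gives_near_zero_parametric_fst(self):
        # m=1, N=50 -> F = 1/201; realized theta dominated by sampling noise
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            config = SimulationConfig(
                loci=(LocusSpec(name="L1", n_codons=40, mutation_count=3, n_alleles=4),),
                n_species=2,
                populations_per_species=2,
                individuals_per_population=50,
                migration_rate=1.0,
                seed=seed,
            )
            _, truth = simulate_metapopulation(config, with_reads=False)
            if truth.parametric_fst["L1"]["population"] < 0.02:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_parametric_fst_monotone_in_migration(self):
        rates = [0.0, 0.002, 0.01, 0.05, 0.25, 1.0]
        pairs = []
        for rate in rates:
            for seed in range(12):
                config = SimulationConfig(
                    loci=(
                        LocusSpec(
                            name="L1", n_codons=40, mutation_count=3, n_alleles=4
                        ),
                    ),
                    n_species=2,
                    populations_per_species=2,
                    individuals_per_population=20,
                    migration_rate=rate,
                    seed=seed,
                )
                _, truth = simulate_metapopulation(config, with_reads=False)
                theta = truth.parametric_fst["L1"]["population"]
                if not math.isnan(theta):  # monomorphic draws are undefined
                    pairs.append((rate, theta))
        rho, p = stats.spearmanr([m for m, _ in pairs], [f for _, f in pairs])
        assert rho < 0
        assert p < 0.01

    def test_regulation_off_silences_expression(self, small_config):
        config = replace(
            small_config,
            regulation={("sp2", "L1"): 0.0},
            clone_error_rate=0.0,
        )
        dataset, _ = simulate_metapopulation(config, with_reads=False)
        expr = dataset.expression
        silenced = expr[(expr.species == "sp2") & (expr.locus == "L1")]
        assert (silenced.normalized_intensity == 0.0).all()
        active = expr[(expr.species == "sp1") & (expr.locus == "L1")]
        assert (active.normalized_intensity > 0).all()

    def test_island_fixation_index(self):
        assert island_fixation_index(0.0, 30) == 1.0
        assert island_fixation_index(0.025, 30) == pytest.approx(0.25)


class TestConfigValidation:
    def test_rates_bounded(self, small_config):
        with pytest.raises(ValueError):
            replace(small_config, migration_rate=1.5)
        with pytest.raises(ValueError):
            replace(small_config, clone_error_rate=-0.1)

    def test_counts_positive(self, small_config):
        with pytest.raises(ValueError):
            replace(small_config, individuals_per_population=0)

    def test_unknown_causal_locus(self, small_config):
        with pytest.raises(ValueError, match="causal_locus"):
            replace(small_config, causal_locus="nope")

    def test_duplicate_locus_names(self, small_config):
        with pytest.raises(ValueError, match="duplicate"):
            replace(
                small_config, loci=(small_config.loci[0], small_config.loci[0])
            )
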