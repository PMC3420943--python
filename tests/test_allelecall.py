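import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alleleflow.allelecall import (
    assign_allele_groups,
    bootstrap_support,
    build_consensus,
    call_alleles,
    merge_clones,
    p_distance_matrix,
    pairwise_nt_diff,
    upgma,
)
from alleleflow.allelecall.types import AlignmentError, DistanceMatrix
from alleleflow.allelecall.upgma import tree_bipartitions

from conftest import make_read
from oracles import nt_diff_oracle, upgma_oracle

DNA = st.text(alphabet="ACGTN-", min_size=1, max_size=40)


class TestPairwiseNtDiff:
    def test_identity(self):
        assert pairwise_nt_diff("ACGT", "ACGT") == 0

    def test_single_substitution(self):
        assert pairwise_nt_diff("ACGT", "ACGA") == 1

    def test_gap_run_counts_once(self):
        # one 2-column gap run = one event (run-length oracle agrees)
        assert pairwise_nt_diff("AC--GT", "ACTTGT", "indel_as_diff") == 1
        assert nt_diff_oracle("AC--GT", "ACTTGT") == 1

    def test_gap_policy_ignore(self):
        assert pairwise_nt_diff("AC--GT", "ACTTGT", "ignore") == 0

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            pairwise_nt_diff("ACGT", "ACG")

    def test_n_never_counts(self):
        assert pairwise_nt_diff("ANGT", "ACGT") == 0

    @given(pairs=st.lists(st.tuples(st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-")), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_character_loop_oracle(self, pairs):
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        for policy in ("indel_as_diff", "ignore"):
            assert pairwise_nt_diff(a, b, policy) == nt_diff_oracle(a, b, policy)

    @given(pairs=st.lists(st.tuples(st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-")), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_symmetric(self, pairs):
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        assert pairwise_nt_diff(a, b) == pairwise_nt_diff(b, a)


class TestMergeClones:
    def test_one_difference_merges(self):
        reads = [make_read("r1", "ACGTACGT"), make_read("r2", "ACGTACGA")]
        alleles = merge_clones(reads)
        assert len(alleles) == 1
        assert not alleles[0].is_singleton
        assert set(alleles[0].member_read_ids) == {"r1", "r2"}

    def test_distant_reads_stay_singletons(self):
        reads = [
            make_read("r1", "AAAAAAAA"),
            make_read("r2", "AAACCCAA"),
            make_read("r3", "TTTAAAGG"),
        ]
        alleles = merge_clones(reads)
        assert len(alleles) == 3
        assert all(a.is_singleton for a in alleles)

    def test_single_linkage_chain(self):
        # A-B=1, B-C=1, A-C=2: connected components of the <=1 graph
        reads = [
            make_read("a", "AAAAAAAA"),
            make_read("b", "AAAAAAAC"),
            make_read("c", "AAAAAAGC"),
        ]
        alleles = merge_clones(reads, d_merge=1)
        assert len(alleles) == 1
        assert set(alleles[0].member_read_ids) == {"a", "b", "c"}

    def test_order_invariance(self):
        reads = [
            make_read("a", "AAAAAAAA"),
            make_read("b", "AAAAAAAC"),
            make_read("c", "GGGGAAAA"),
            make_read("d", "GGGGAAAT"),
        ]
        forward = merge_clones(reads)
        backward = merge_clones(list(reversed(reads)))
        key = lambda als: sorted(tuple(sorted(a.member_read_ids)) for a in als)
        assert key(forward) == key(backward)

    def test_majority_consensus_over_members(self):
        reads = [
            make_read("r1", "ACGT"),
            make_read("r2", "ACGA"),
            make_read("r3", "ACGT"),
        ]
        (allele,) = merge_clones(reads, d_merge=1)
        assert allele.consensus == "ACGT"

    def test_empty_input(self):
        assert merge_clones([]) == []

    def test_unaligned_reads_error(self):
        with pytest.raises(AlignmentError):
            merge_clones([make_read("r1", "ACGT"), make_read("r2", "ACG")])

    def test_mixed_loci_rejected(self):
        reads = [
            make_read("r1", "ACGT", locus="L1"),
            make_read("r2", "ACGT", locus="L2"),
        ]
        with pytest.raises(ValueError, match="loci"):
            merge_clones(reads)


class TestBuildConsensus:
    def test_majority_column(self):
        reads = [
            make_read("r1", "A"),
            make_read("r2", "A"),
            make_read("r3", "G"),
        ]
        assert build_consensus(reads) == "A"

    def test_tie_broken_by_smallest_id(self):
        reads = [make_read("r1", "A"), make_read("r2", "G")]
        assert build_consensus(reads) == "A"
        reads = [make_read("r1", "G"), make_read("r2", "A")]
        assert build_consensus(reads) == "G"

    def test_identical_reads(self):
        reads = [make_read("r1", "ACGT"), make_read("r2", "ACGT")]
        assert build_consensus(reads) == "ACGT"


class TestPDistance:
    def test_identical(self):
        dm = p_distance_matrix([("a", "ACGT"), ("b", "ACGT")])
        assert dm.get("a", "b") == 0.0

    def test_half_distance(self):
        dm = p_distance_matrix([("a", "AAAA"), ("b", "AATT")])
        assert dm.get("a", "b") == pytest.approx(0.5)

    def test_pairwise_deletion_of_gap_column(self):
        dm = p_distance_matrix([("a", "AA-A"), ("b", "AATA")])
        assert dm.get("a", "b") == 0.0
        assert dm.overlap_counts[0, 1] == 3

    def test_zero_overlap_names_pair(self):
        with pytest.raises(AlignmentError, match="'a'.*'b'"):
            p_distance_matrix([("a", "AA--"), ("b", "--TT")])


class TestUpgma:
    def test_three_taxa_topology_and_height(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = upgma(dm)
        nodes = {node.leaves(): node.height for node in tree.walk() if not node.is_leaf}
        assert nodes[frozenset({"A", "B"})] == pytest.approx(0.05)
        assert nodes[frozenset({"A", "B", "C"})] == pytest.approx(0.2)

    def test_ultrametric_heights(self, rng):
        for _ in range(20):
            n = 6
            raw = rng.random((n, n))
            mat = (raw + raw.T) / 2
            np.fill_diagonal(mat, 0)
            tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], mat))
            for node in tree.walk():
                if node.is_leaf:
                    assert node.height == 0.0
                for child in node.children:
                    assert child.height <= node.height * (1 + 1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        # 200 random <=6-taxon matrices against stepwise recomputation
        for _ in range(200):
            n = int(rng.integers(3, 7))
            raw = rng.random((n, n))
            mat = (raw + raw.T) / 2
            np.fill_diagonal(mat, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, mat))
            got = {
                (node.leaves(), round(node.height, 10))
                for node in tree.walk()
                if not node.is_leaf
            }
            expected = {
                (leafset, round(h, 10)) for leafset, h in upgma_oracle(labels, mat)
            }
            assert got == expected

    def test_newick_roundtrip_parses(self):
        import io

        from Bio import Phylo

        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]]),
        )
        newick = upgma(dm).to_newick()
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == {"A", "B", "C"}


class TestBootstrapSupport:
    ALIGNMENT = [
        ("a1", "AAAAAAAAAATTTTTTTTTT"),
        ("a2", "AAAAAAAAAATTTTTTTTTT"),
        ("b1", "CCCCCCCCCCGGGGGGGGGG"),
        ("b2", "CCCCCCCCCCGGGGGGGGGG"),
    ]

    def test_clear_clades_full_support(self):
        supports = bootstrap_support(self.ALIGNMENT, n_reps=50, seed=1)
        assert supports[frozenset({"a1", "a2"})] == 1.0
        assert supports[frozenset({"b1", "b2"})] == 1.0

    def test_single_replicate_is_binary(self):
        supports = bootstrap_support(self.ALIGNMENT, n_reps=1, seed=5)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_deterministic_given_seed(self):
        s1 = bootstrap_support(self.ALIGNMENT, n_reps=25, seed=9)
        s2 = bootstrap_support(self.ALIGNMENT, n_reps=25, seed=9)
        assert s1 == s2

    def test_root_support_trivially_one(self):
        supports = bootstrap_support(self.ALIGNMENT, n_reps=10, seed=2)
        assert supports[frozenset({"a1", "a2", "b1", "b2"})] == 1.0


class TestAssignAlleleGroups:
    def _tree_and_supports(self, alignment, n_reps=50):
        tree = upgma(p_distance_matrix(alignment))
        supports = bootstrap_support(alignment, n_reps=n_reps, seed=3)
        return tree, supports

    def test_everything_close_one_group(self):
        alignment = [("x", "A" * 50), ("y", "A" * 49 + "T"), ("z", "A" * 50)]
        tree, supports = self._tree_and_supports(alignment)
        groups = assign_allele_groups(tree, supports, max_within_distance=0.5)
        assert len(groups) == 1
        assert groups[0].label == "A"
        assert set(groups[0].member_allele_ids) == {"x", "y", "z"}

    def test_two_supported_clades(self):
        alignment = [
            ("a1", "AAAAAAAAAATTTTTTTTTT"),
            ("a2", "AAAAAAAAAATTTTTTTTTT"),
            ("a3", "AAAAAAAAAATTTTTTTTTT"),
            ("b1", "CCCCCCCCCCGGGGGGGGGG"),
            ("b2", "CCCCCCCCCCGGGGGGGGGG"),
        ]
        tree, supports = self._tree_and_supports(alignment)
        groups = assign_allele_groups(tree, supports)
        labels = {g.label: set(g.member_allele_ids) for g in groups}
        assert labels == {"A": {"a1", "a2", "a3"}, "B": {"b1", "b2"}}

    def test_no_support_everyone_singleton(self):
        alignment = [
            ("a", "AAAAAAAAAATTTTTTTTTT"),
            ("b", "AAAAAAAAAATTTTTTTTGG"),
            ("c", "CCCCCCCCCCGGGGGGGGGG"),
        ]
        tree, supports = self._tree_and_supports(alignment)
        groups = assign_allele_groups(
            tree, supports, min_support=1.1, max_within_distance=1.0
        )
        assert len(groups) == 3
        assert all(g.size == 1 for g in groups)
        assert all(math.isnan(g.support) for g in groups)

    def test_groups_partition_alleles(self):
        alignment = self._random_alignment()
        tree, supports = self._tree_and_supports(alignment)
        groups = assign_allele_groups(tree, supports)
        members = [a for g in groups for a in g.member_allele_ids]
        assert sorted(members) == sorted(label for label, _ in alignment)

    @staticmethod
    def _random_alignment():
        rng = np.random.default_rng(0)
        return [
            (f"s{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(6)
        ]


class TestEndToEnd:
    def test_merge_idempotent_on_consensus_sequences(self, small_config):
        from alleleflow.synth import simulate_metapopulation

        dataset, _ = simulate_metapopulation(small_config)
        alleles = merge_clones(dataset.reads["L1"], d_merge=4)
        rereads = [
            make_read(a.id, a.consensus, locus=a.locus) for a in alleles
        ]
        again = merge_clones(rereads, d_merge=4)
        assert len(again) == len(alleles)
        assert all(a.is_singleton for a in again)
        assert sorted(a.consensus for a in again) == sorted(
            a.consensus for a in alleles
        )

    def test_call_alleles_smoke(self, small_config):
        from alleleflow.synth import simulate_metapopulation

        dataset, _ = simulate_metapopulation(small_config)
        alleles, tree, supports, groups = call_alleles(
            dataset.reads["L2"], d_merge=4, n_boot=25, seed=0
        )
        assert alleles
        assert groups
        called = {a for g in groups for a in g.member_allele_ids}
        assert called == {a.id for a in alleles}
        if tree is not None:
            assert tree_bipartitions(tree)
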