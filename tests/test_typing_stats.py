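import numpy as np
import pytest

from phagemod import typing_stats as ts
from phagemod import synthetic_genome as syn
from phagemod.io_formats import Genome, HostRangeMatrix
from phagemod.workflows import _stub_truth


class TestRounding:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (17, 255, 6.7),
            (10, 18, 55.6),
            (5, 18, 27.8),
            (13, 227, 5.7),
            (31, 255, 12.2),
            (7, 14, 50.0),
            (0, 5, 0.0),
            (1, 16, 6.3),  # 6.25 rounds half-up to 6.3
        ],
    )
    def test_percent_from_counts_half_up(self, k, n, expected):
        assert ts.percent_from_counts(k, n) == expected

    def test_zero_tested_errors(self):
        with pytest.raises(ValueError, match="zero"):
            ts.percent_from_counts(1, 0)


def toy_matrix():
    strains = [(f"j{i}", "C. jejuni") for i in range(4)] + [(f"c{i}", "C. coli") for i in range(2)]
    phages = ["P1", "P2", "P3"]
    values = [
        [1, 1, 0],
        [1, 1, 0],
        [0, 0, 0],
        [1, 0, 0],
        [0, 0, 0],
        [1, 1, 1],
    ]
    return HostRangeMatrix(strains=strains, phages=phages, values=values)


class TestPercentPositive:
    def test_counts_and_percent(self):
        m = toy_matrix()
        assert ts.percent_positive(m, "P1") == (4, 6, 66.7)
        assert ts.percent_positive(m, "P1", "C. jejuni") == (3, 4, 75.0)
        assert ts.percent_positive(m, "P3", "C. jejuni") == (0, 4, 0.0)

    def test_unknown_species_errors(self):
        with pytest.raises(ValueError, match="no strains"):
            ts.percent_positive(toy_matrix(), "P1", "C. lari")


class TestProfileSimilarity:
    def test_identical_columns(self):
        m = toy_matrix()
        assert ts.profile_similarity(m, "P1", "P1").value == 1.0

    def test_disjoint_sets(self):
        m = HostRangeMatrix(
            strains=[("a", "C. jejuni"), ("b", "C. jejuni")],
            phages=["X", "Y"],
            values=[[1, 0], [0, 1]],
        )
        assert ts.profile_similarity(m, "X", "Y").value == 0.0

    def test_hand_worked_jaccard(self):
        # A = {s1,s2,s3}, B = {s2,s3,s4} -> 2/4
        m = HostRangeMatrix(
            strains=[(f"s{i}", "C. jejuni") for i in range(1, 5)],
            phages=["A", "B"],
            values=[[1, 0], [1, 1], [1, 1], [0, 1]],
        )
        assert ts.profile_similarity(m, "A", "B").value == 0.5

    def test_both_empty_flagged_one(self):
        m = HostRangeMatrix(
            strains=[("a", "C. jejuni")], phages=["X", "Y"], values=[[0, 0]]
        )
        sim = ts.profile_similarity(m, "X", "Y")
        assert sim.value == 1.0 and sim.both_empty


class TestGp047:
    def test_identical_query(self):
        q = Genome(id="q", sequence=syn.GP047_REFERENCE)
        c = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        assert (c.length_difference, c.deletion, c.cterm_identity, c.resolved) == (0, False, 1.0, True)

    def test_internal_kilobase_deletion_flagged(self):
        q = Genome(id="q", sequence=syn.GP047_REFERENCE[:1500] + syn.GP047_REFERENCE[2500:])
        c = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        assert c.length_difference == 1000 and c.deletion

    def test_small_deletion_below_window_not_flagged(self):
        q = Genome(id="q", sequence=syn.GP047_REFERENCE[:1500] + syn.GP047_REFERENCE[1600:])
        c = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        assert c.length_difference == 100 and not c.deletion

    def test_minus_strand_locus_located(self):
        from phagemod._seq import revcomp

        q = Genome(id="q", sequence="ACGT" * 100 + revcomp(syn.GP047_REFERENCE) + "TTTT" * 50)
        c = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        assert c.resolved and c.length_difference == 0 and c.cterm_identity == 1.0

    def test_absent_locus_unresolved_not_exception(self, rng):
        from phagemod._seq import random_seq

        q = Genome(id="q", sequence=random_seq(rng, 5000, 0.3))
        c = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        assert not c.resolved and c.length_difference is None

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            ts.detect_gp047_deletion(Genome(id="q", sequence="ACGT" * 300), "ACGT" * 100)


class TestClassifySubgroup:
    def ev(self, **kw):
        return ts.SubgroupEvidence(phage_id="P", **kw)

    def test_all_cp21_criteria_full_concordance(self):
        call = ts.classify_subgroup(
            self.ev(
                signature=ts.CP21_SIGNATURE,
                trna_labels=frozenset({"Thr", "Pro"}),
                digest_vote="CP21like",
                pcr_vote="CP21like",
            )
        )
        assert (call.call, call.atypical, call.concordance) == ("CP21_subgroup", False, 1.0)

    def test_dissenting_criterion_marks_atypical_but_keeps_majority(self):
        # the IBB_35 situation: CP220-like architecture, deviant marker
        call = ts.classify_subgroup(
            self.ev(
                signature=ts.CP220_SIGNATURE,
                trna_labels=frozenset({"Arg", "Tyr"}),
                digest_vote="CP21like",
            )
        )
        assert call.call == "CP220_subgroup" and call.atypical
        assert call.concordance == pytest.approx(2 / 3, abs=1e-3)

    def test_gp047_deletion_votes_cp220(self):
        q = Genome(id="q", sequence=syn.GP047_REFERENCE[:1500] + syn.GP047_REFERENCE[2500:])
        cmp047 = ts.detect_gp047_deletion(q, syn.GP047_REFERENCE)
        call = ts.classify_subgroup(self.ev(gp047=cmp047))
        assert call.call == "CP220_subgroup"

    def test_no_computable_criteria_unresolved(self):
        assert ts.classify_subgroup(self.ev()).call == "unresolved"

    def test_tie_is_unresolved_never_broken_arbitrarily(self):
        call = ts.classify_subgroup(self.ev(digest_vote="CP21like", pcr_vote="CP220like"))
        assert call.call == "unresolved"

    def test_unrecognized_signature_is_not_a_vote(self):
        call = ts.classify_subgroup(self.ev(signature="A+,B?,C-,D+", digest_vote="CP220like"))
        assert call.call == "CP220_subgroup" and not call.atypical


class TestPermutationTest:
    def test_identical_lysis_gives_zero_statistic(self):
        m = HostRangeMatrix(
            strains=[(f"s{i}", "C. jejuni") for i in range(10)],
            phages=["P1", "P2", "P3", "P4"],
            values=[[1, 1, 1, 1]] * 6 + [[0, 0, 0, 0]] * 4,
        )
        res = ts.subgroup_hostrange_test(m, {"P1": "a", "P2": "a", "P3": "b", "P4": "b"}, 99, seed=0)
        assert res.observed == 0.0

    def test_strong_structure_is_significant(self):
        truths = [_stub_truth(f"P{i + 1}", "CP220like" if i < 4 else "CP21like") for i in range(8)]
        calls = {t.genome_id: t.subgroup for t in truths}
        m = syn.generate_hostrange(truths, n_jejuni=100, n_coli=18, seed=7)
        res = ts.subgroup_hostrange_test(m, calls, n_permutations=999, seed=7)
        assert res.p_value <= 0.05

    def test_degenerate_labels_rejected(self):
        m = toy_matrix()
        with pytest.raises(ValueError, match="2 subgroups"):
            ts.subgroup_hostrange_test(m, {"P1": "a", "P2": "a", "P3": "a"}, 9, seed=0)

    def test_seed_reproducibility(self):
        truths = [_stub_truth(f"P{i + 1}", "CP220like" if i < 2 else "CP21like") for i in range(4)]
        calls = {t.genome_id: t.subgroup for t in truths}
        m = syn.generate_hostrange(truths, n_jejuni=40, n_coli=10, seed=5)
        a = ts.subgroup_hostrange_test(m, calls, 199, seed=11)
        b = ts.subgroup_hostrange_test(m, calls, 199, seed=11)
        assert a.p_value == b.p_value


class TestGenomeSummary:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("ACGTN", 50.0)])
    def test_gc_percent(self, seq, expected):
        assert ts.genome_summary(Genome(id="g", sequence=seq)).gc_percent == expected

    def test_default_synthetic_genome_matches_target_gc(self):
        g, _ = syn.generate_genome(syn.GeneratorConfig(seed=4, scale=0.5))
        s = ts.genome_summary(g)
        assert abs(s.gc_percent - 27.2) <= 1.0

    def test_module_lengths_reported(self, small_cohort):
        from phagemod import workflows

        genome, truth = small_cohort[0]
        _, _, modules = workflows.analyze_genome(genome)
        s = ts.genome_summary(genome, modules)
        assert set(s.module_lengths) == {"A", "B", "C", "D"}
        assert sum(s.module_lengths.values()) < s.length


class TestTailGeneTree:
    def test_subgroup_gene_variants_cluster(self, rng):
        from phagemod._seq import mutate

        base = syn.GP047_REFERENCE[:1500]
        variant, _ = mutate(base, 0.10, rng, 0.272)
        seqs = {
            "a1": base,
            "a2": mutate(base, 0.005, rng, 0.272)[0],
            "b1": variant,
            "b2": mutate(variant, 0.005, rng, 0.272)[0],
        }
        tree = ts.tail_gene_tree(seqs)
        clusters = tree.cut(2)
        assert clusters["a1"] == clusters["a2"] != clusters["b1"]
        assert clusters["b1"] == clusters["b2"]
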