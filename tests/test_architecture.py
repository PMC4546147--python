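import numpy as np
import pytest

from phagemod import architecture as arch
from phagemod import insilico_assays as assays
from phagemod import repeat_finder as rf
from phagemod import workflows
from phagemod._seq import random_seq, revcomp
from phagemod.io_formats import Genome
from phagemod.repeat_finder import RepeatRegion, RepeatUnit


def make_region(i, s, e):
    return RepeatRegion(
        id=f"RR{i}",
        start=s,
        end=e,
        left_arm=[RepeatUnit(s, s + 80, "+", 0)],
        right_arm=[RepeatUnit(e - 80, e, "+", 0)],
        inner_start=s + 80,
        inner_end=e - 80,
    )


class TestSegmentModules:
    def test_circular_four_regions_four_modules(self):
        g = Genome(id="c", sequence="A" * 160_000, topology="circular")
        regions = [make_region(i + 1, 10_000 + 40_000 * i, 12_000 + 40_000 * i) for i in range(4)]
        mods = arch.segment_modules(g, regions)
        assert [m.id for m in mods] == ["A", "B", "C", "D"]
        assert sum(m.length for m in mods) == 160_000 - 4 * 2_000
        # tiling: modules plus regions cover the genome exactly (asserted inside too)
        assert any(m.wraps for m in mods)

    def test_zero_regions_whole_genome_is_one_module(self):
        g = Genome(id="g", sequence="A" * 5000)
        (m,) = arch.segment_modules(g, [])
        assert (m.id, m.start, m.end) == ("A", 0, 5000)

    def test_linear_one_region_two_modules(self):
        g = Genome(id="g", sequence="A" * 10_000)
        mods = arch.segment_modules(g, [make_region(1, 4000, 5000)])
        assert [(m.id, m.start, m.end) for m in mods] == [("A", 0, 4000), ("B", 5000, 10_000)]

    def test_overlapping_regions_rejected(self):
        g = Genome(id="g", sequence="A" * 10_000)
        with pytest.raises(ValueError, match="overlap"):
            arch.segment_modules(g, [make_region(1, 1000, 3000), make_region(2, 2500, 4000)])

    def test_region_abutting_origin_circular(self):
        g = Genome(id="g", sequence="A" * 10_000, topology="circular")
        mods = arch.segment_modules(g, [make_region(1, 9000, 10_000)])
        assert [(m.id, m.start, m.end) for m in mods] == [("A", 0, 9000)]


class TestDotPlot:
    def test_self_alignment_is_one_full_length_plus_match(self, rng):
        g = Genome(id="a", sequence=random_seq(rng, 5000, 0.3))
        dp = arch.compute_dotplot(g, g, k=31)
        assert [(m.query_start, m.query_end, m.orientation) for m in dp.matches] == [(0, 5000, "+")]

    def test_reverse_complement_gives_minus_matches_only(self, rng):
        s = random_seq(rng, 5000, 0.3)
        dp = arch.compute_dotplot(Genome(id="a", sequence=s), Genome(id="b", sequence=revcomp(s)), k=31)
        assert dp.matches and all(m.orientation == "-" for m in dp.matches)

    def test_mask_suppresses_seeding(self, rng):
        s = random_seq(rng, 3000, 0.3)
        g = Genome(id="a", sequence=s)
        dp = arch.compute_dotplot(g, g, k=31, query_mask=[(0, 3000)])
        assert dp.matches == []

    def test_k_floor(self, rng):
        g = Genome(id="a", sequence=random_seq(rng, 100, 0.5))
        with pytest.raises(ValueError, match=">= 11"):
            arch.compute_dotplot(g, g, k=8)


class TestCompareArchitectures:
    def test_identity_signature_against_self(self, small_cohort):
        genome, _ = small_cohort[0]
        _, bip, modules = workflows.analyze_genome(genome)
        spans = [(r.start, r.end) for r in bip]
        sig = arch.compare_architectures(
            genome, modules, genome, modules, query_region_spans=spans, subject_region_spans=spans
        )
        assert sig.as_string() == "A+,B+,C+,D+"

    def test_subgroup_pair_shows_b_c_inversion(self, small_cohort):
        ref = next(g for g, t in small_cohort if t.subgroup == "CP220like")
        qry = next(g for g, t in small_cohort if t.subgroup == "CP21like")
        _, rbip, rmod = workflows.analyze_genome(ref)
        _, qbip, qmod = workflows.analyze_genome(qry)
        sig = arch.compare_architectures(
            qry, qmod, ref, rmod,
            query_region_spans=[(r.start, r.end) for r in qbip],
            subject_region_spans=[(r.start, r.end) for r in rbip],
        )
        assert sig.as_string() == "A+,B-,C-,D+"

    def test_orientation_involution(self, small_cohort):
        a = next(g for g, t in small_cohort if t.subgroup == "CP220like")
        b = next(g for g, t in small_cohort if t.subgroup == "CP21like")
        _, abip, amod = workflows.analyze_genome(a)
        _, bbip, bmod = workflows.analyze_genome(b)
        spans_a = [(r.start, r.end) for r in abip]
        spans_b = [(r.start, r.end) for r in bbip]
        fwd = arch.compare_architectures(b, bmod, a, amod, query_region_spans=spans_b, subject_region_spans=spans_a)
        rev = arch.compare_architectures(a, amod, b, bmod, query_region_spans=spans_a, subject_region_spans=spans_b)
        fwd_map = {e.subject_module: e.orientation for e in fwd.entries if e.subject_module}
        rev_map = {e.query_module: e.orientation for e in rev.entries if e.subject_module}
        for mod, orient in fwd_map.items():
            assert rev_map[mod] == orient  # inversion is symmetric between the two


class TestOrderContigs:
    def cut(self, rng, n=3, size=4000):
        segs = [random_seq(rng, size, 0.3) for _ in range(n)]
        genome = Genome(id="G", sequence="".join(segs), topology="circular")
        contigs = [Genome(id=f"C{i + 1}", sequence=s) for i, s in enumerate(segs)]
        panel = arch.design_end_primers(contigs, primer_len=30, offset=300)
        amps = assays.virtual_pcr(genome, panel, max_mismatches=0, max_product=1200)
        return genome, contigs, panel, amps

    def test_cycle_recovered_with_zero_gaps(self, rng):
        genome, contigs, panel, amps = self.cut(rng)
        order = arch.order_contigs(contigs, panel, amps, circular=True)
        assert order.order == [("C1", "+"), ("C2", "+"), ("C3", "+")]
        assert order.gaps == [0, 0, 0]
        assert order.total_length == len(genome.sequence)

    def test_flipped_contig_orientation_recovered(self, rng):
        genome, contigs, panel, amps = self.cut(rng)
        flipped = [contigs[0], Genome(id="C2", sequence=revcomp(contigs[1].sequence)), contigs[2]]
        order = arch.order_contigs(flipped, panel, amps, circular=True)
        assert order.order == [("C1", "+"), ("C2", "-"), ("C3", "+")]

    def test_two_contigs_one_amplicon_forces_order(self, rng):
        segs = [random_seq(rng, 4000, 0.3) for _ in range(2)]
        template = Genome(id="L", sequence="".join(segs))
        contigs = [Genome(id=f"C{i + 1}", sequence=s) for i, s in enumerate(segs)]
        panel = arch.design_end_primers(contigs, primer_len=30, offset=300)
        amps = assays.virtual_pcr(template, panel, max_mismatches=0, max_product=1200)
        order = arch.order_contigs(contigs, panel, amps, circular=False)
        assert order.order == [("C1", "+"), ("C2", "+")] and order.gaps == [0]

    def test_missing_junction_names_the_break(self, rng):
        _, contigs, panel, amps = self.cut(rng)
        kept = [a for a in amps if not (a.forward_name.startswith("C2") and a.reverse_name.startswith("C3"))]
        with pytest.raises(ValueError, match="after C2"):
            arch.order_contigs(contigs, panel, kept, circular=True)

    def test_gap_measured_from_primer_offsets(self, rng):
        # contigs separated by a real 500 bp gap on the template
        segs = [random_seq(rng, 4000, 0.3) for _ in range(2)]
        gap_seq = random_seq(rng, 500, 0.3)
        template = Genome(id="T", sequence=segs[0] + gap_seq + segs[1])
        contigs = [Genome(id=f"C{i + 1}", sequence=s) for i, s in enumerate(segs)]
        panel = arch.design_end_primers(contigs, primer_len=30, offset=300)
        amps = assays.virtual_pcr(template, panel, max_mismatches=0, max_product=2000)
        order = arch.order_contigs(contigs, panel, amps, circular=False)
        assert order.gaps == [500]
        assert order.total_length == len(template.sequence)


class TestCohortArchitectureRecovery:
    def test_module_tiling_on_detected_regions(self, small_cohort):
        for genome, truth in small_cohort:
            _, bip, modules = workflows.analyze_genome(genome)
            total = sum(m.length for m in modules) + sum(r.length for r in bip)
            assert total == len(genome.sequence)

    def test_contig_order_recovery_on_generator_genome(self, small_cohort):
        genome, truth = small_cohort[0]
        from phagemod.synthetic_genome import GeneratorConfig

        assert workflows._contig_order_check(genome, truth, GeneratorConfig(scale=0.25))
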