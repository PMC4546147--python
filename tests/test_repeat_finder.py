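import numpy as np
import pytest
from hypothesis import given, strategies as st

from phagemod import repeat_finder as rf
from phagemod.io_formats import Genome
from phagemod.repeat_finder import CORE_MOTIF, MotifHit, RepeatUnit

# Independent complement table for the test-side oracle (no package imports).
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_scan(seq: str, motif: str, max_mm: int):
    """Position-by-position Hamming scan, both strands (test-side oracle)."""
    out = []
    for strand, pat in (("+", motif), ("-", oracle_revcomp(motif))):
        for i in range(len(seq) - len(pat) + 1):
            mm = sum(1 for a, b in zip(seq[i : i + len(pat)], pat) if a != b)
            if mm <= max_mm:
                out.append((i, strand, mm))
    return sorted(out)


def random_genome(rng, n, gc=0.3, with_n=False):
    bases = "ACGT" + ("N" if with_n else "")
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    if with_n:
        p = [x * 0.98 for x in p] + [0.02]
    return "".join(rng.choice(list(bases), size=n, p=p))


class TestScanCoreMotif:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAACTTAAAGCAA", [(0, 13, "+", 0)]),  # the core itself
            ("TTGCTTTAAGTTT", [(0, 13, "-", 0)]),  # its reverse complement
            ("AAACTTAAAGCGG", []),  # two mismatches: rejected at allowance 1
            ("AAACTTAAAGCAT", [(0, 13, "+", 1)]),  # one mismatch accepted
        ],
    )
    def test_motif_examples(self, seq, expected):
        hits = rf.scan_core_motif(Genome(id="g", sequence=seq), CORE_MOTIF, 1)
        assert [(h.start, h.end, h.strand, h.mismatches) for h in hits] == expected

    def test_motif_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            rf.scan_core_motif(Genome(id="g", sequence="ACGTACGTACGT"), "ACGTACG", 0)

    def test_n_mismatches_every_base(self):
        seq = CORE_MOTIF.replace("C", "N", 1)
        hits = rf.scan_core_motif(Genome(id="g", sequence=seq), CORE_MOTIF, 1)
        assert hits and hits[0].mismatches == 1

    def test_circular_origin_spanning_hit(self):
        # core split across the origin of a circular genome
        seq = CORE_MOTIF[5:] + "GGGGGGCCCCCC" + CORE_MOTIF[:5]
        g = Genome(id="g", sequence=seq, topology="circular")
        hits = rf.scan_core_motif(g, CORE_MOTIF, 0)
        assert any(h.start == len(seq) - 5 for h in hits)
        lin = Genome(id="g", sequence=seq, topology="linear")
        assert rf.scan_core_motif(lin, CORE_MOTIF, 0) == []

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_genome(rng, int(rng.integers(50, 2000)), with_n=True)
        hits = rf.scan_core_motif(Genome(id="g", sequence=seq), CORE_MOTIF, 1)
        assert [(h.start, h.strand, h.mismatches) for h in hits] == oracle_scan(seq, CORE_MOTIF, 1)


class TestBuildUnits:
    def test_regular_spacing_gives_unit_sized_blocks(self):
        hits = [MotifHit("g", s, s + 13, "+", 0) for s in (100, 178, 256)]
        units = rf.build_units(hits)
        assert len(units) == 3
        assert all(abs(u.length - 78) <= 1 for u in units)
        assert all(u.start < h.start < u.end for u, h in zip(units, hits))

    def test_single_isolated_hit_gets_default_length(self):
        units = rf.build_units([MotifHit("g", 500, 513, "+", 0)])
        assert len(units) == 1 and units[0].length == 80
        # centered on the core
        assert units[0].core_offset == (80 - 13) // 2

    def test_spacing_cutoff_splits_chains(self):
        hits = [MotifHit("g", 0, 13, "+", 0), MotifHit("g", 5000, 5013, "+", 0)]
        units = rf.build_units(hits, max_core_spacing=300)
        assert len(units) == 2

    def test_opposite_strand_duplicate_keeps_lower_mismatch_plus_tie(self):
        hits = [MotifHit("g", 100, 113, "-", 1), MotifHit("g", 100, 113, "+", 1)]
        units = rf.build_units(sorted(hits, key=lambda h: (h.start, h.strand)))
        assert len(units) == 1 and units[0].strand == "+"

    def test_empty_input(self):
        assert rf.build_units([]) == []


class TestAssembleRegions:
    def make_arm(self, start, n, strand="+"):
        return [RepeatUnit(start + 80 * i, start + 80 * (i + 1), strand, 33) for i in range(n)]

    def test_two_arms_with_600bp_spacer_form_one_region(self):
        units = self.make_arm(1000, 5) + self.make_arm(2000, 5)
        regions = rf.assemble_regions(units, arm_gap_max=200, inner_gap_max=1500)
        assert len(regions) == 1
        r = regions[0]
        assert r.arm_unit_counts == (5, 5)
        assert (r.inner_start, r.inner_end) == (1400, 2000)
        assert (r.start, r.end) == (1000, 2400)
        assert r.id == "RR1"

    def test_distant_arms_stay_separate_regions(self):
        units = self.make_arm(1000, 5) + self.make_arm(7000, 5)
        regions = rf.assemble_regions(units)
        assert len(regions) == 2 and all(r.single_armed for r in regions)

    def test_lone_small_arm_is_flagged_single_armed(self):
        regions = rf.assemble_regions(self.make_arm(100, 1))
        assert regions[0].single_armed

    def test_unequal_arm_counts_allowed(self):
        units = self.make_arm(1000, 3) + self.make_arm(1600, 9)
        (r,) = rf.assemble_regions(units)
        assert r.arm_unit_counts == (3, 9)


class TestClassifyRegion:
    def arm(self, start, n, strand):
        return [RepeatUnit(start + 80 * i, start + 80 * (i + 1), strand, 33) for i in range(n)]

    def build(self, left_strand, right_strand):
        units = self.arm(0, 3, left_strand) + self.arm(600, 3, right_strand)
        return rf.assemble_regions(units)[0]

    def test_same_strands_direct(self):
        assert rf.classify_region(self.build("+", "+")) == "direct"

    def test_opposite_strands_inverted(self):
        assert rf.classify_region(self.build("+", "-")) == "inverted"

    def test_within_arm_tie_is_ambiguous(self):
        units = self.arm(0, 1, "+") + self.arm(80, 1, "-") + self.arm(600, 3, "+")
        r = rf.assemble_regions(units, min_units_per_arm=2)[0]
        assert not r.single_armed
        assert rf.classify_region(r) == "ambiguous"

    def test_single_armed_region_raises(self):
        (r,) = rf.assemble_regions(self.arm(0, 3, "+"))
        with pytest.raises(ValueError, match="single arm"):
            rf.classify_region(r)


class TestDeriveConsensus:
    def test_identical_units_give_full_unit_consensus(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=80, p=[0.35, 0.15, 0.15, 0.35]))
        g = Genome(id="g", sequence=unit * 10)
        units = [RepeatUnit(80 * i, 80 * (i + 1), "+", 0) for i in range(10)]
        res = rf.derive_consensus(units, g, 1)
        assert res.length == 80 and res.consensus == unit and not res.short_warning

    def test_units_sharing_only_the_core_recover_it(self, rng):
        parts = []
        for i in range(8):
            left = "".join(rng.choice(list("ACGT"), size=30, p=[0.35, 0.15, 0.15, 0.35]))
            right = "".join(rng.choice(list("ACGT"), size=37, p=[0.35, 0.15, 0.15, 0.35]))
            core = CORE_MOTIF
            if i > 0 and rng.random() < 0.5:  # seed unit keeps the exact core
                pos = int(rng.integers(13))
                core = core[:pos] + ("A" if core[pos] != "A" else "C") + core[pos + 1 :]
            parts.append(left + core + right)
        g = Genome(id="g", sequence="".join(parts))
        units = [RepeatUnit(80 * i, 80 * (i + 1), "+", 30) for i in range(8)]
        res = rf.derive_consensus(units, g, 1)
        assert CORE_MOTIF in res.consensus
        assert all(m <= 1 for m in res.per_unit_mismatches)

    def test_minus_strand_units_are_oriented_before_comparison(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=60))
        from phagemod._seq import revcomp

        g = Genome(id="g", sequence=unit + "GG" + revcomp(unit))
        units = [RepeatUnit(0, 60, "+", 0), RepeatUnit(62, 122, "-", 0)]
        res = rf.derive_consensus(units, g, 0)
        assert res.length == 60

    def test_unrelated_units_warn_short(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("AC"), size=80))
        g = Genome(id="g", sequence=a + b)
        res = rf.derive_consensus([RepeatUnit(0, 80, "+", 0), RepeatUnit(80, 160, "+", 0)], g, 0)
        assert res.short_warning and res.length < 8

    def test_fewer_than_two_units_raises(self):
        g = Genome(id="g", sequence="ACGT" * 30)
        with pytest.raises(ValueError, match="at least 2"):
            rf.derive_consensus([RepeatUnit(0, 80, "+", 0)], g, 1)


class TestGeneratorRecovery:
    def test_planted_regions_recovered_exactly(self, small_cohort):
        for genome, truth in small_cohort:
            detected = rf.bipartite_regions(rf.find_repeat_regions(genome))
            assert len(detected) == len(truth.regions)
            for d, t in zip(detected, sorted(truth.regions, key=lambda r: r["start"])):
                assert (d.start, d.end) == (t["start"], t["end"])
                assert d.arm_unit_counts == (t["n_left"], t["n_right"])
                assert d.orientation_class == t["orientation_class"]

    def test_scattered_units_surface_as_singletons_never_merged(self, small_cohort):
        for genome, truth in small_cohort:
            regions = rf.find_repeat_regions(genome)
            singles = [r for r in regions if r.single_armed]
            planted_spans = {(s["start"], s["end"]) for s in truth.scattered}
            for s, e in planted_spans:
                mid = (s + e) // 2  # the planted core sits at the unit center
                hosts = [r for r in singles if r.start <= mid < r.end]
                assert len(hosts) == 1

    def test_consensus_of_one_detected_region_contains_core(self, small_cohort):
        genome, _ = small_cohort[0]
        region = rf.bipartite_regions(rf.find_repeat_regions(genome))[0]
        res = rf.derive_consensus(region.units, genome, 1)
        assert len(CORE_MOTIF) <= res.length
        assert CORE_MOTIF in res.consensus or res.length >= 13
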