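"""End-to-end study drivers.

These functions wire the pipeline stages together the way the analyses are
meant to be run: generate (or load) a cohort, detect repeat regions, segment
modules, compare architectures against a reference, run the in-silico
typing assays, classify subgroups, and score everything against the
generator's ground truth. They are used by the test suite, the acceptance
script and the CLI alike so all three exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import architecture as arch
from . import insilico_assays as assays
from . import repeat_finder as rf
from . import synthetic_genome as syn
from . import typing_stats as ts
from .io_formats import Genome


@dataclass
class GenomeScore:
    genome_id: str
    subgroup: str
    regions_ok: bool
    signature_ok: bool
    gp047_ok: bool
    call_ok: bool
    signature: str
    call: str
    concordance: float


@dataclass
class CohortResult:
    seed: int
    scores: list[GenomeScore]
    contig_order_ok: bool
    vspi_within_mean: float
    vspi_between_mean: float
    digest_separated: bool

    @property
    def all_regions_ok(self) -> bool:
        return all(s.regions_ok for s in self.scores)

    @property
    def all_signatures_ok(self) -> bool:
        return all(s.signature_ok for s in self.scores)

    @property
    def all_gp047_ok(self) -> bool:
        return all(s.gp047_ok for s in self.scores)

    @property
    def all_calls_ok(self) -> bool:
        return all(s.call_ok for s in self.scores)


def _interval_agreement(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    longer = max(a[1] - a[0], b[1] - b[0])
    return inter / longer if longer else 0.0


def _regions_match_truth(detected: list[rf.RepeatRegion], truth_regions: list[dict], min_overlap=0.95) -> bool:
    """Every planted region must be recovered by exactly one bipartite
    detection with >= min_overlap span agreement, exact per-arm unit counts
    and the planted orientation class."""
    if len(detected) != len(truth_regions):
        return False
    for t in truth_regions:
        cands = [d for d in detected if _interval_agreement((d.start, d.end), (t["start"], t["end"])) >= min_overlap]
        if len(cands) != 1:
            return False
        d = cands[0]
        if (len(d.left_arm), len(d.right_arm)) != (t["n_left"], t["n_right"]):
            return False
        if d.orientation_class != t["orientation_class"]:
            return False
    return True


def analyze_genome(genome: Genome, params: rf.RepeatFinderParams | None = None):
    """Repeat regions, module segmentation and summary for one genome."""
    regions = rf.find_repeat_regions(genome, params)
    bip = rf.bipartite_regions(regions)
    modules = arch.segment_modules(genome, bip)
    return regions, bip, modules


def _cut_contigs(genome: Genome, truth: syn.TruthRecord) -> list[Genome]:
    """Cut a circular genome into contigs at repeat-region midpoints."""
    L = len(genome.sequence)
    mids = sorted((r["start"] + r["end"]) // 2 for r in truth.regions)
    contigs = []
    for i, m in enumerate(mids):
        nxt = mids[(i + 1) % len(mids)]
        seq = genome.sequence[m:nxt] if nxt > m else genome.sequence[m:] + genome.sequence[:nxt]
        contigs.append(Genome(id=f"C{i + 1}", sequence=seq, topology="linear"))
    return contigs


def _contig_order_check(genome: Genome, truth: syn.TruthRecord, config: syn.GeneratorConfig) -> bool:
    contigs = _cut_contigs(genome, truth)
    max_region = max(r["end"] - r["start"] for r in truth.regions)
    offset = max_region // 2 + 250
    panel = arch.design_end_primers(contigs, primer_len=30, offset=offset)
    amplicons = assays.virtual_pcr(genome, panel, max_mismatches=0, three_prime_exact=3, max_product=6000)
    try:
        order = arch.order_contigs(contigs, panel, amplicons, circular=True)
    except ValueError:
        return False
    ids = [cid for cid, _ in order.order]
    orients = [o for _, o in order.order]
    expected = [c.id for c in contigs]
    if ids != expected or any(o != "+" for o in orients):
        return False
    if abs(order.total_length - len(genome.sequence)) > len(truth.regions):
        return False
    return all(abs(g) <= 1 for g in order.gaps)


def run_cohort_study(
    seed: int,
    scale: float = 0.25,
    n_per_subgroup: int = 3,
    base_config: syn.GeneratorConfig | None = None,
) -> CohortResult:
    """Generate one cohort and score recovery of every planted property."""
    config = base_config or syn.GeneratorConfig(scale=scale)
    cohort = syn.generate_cohort(n_per_subgroup, config, seed=seed)
    genomes = [g for g, _ in cohort]
    truths = [t for _, t in cohort]

    analyzed = [analyze_genome(g) for g in genomes]
    ref_idx = 0  # first CP220-like member is the canonical reference
    ref_genome = genomes[ref_idx]
    _, ref_bip, ref_modules = analyzed[ref_idx]
    ref_spans = [(r.start, r.end) for r in ref_bip]

    # typing panels from the reference's detected module intervals
    ref_mod_intervals = [(m.id, m.start, m.end) for m in ref_modules if not m.wraps]
    wraps = [m for m in ref_modules if m.wraps]
    for m in wraps:  # wrapping module: use its largest linear piece
        s, e = max(m.pieces(), key=lambda p: p[1] - p[0])
        ref_mod_intervals.append((m.id, s, e))
    panels = assays.design_typing_panels(ref_genome, sorted(ref_mod_intervals))

    # digests and prototypes
    patterns = [assays.digest(g, "VspI") for g in genomes]
    proto = {}
    for sub in ("CP220like", "CP21like"):
        idx = next(i for i, t in enumerate(truths) if t.subgroup == sub)
        proto[sub] = patterns[idx]

    scores: list[GenomeScore] = []
    for i, (g, t) in enumerate(cohort):
        regions, bip, modules = analyzed[i]
        regions_ok = _regions_match_truth(bip, t.regions)
        spans = [(r.start, r.end) for r in bip]
        sig = arch.compare_architectures(
            g, modules, ref_genome, ref_modules,
            query_region_spans=spans, subject_region_spans=ref_spans,
        )
        sig_str = sig.as_string()
        signature_ok = sig_str == t.signature
        cmp047 = ts.detect_gp047_deletion(g, syn.GP047_REFERENCE)
        gp047_ok = (
            cmp047.resolved
            and cmp047.deletion == (t.gp047_deletion > 0)
            and (cmp047.length_difference == t.gp047_deletion)
        )
        trna = frozenset(f.label for f in g.features if f.kind == "tRNA")
        dvote = min(
            ("CP220like", "CP21like"),
            key=lambda s: assays.pattern_distance(patterns[i], proto[s]),
        )
        profile = assays.typing_pcr(g, panels)
        pvote = assays.typing_profile_vote(profile)
        call = ts.classify_subgroup(
            ts.SubgroupEvidence(
                phage_id=g.id,
                signature=sig_str,
                trna_labels=trna or None,
                gp047=cmp047,
                digest_vote=dvote,
                pcr_vote=pvote,
            )
        )
        call_ok = call.call == ts.CALL_NAMES[t.subgroup] and call.concordance == 1.0
        scores.append(
            GenomeScore(
                genome_id=g.id,
                subgroup=t.subgroup,
                regions_ok=regions_ok,
                signature_ok=signature_ok,
                gp047_ok=gp047_ok,
                call_ok=call_ok,
                signature=sig_str,
                call=call.call,
                concordance=call.concordance,
            )
        )

    # digest separation: within- vs between-subgroup mean pattern distance
    within, between = [], []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            d = assays.pattern_distance(patterns[i], patterns[j])
            (within if truths[i].subgroup == truths[j].subgroup else between).append(d)
    w, b = float(np.mean(within)), float(np.mean(between))

    contig_ok = _contig_order_check(ref_genome, truths[ref_idx], config)

    return CohortResult(
        seed=seed,
        scores=scores,
        contig_order_ok=contig_ok,
        vspi_within_mean=w,
        vspi_between_mean=b,
        digest_separated=w < b,
    )


@dataclass
class StudySummary:
    n_cohorts: int
    n_genomes: int
    region_recovery: float
    signature_recovery: float
    gp047_recovery: float
    subgroup_call_recovery: float
    contig_order_recovery: float
    digest_separated_cohorts: int
    results: list[CohortResult] = field(default_factory=list)


def run_recovery_study(
    n_cohorts: int = 20,
    base_seed: int = 0,
    scale: float = 0.25,
    n_per_subgroup: int = 3,
) -> StudySummary:
    """The full recovery study: seed-indexed cohorts at reduced scale."""
    results = [run_cohort_study(base_seed + i, scale=scale, n_per_subgroup=n_per_subgroup) for i in range(n_cohorts)]
    scores = [s for r in results for s in r.scores]
    n = len(scores)
    return StudySummary(
        n_cohorts=n_cohorts,
        n_genomes=n,
        region_recovery=sum(s.regions_ok for s in scores) / n,
        signature_recovery=sum(s.signature_ok for s in scores) / n,
        gp047_recovery=sum(s.gp047_ok for s in scores) / n,
        subgroup_call_recovery=sum(s.call_ok for s in scores) / n,
        contig_order_recovery=sum(r.contig_order_ok for r in results) / n_cohorts,
        digest_separated_cohorts=sum(r.digest_separated for r in results),
        results=results,
    )


def _stub_truth(genome_id: str, subgroup: str) -> syn.TruthRecord:
    """Minimal truth record carrying only identity and subgroup (all that
    host-range generation consumes)."""
    return syn.TruthRecord(
        genome_id=genome_id, subgroup=subgroup, genome_length=0, regions=[], modules=[],
        trna_labels=[], gp047_start=None, gp047_end=None, gp047_deletion=0, scattered=[],
        restriction_sites={}, signature="",
    )


def run_null_calibration(
    n_seeds: int = 50,
    n_permutations: int = 999,
    base_seed: int = 10_000,
    n_jejuni: int = 60,
    n_coli: int = 18,
) -> list[float]:
    """Permutation p-values under the generator's null: both subgroups share
    one susceptibility model, so labels carry no information and the
    p-values should be approximately uniform."""
    shared = {"C. jejuni": 0.15, "C. coli": 0.5}
    # all phages drawn from one susceptibility group -> fully exchangeable;
    # the tested labels are arbitrary and carry no information
    truths = [_stub_truth(f"P{i + 1}", "CP220like") for i in range(6)]
    calls = {t.genome_id: ("g1" if i < 3 else "g2") for i, t in enumerate(truths)}
    pvals = []
    for s in range(n_seeds):
        m = syn.generate_hostrange(
            truths, n_jejuni=n_jejuni, n_coli=n_coli,
            susceptibility={"CP220like": shared}, seed=base_seed + s,
        )
        res = ts.subgroup_hostrange_test(m, calls, n_permutations=n_permutations, seed=base_seed + s)
        pvals.append(res.p_value)
    return pvals
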