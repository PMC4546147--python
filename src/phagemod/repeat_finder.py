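"""Detection of tandem repeat units and bipartite repeat regions.

The scan is anchored to a degenerate core motif (default
5'-AAACTTAAAGCAA-3', up to one mismatch): every approximate occurrence on
either strand seeds a repeat unit, runs of closely spaced units form arms,
and two arms separated by a short non-repetitive spacer form one bipartite
repeat region — the structure that delimits the genome modules of
*Campylobacter* group II phages. Arm orientation (direct vs inverted
repeats) is read off the strands of the member core hits.

Gap thresholds (arm_gap_max, inner_gap_max) are tool parameters, not
biological constants; the defaults reproduce 1-2.9 kb regions on genomes
with the published architecture and are exposed on the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, hamming_scan, revcomp
from .io_formats import Genome

CORE_MOTIF = "AAACTTAAAGCAA"


@dataclass
class MotifHit:
    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class RepeatUnit:
    start: int
    end: int
    strand: str  # strand of the core hit
    core_offset: int  # bp from unit start to core start
    core_mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatRegion:
    id: str
    start: int
    end: int
    left_arm: list[RepeatUnit]
    right_arm: list[RepeatUnit]  # empty for single-armed regions
    inner_start: int
    inner_end: int
    orientation_class: str | None = None  # direct | inverted | ambiguous
    single_armed: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def arm_unit_counts(self) -> tuple[int, int]:
        return (len(self.left_arm), len(self.right_arm))

    @property
    def units(self) -> list[RepeatUnit]:
        return self.left_arm + self.right_arm

    @property
    def mean_core_mismatch(self) -> float:
        u = self.units
        return float(np.mean([x.core_mismatches for x in u])) if u else 0.0


@dataclass
class ConsensusResult:
    consensus: str
    length: int
    per_unit_mismatches: list[int]
    short_warning: bool = False  # no common >= 8-mer at the allowance


@dataclass
class RepeatFinderParams:
    motif: str = CORE_MOTIF
    max_mismatches: int = 1
    max_core_spacing: int = 300
    unit_length_window: tuple[int, int] = (60, 100)
    arm_gap_max: int = 200
    inner_gap_max: int = 1500
    min_units_per_arm: int = 2


# ---------------------------------------------------------------------------


def scan_core_motif(genome: Genome, motif: str = CORE_MOTIF, max_mismatches: int = 1) -> list[MotifHit]:
    """All positions (both strands) where the motif occurs within the
    mismatch allowance, sorted by start.

    N in the genome mismatches every motif base. For circular genomes the
    origin-spanning window is scanned as well (hit starts reported modulo
    genome length; ends may exceed it, meaning the hit wraps).
    """
    if len(motif) < 8:
        raise ValueError("motif length must be >= 8")
    pat_plus = encode(motif.upper(), allow_n=False)
    pat_minus = encode(revcomp(motif.upper()), allow_n=False)
    L = len(genome.sequence)
    seq = genome.sequence
    if genome.topology == "circular" and L > len(motif):
        seq = seq + genome.sequence[: len(motif) - 1]
    arr = encode(seq)
    hits: list[MotifHit] = []
    for strand, pat in (("+", pat_plus), ("-", pat_minus)):
        mm = hamming_scan(arr, pat)
        for i in np.flatnonzero(mm <= max_mismatches):
            hits.append(MotifHit(genome.id, int(i), int(i) + len(motif), strand, int(mm[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _dedupe_hits(hits: list[MotifHit], min_separation: int) -> list[MotifHit]:
    """Collapse clusters of hits closer than ``min_separation`` to the best
    hit (lowest mismatch count, plus strand on ties, then leftmost)."""
    out: list[MotifHit] = []
    for h in hits:
        if out and h.start - out[-1].start < min_separation:
            prev = out[-1]
            if (h.mismatches, h.strand != "+", h.start) < (prev.mismatches, prev.strand != "+", prev.start):
                out[-1] = h
        else:
            out.append(h)
    return out


def build_units(
    hits: list[MotifHit],
    unit_length_window: tuple[int, int] = (60, 100),
    max_core_spacing: int = 300,
    genome_length: int | None = None,
) -> list[RepeatUnit]:
    """Delimit repeat units around sorted core hits.

    Consecutive hits closer than ``max_core_spacing`` belong to one chain;
    interior unit boundaries sit at the midpoint between neighbouring cores,
    terminal units extend half the chain's median core spacing (half the
    default unit length, 80 bp, for singletons). Each unit holds exactly one
    core.
    """
    default_len = (unit_length_window[0] + unit_length_window[1]) // 2
    hits = _dedupe_hits(sorted(hits, key=lambda h: (h.start, h.strand)), unit_length_window[0] // 2)
    units: list[RepeatUnit] = []
    chain: list[MotifHit] = []

    def flush(chain: list[MotifHit]) -> None:
        if not chain:
            return
        m = chain[0].end - chain[0].start
        if len(chain) == 1:
            s = default_len
        else:
            s = int(np.median([b.start - a.start for a, b in zip(chain, chain[1:])]))
        ext_left = (s - m) // 2
        ext_right = s - m - ext_left
        starts = [chain[0].start - ext_left] + [
            (a.end + b.start) // 2 for a, b in zip(chain, chain[1:])
        ]
        ends = [(a.end + b.start) // 2 for a, b in zip(chain, chain[1:])] + [chain[-1].end + ext_right]
        for h, us, ue in zip(chain, starts, ends):
            us = max(0, us)
            if genome_length is not None:
                ue = min(ue, genome_length)
            units.append(
                RepeatUnit(start=us, end=ue, strand=h.strand, core_offset=h.start - us, core_mismatches=h.mismatches)
            )

    for h in hits:
        if chain and h.start - chain[-1].start > max_core_spacing:
            flush(chain)
            chain = []
        chain.append(h)
    flush(chain)
    return units


def assemble_regions(
    units: list[RepeatUnit],
    arm_gap_max: int = 200,
    inner_gap_max: int = 1500,
    min_units_per_arm: int = 2,
) -> list[RepeatRegion]:
    """Group sorted units into bipartite repeat regions.

    Maximal runs of units with inter-unit gap <= ``arm_gap_max`` form arms;
    two adjacent arms of >= ``min_units_per_arm`` units separated by a spacer
    of <= ``inner_gap_max`` form one bipartite region with the spacer as its
    inner (non-repetitive) interval. Any remaining arm becomes a
    single-armed region flagged as such. Regions are named RR1... left to
    right.
    """
    units = sorted(units, key=lambda u: u.start)
    arms: list[list[RepeatUnit]] = []
    for u in units:
        if arms and u.start - arms[-1][-1].end <= arm_gap_max:
            arms[-1].append(u)
        else:
            arms.append([u])

    regions: list[RepeatRegion] = []
    i = 0
    while i < len(arms):
        left = arms[i]
        paired = (
            i + 1 < len(arms)
            and len(left) >= min_units_per_arm
            and len(arms[i + 1]) >= min_units_per_arm
            and arms[i + 1][0].start - left[-1].end <= inner_gap_max
        )
        if paired:
            right = arms[i + 1]
            regions.append(
                RepeatRegion(
                    id="",
                    start=left[0].start,
                    end=right[-1].end,
                    left_arm=left,
                    right_arm=right,
                    inner_start=left[-1].end,
                    inner_end=right[0].start,
                )
            )
            i += 2
        else:
            regions.append(
                RepeatRegion(
                    id="",
                    start=left[0].start,
                    end=left[-1].end,
                    left_arm=left,
                    right_arm=[],
                    inner_start=left[-1].end,
                    inner_end=left[-1].end,
                    single_armed=True,
                )
            )
            i += 1
    for n, r in enumerate(regions, start=1):
        r.id = f"RR{n}"
    return regions


def classify_region(region: RepeatRegion) -> str:
    """Orientation class of a bipartite region: ``direct`` when the majority
    core strand of the two arms agrees, ``inverted`` when opposite,
    ``ambiguous`` on a within-arm tie (never silently assigned)."""
    if region.single_armed or not region.right_arm:
        raise ValueError(f"region {region.id} has a single arm; skip orientation classification")

    def majority(arm: list[RepeatUnit]) -> str | None:
        plus = sum(1 for u in arm if u.strand == "+")
        minus = len(arm) - plus
        if plus == minus:
            return None
        return "+" if plus > minus else "-"

    left, right = majority(region.left_arm), majority(region.right_arm)
    if left is None or right is None:
        return "ambiguous"
    return "direct" if left == right else "inverted"


def derive_consensus(units: list[RepeatUnit], genome: Genome, max_mismatches: int = 1) -> ConsensusResult:
    """Longest sequence contained in every unit within the mismatch allowance.

    Units are oriented by their core strand (minus-strand units are
    reverse-complemented). The search is exhaustive over substrings of the
    first oriented unit, so the result is optimal relative to that seed;
    equal-length candidates are ranked by total mismatch count, then
    lexicographically.
    """
    if len(units) < 2:
        raise ValueError("consensus derivation needs at least 2 units")
    seqs = []
    for u in units:
        s = genome.sequence[u.start : u.end]
        seqs.append(revcomp(s) if u.strand == "-" else s)
    arrs = [encode(s) for s in seqs]
    first = arrs[0]
    L0 = len(first)

    def best_at_length(l: int):
        """Best (total_mm, candidate string, per-unit mm) at length l, or None."""
        best = None
        for off in range(L0 - l + 1):
            cand = first[off : off + l]
            total = 0
            per_unit = []
            ok = True
            for arr in arrs:
                n = len(arr) - l + 1
                if n <= 0:
                    ok = False
                    break
                mm = np.zeros(n, dtype=np.int64)
                for j in range(l):
                    mm += arr[j : j + n] != cand[j]
                m = int(mm.min())
                if m > max_mismatches:
                    ok = False
                    break
                per_unit.append(m)
                total += m
            if ok:
                cand_str = seqs[0][off : off + l]
                key = (total, cand_str)
                if best is None or key < (best[0], best[1]):
                    best = (total, cand_str, per_unit)
        return best

    lo, hi = 1, min(len(a) for a in arrs)
    best_len = 0
    # containment is monotone in length: binary search for the longest feasible
    while lo <= hi:
        mid = (lo + hi) // 2
        if best_at_length(mid) is not None:
            best_len = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best_len == 0:
        return ConsensusResult(consensus="", length=0, per_unit_mismatches=[], short_warning=True)
    total, cand, per_unit = best_at_length(best_len)
    return ConsensusResult(
        consensus=cand, length=best_len, per_unit_mismatches=per_unit, short_warning=best_len < 8
    )


def find_repeat_regions(genome: Genome, params: RepeatFinderParams | None = None) -> list[RepeatRegion]:
    """End-to-end detection: motif scan -> units -> regions -> orientation."""
    p = params or RepeatFinderParams()
    hits = scan_core_motif(genome, p.motif, p.max_mismatches)
    units = build_units(hits, p.unit_length_window, p.max_core_spacing, genome_length=len(genome.sequence))
    regions = assemble_regions(units, p.arm_gap_max, p.inner_gap_max, p.min_units_per_arm)
    for r in regions:
        if not r.single_armed:
            r.orientation_class = classify_region(r)
    return regions


def bipartite_regions(regions: list[RepeatRegion], min_units_per_arm: int = 2) -> list[RepeatRegion]:
    """Regions with two qualifying arms — the module delimiters."""
    return [
        r
        for r in regions
        if not r.single_armed
        and len(r.left_arm) >= min_units_per_arm
        and len(r.right_arm) >= min_units_per_arm
    ]


def region_summary_table(regions: list[RepeatRegion]):
    """Region summary (id, span, size, units per arm, orientation, inner)."""
    import pandas as pd

    rows = []
    for r in regions:
        rows.append(
            {
                "region": r.id,
                "start": r.start,
                "end": r.end,
                "size_bp": r.length,
                "units_left": len(r.left_arm),
                "units_right": len(r.right_arm),
                "orientation": r.orientation_class or ("single_armed" if r.single_armed else "unclassified"),
                "inner_bp": r.inner_end - r.inner_start,
                "mean_core_mismatch": round(r.mean_core_mismatch, 3),
            }
        )
    return pd.DataFrame(rows)
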