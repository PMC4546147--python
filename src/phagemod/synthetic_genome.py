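"""Synthetic *Campylobacter* group II phage genomes with ground truth.

The generator emulates the published architecture of the CP220-like virus
genus: circularly permuted genomes of ~27% G+C built from four large modules
(A-D) separated by bipartite repeat regions whose arms hold tandem 72-86 bp
units, each containing the 13-nt core 5'-AAACTTAAAGCAA-3' (at most one
mismatch). Two subgroup arrangements are produced: CP220-like (all modules
forward, tRNA-Arg/Tyr, an internal deletion in the gp047 tail-fiber gene)
and CP21-like (modules B and C inverted in place, tRNA-Thr/Pro, intact
gp047, and only one direct-repeat region instead of two).

Cohorts share an ancestral sequence plan: the two subgroup ancestors
diverge by independent substitution passes, members of a subgroup by a much
smaller pass, and repeat regions plus the sequence flanking them are held
conserved — the premise that makes junction-PCR typing with one primer
panel possible. Backgrounds are actively scrubbed of chance core-motif
matches so the planted repeat architecture is the unique, exact ground
truth; "scattered" single units are planted deliberately instead.

Every random decision flows from a single :class:`numpy.random.SeedSequence`
per cohort, spawned per subgroup and member, so cohorts are reproducible
member-wise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seq import base_probs, decode, encode, hamming_scan, mutate, random_seq, revcomp
from .io_formats import Feature, Genome, HostRangeMatrix

CORE_MOTIF = "AAACTTAAAGCAA"
SUBGROUPS = ("CP21like", "CP220like")

#: tRNA gene identities per subgroup (Thr/Pro vs Arg/Tyr).
SUBGROUP_TRNAS = {"CP21like": ("Thr", "Pro"), "CP220like": ("Arg", "Tyr")}

#: Module orientations per subgroup for the four-module architecture.
SUBGROUP_INVERTED_MODULES = {"CP21like": (1, 2), "CP220like": ()}

#: Indices of regions built from direct (rather than inverted) repeats, in
#: priority order: RR3 is direct in both subgroups, RR1 only in CP220-like.
_DIRECT_PRIORITY = (2, 0, 1, 3)
SUBGROUP_DIRECT_COUNT = {"CP21like": 1, "CP220like": 2}

GP047_LENGTH = 4000
_GP047_SEED = 834047
_FLANK_CONSERVED = 300  # bp at each module edge never mutated (PCR anchor zone)
_SCATTER_MARGIN = 1600  # min distance of scattered units from module edges
_INNER_MIN = 250  # min inner spacer (> default arm_gap_max, keeps arms separate)


# ---------------------------------------------------------------------------
# Core-motif hygiene helpers


def _core_hit_starts(seq: str, motif: str, max_mm: int) -> list[int]:
    arr = encode(seq)
    starts: set[int] = set()
    for pat in (motif, revcomp(motif)):
        mm = hamming_scan(arr, encode(pat, allow_n=False))
        starts.update(int(i) for i in np.flatnonzero(mm <= max_mm))
    return sorted(starts)


def _scrub(
    seq: str,
    rng: np.random.Generator,
    gc: float,
    motif: str,
    max_mm: int,
    core_intervals: list[tuple[int, int]] | None = None,
    max_rounds: int = 60,
) -> str:
    """Resample bases until the sequence holds no chance core-motif match
    (either strand) outside the planted ``core_intervals``."""
    m = len(motif)
    core = sorted(core_intervals or [])
    chars = list(seq)
    probs = base_probs(gc)
    for _ in range(max_rounds):
        offenders = [
            s
            for s in _core_hit_starts("".join(chars), motif, max_mm)
            if not any(s < ce and s + m > cs for cs, ce in core)
        ]
        if not offenders:
            return "".join(chars)
        for s in offenders:
            for i in range(s, min(s + m, len(chars))):
                if any(cs <= i < ce for cs, ce in core):
                    continue
                chars[i] = "ACGT"[rng.choice(4, p=probs)]
    raise RuntimeError("failed to scrub chance core-motif matches")


def _mutate_clean(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    gc: float,
    protected: np.ndarray | None,
    core_intervals: list[tuple[int, int]],
    motif: str,
    max_mm: int,
) -> str:
    """Substitution pass that cannot create new core-motif matches: any
    mutation whose 13-bp neighbourhood gains a chance hit is reverted."""
    new, pos = mutate(seq, rate, rng, gc, protected)
    if len(pos) == 0:
        return new
    m = len(motif)
    offenders = [
        s
        for s in _core_hit_starts(new, motif, max_mm)
        if not any(s < ce and s + m > cs for cs, ce in core_intervals)
    ]
    if not offenders:
        return new
    chars = list(new)
    mutated = set(int(p) for p in pos)
    for s in offenders:
        for i in range(s, min(s + m, len(chars))):
            if i in mutated:
                chars[i] = seq[i]
    return "".join(chars)


# ---------------------------------------------------------------------------
# gp047 reference locus (synthetic stand-in, deterministic)


def _build_gp047_reference() -> str:
    """Synthetic gp047 tail-fiber locus used as the deletion-detection anchor.

    A fixed ~4 kb coding-like stretch at phage-typical base composition,
    generated once from a hard-coded seed and scrubbed of core-motif
    look-alikes; it is the package's stable stand-in for the real receptor
    binding protein gene, not a published sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence(_GP047_SEED))
    seq = random_seq(rng, GP047_LENGTH, 0.272)
    return _scrub(seq, rng, 0.272, CORE_MOTIF, 1)


GP047_REFERENCE = _build_gp047_reference()


# ---------------------------------------------------------------------------
# Configuration and truth


@dataclass
class GeneratorConfig:
    seed: int = 0
    subgroup_label: str = "CP220like"
    genome_length_target: int = 180_000
    n_modules: int = 4
    module_size_range: tuple[int, int] = (28_000, 55_000)
    region_size_range: tuple[int, int] = (1_000, 2_900)
    units_per_arm_range: tuple[int, int] = (3, 18)
    unit_length_range: tuple[int, int] = (72, 86)
    core_motif: str = CORE_MOTIF
    core_mismatches_max: int = 1
    gc_target: float = 0.272
    direct_region_count: int | None = None
    scattered_unit_count: int = 4
    trna_labels: tuple[str, str] | None = None
    gp047_deletion: int | None = None  # bp, in [200, 2500]; sampled if None
    unit_mutation_rate: float = 0.02
    subgroup_divergence: float = 0.015
    member_divergence: float = 0.002
    scale: float = 1.0

    def __post_init__(self):
        for lo, hi in (
            self.module_size_range,
            self.region_size_range,
            self.units_per_arm_range,
            self.unit_length_range,
        ):
            if lo > hi:
                raise ValueError("ranges must be ordered low <= high")
        if not (0 < self.gc_target < 1):
            raise ValueError("gc_target must be in (0, 1)")
        encode(self.core_motif, allow_n=False)
        if self.subgroup_label not in SUBGROUPS:
            raise ValueError(f"subgroup_label must be one of {SUBGROUPS}")
        if self.gp047_deletion is not None and not (200 <= self.gp047_deletion <= 2500):
            raise ValueError("gp047_deletion must lie in [200, 2500] bp")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    # size ranges after applying the scale factor (unit lengths, unit counts
    # and the motif are never scaled — they are sequence-level constants)
    @property
    def scaled_target(self) -> int:
        return int(round(self.genome_length_target * self.scale))

    @property
    def scaled_module_range(self) -> tuple[int, int]:
        return (
            int(round(self.module_size_range[0] * self.scale)),
            int(round(self.module_size_range[1] * self.scale)),
        )

    @property
    def scaled_region_range(self) -> tuple[int, int]:
        lo = int(round(self.region_size_range[0] * self.scale))
        hi = int(round(self.region_size_range[1] * self.scale))
        # floor at the smallest feasible bipartite region
        feasible = 2 * self.units_per_arm_range[0] * self.unit_length_range[1] + _INNER_MIN
        lo = max(lo, feasible)
        hi = max(hi, lo + 120)
        return lo, hi


@dataclass
class TruthRecord:
    """Machine-readable ground truth for one generated genome."""

    genome_id: str
    subgroup: str
    genome_length: int
    regions: list[dict]
    modules: list[dict]
    trna_labels: list[str]
    gp047_start: int | None
    gp047_end: int | None
    gp047_deletion: int
    scattered: list[dict]
    restriction_sites: dict[str, list[int]]
    signature: str


def subgroup_signature(subgroup: str, n_modules: int = 4) -> str:
    inverted = set(SUBGROUP_INVERTED_MODULES[subgroup])
    return ",".join(
        f"{chr(ord('A') + i)}{'-' if i in inverted else '+'}" for i in range(n_modules)
    )


# ---------------------------------------------------------------------------
# Pieces: sequence fragments that carry local features and planted-core masks


@dataclass
class _Piece:
    seq: str
    feats: list[Feature] = field(default_factory=list)
    cores: list[tuple[int, int]] = field(default_factory=list)  # planted core intervals


def _flip_piece(p: _Piece) -> _Piece:
    L = len(p.seq)
    feats = [
        Feature(
            label=f.label,
            start=L - f.end,
            end=L - f.start,
            strand="-" if f.strand == "+" else "+",
            kind=f.kind,
        )
        for f in p.feats
    ]
    cores = sorted((L - e, L - s) for s, e in p.cores)
    return _Piece(seq=revcomp(p.seq), feats=feats, cores=cores)


def _delete_slice(p: _Piece, start: int, end: int) -> _Piece:
    d = end - start
    seq = p.seq[:start] + p.seq[end:]
    feats = []
    for f in p.feats:
        s, e = f.start, f.end
        s = s - d if s >= end else min(s, start)
        e = e - d if e >= end else min(e, start)
        if e > s:
            feats.append(Feature(label=f.label, start=s, end=e, strand=f.strand, kind=f.kind))
    cores = []
    for s, e in p.cores:
        s2 = s - d if s >= end else min(s, start)
        e2 = e - d if e >= end else min(e, start)
        if e2 > s2:
            cores.append((s2, e2))
    return _Piece(seq=seq, feats=feats, cores=cores)


# ---------------------------------------------------------------------------
# Cohort plan (ancestral state shared by every member)


@dataclass
class _RegionPlan:
    unit_len: int
    units: list[str]  # forward-orientation unit sequences
    n_left: int
    inner: str
    cargo: bool


class _CohortPlan:
    """Everything sampled once per cohort: module lengths and ancestral
    sequences, region structures, marker placements."""

    def __init__(self, config: GeneratorConfig, ss: np.random.SeedSequence):
        self.config = c = config
        rng = np.random.default_rng(ss)
        motif, max_mm, gc = c.core_motif, c.core_mismatches_max, c.gc_target
        m = len(motif)

        # --- region plans
        reg_lo, reg_hi = c.scaled_region_range
        n_lo, n_hi = c.units_per_arm_range
        self.regions: list[_RegionPlan] = []
        n_regions = c.n_modules  # circular: one region between each pair of modules
        for _ in range(n_regions):
            u = int(rng.integers(c.unit_length_range[0], c.unit_length_range[1] + 1))
            size = int(rng.integers(reg_lo + 25, max(reg_lo + 26, reg_hi - 25)))
            n_total = (size - _INNER_MIN) // u
            n_total = int(np.clip(n_total, 2 * n_lo, 2 * n_hi))
            inner_len = size - n_total * u
            if inner_len < _INNER_MIN:  # n_total was clipped upward
                n_total = (size - _INNER_MIN) // u
                inner_len = size - n_total * u
            n_left = int(np.clip(round(n_total * rng.uniform(0.35, 0.65)), n_lo, n_total - n_lo))
            n_left = int(np.clip(n_left, n_total - n_hi, n_hi))
            template = self._unit_template(rng, u, motif, max_mm, gc)
            units = [
                self._mutate_unit(template, u, rng, motif, max_mm, gc, c.unit_mutation_rate)
                for _ in range(n_total)
            ]
            inner = _scrub(random_seq(rng, inner_len, gc), rng, gc, motif, max_mm)
            self.regions.append(_RegionPlan(unit_len=u, units=units, n_left=n_left, inner=inner, cargo=False))
        for i in range(min(2, n_regions)):  # RR1 and RR2 carry inner cargo genes
            self.regions[i].cargo = True

        # --- module lengths (rejection sample to hit the genome length target)
        region_total = sum(self._region_span(r) for r in self.regions)
        t_mod = c.scaled_target - region_total
        mod_lo, mod_hi = c.scaled_module_range
        n = c.n_modules
        if not (n * mod_lo <= t_mod <= n * mod_hi):
            raise ValueError(
                f"infeasible config: modules must total {t_mod} bp but the size range allows "
                f"[{n * mod_lo}, {n * mod_hi}]"
            )
        for _ in range(10_000):
            lengths = [int(rng.integers(mod_lo, mod_hi + 1)) for _ in range(n - 1)]
            last = t_mod - sum(lengths)
            if mod_lo <= last <= mod_hi:
                lengths.append(last)
                break
        else:
            raise ValueError("could not sample module lengths for the requested target")
        self.module_lengths = lengths

        # --- marker placements
        la = lengths[0]
        self.trna_intervals = [(1000, 1076), (1200, 1276)] if la >= 1600 + _FLANK_CONSERVED else []
        ld = lengths[-1]
        self.gp047_offset: int | None = None
        if ld >= GP047_LENGTH + 2 * _FLANK_CONSERVED + 800:
            self.gp047_offset = min(2000, ld - GP047_LENGTH - _FLANK_CONSERVED - 400)

        # --- ancestral module sequences with scattered units and gp047 overlaid
        scatter_template = self.regions[0].units[0]
        self.module_seq: list[str] = []
        self.module_cores: list[list[tuple[int, int]]] = []
        self.scattered: list[list[tuple[int, int, str]]] = []  # per module: (start, end, strand)
        core_off = (len(scatter_template) - m) // 2
        scatter_targets = [i % n for i in range(c.scattered_unit_count)]
        for mi, L in enumerate(lengths):
            seq = random_seq(rng, L, gc)
            placed: list[tuple[int, int, str]] = []
            occupied: list[tuple[int, int]] = []
            if mi == n - 1 and self.gp047_offset is not None:
                occupied.append((self.gp047_offset, self.gp047_offset + GP047_LENGTH))
            if mi == 0:
                occupied.extend(self.trna_intervals)
            for _ in range(scatter_targets.count(mi)):
                ulen = len(scatter_template)
                lo, hi = _SCATTER_MARGIN, L - _SCATTER_MARGIN - ulen
                if hi <= lo:
                    continue
                for _try in range(100):
                    pos = int(rng.integers(lo, hi))
                    if all(pos + ulen + 500 <= s or pos >= e + 500 for s, e in occupied):
                        break
                else:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                unit = self._mutate_unit(scatter_template, ulen, rng, motif, max_mm, gc, c.unit_mutation_rate)
                if strand == "-":
                    unit = revcomp(unit)
                seq = seq[:pos] + unit + seq[pos + ulen :]
                placed.append((pos, pos + ulen, strand))
                occupied.append((pos, pos + ulen))
            if mi == n - 1 and self.gp047_offset is not None:
                o = self.gp047_offset
                seq = seq[:o] + GP047_REFERENCE + seq[o + GP047_LENGTH :]
            cores = []
            for s, e, strand in placed:
                if strand == "+":
                    cores.append((s + core_off, s + core_off + m))
                else:
                    ce = e - core_off
                    cores.append((ce - m, ce))
            seq = _scrub(seq, rng, gc, motif, max_mm, cores)
            self.module_seq.append(seq)
            self.module_cores.append(cores)
            self.scattered.append(placed)

        # --- per-member gp047 deletion sizes are sampled downstream; the
        #     breakpoint offset is a plan constant so members share it
        self.gp047_del_offset = 300

        self._fix_junctions(rng)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _region_span(r: "_RegionPlan") -> int:
        return len(r.units) * r.unit_len + len(r.inner)

    @staticmethod
    def _unit_template(rng, u: int, motif: str, max_mm: int, gc: float) -> str:
        """Repeat-unit template with the core motif centered; resampled until
        the doubled template (covering unit-unit junctions) holds no chance
        core match."""
        m = len(motif)
        off = (u - m) // 2
        for _ in range(200):
            left = random_seq(rng, off, gc)
            right = random_seq(rng, u - m - off, gc)
            tpl = left + motif + right
            doubled = tpl + tpl
            hits = _core_hit_starts(doubled, motif, max_mm)
            if all(h in (off, u + off) for h in hits):
                return tpl
        raise RuntimeError("failed to build a clean unit template")

    @staticmethod
    def _mutate_unit(tpl: str, u: int, rng, motif: str, max_mm: int, gc: float, rate: float) -> str:
        """Per-unit copy of the template: flanks mutate at ``rate`` (reverted
        if they spawn chance core hits), the core accumulates at most
        ``max_mm`` mismatches."""
        m = len(motif)
        off = (u - m) // 2
        protected = np.zeros(u, dtype=bool)
        protected[off : off + m] = True
        out = _mutate_clean(tpl, rate, rng, gc, protected, [(off, off + m)], motif, max_mm)
        k = min(int(rng.binomial(m, rate)), max_mm)
        if k:
            chars = list(out)
            probs = base_probs(gc)
            for i in rng.choice(m, size=k, replace=False):
                pos = off + int(i)
                while True:
                    b = "ACGT"[rng.choice(4, p=probs)]
                    if b != chars[pos]:
                        chars[pos] = b
                        break
            out = "".join(chars)
        return out

    def direct_region_indices(self, subgroup: str) -> set[int]:
        c = self.config
        count = c.direct_region_count if c.direct_region_count is not None else SUBGROUP_DIRECT_COUNT[subgroup]
        priority = [i for i in _DIRECT_PRIORITY if i < len(self.regions)]
        priority += [i for i in range(len(self.regions)) if i not in priority]
        return set(priority[:count])

    def region_piece(self, i: int, direct: bool) -> _Piece:
        r = self.regions[i]
        m = len(self.config.core_motif)
        off = (r.unit_len - m) // 2
        left_units = r.units[: r.n_left]
        right_units = r.units[r.n_left :]
        seq_parts: list[str] = []
        feats: list[Feature] = []
        cores: list[tuple[int, int]] = []
        pos = 0
        for u in left_units:
            feats.append(Feature(f"RR{i + 1}_unit", pos, pos + r.unit_len, "+", "repeat_unit"))
            cores.append((pos + off, pos + off + m))
            seq_parts.append(u)
            pos += r.unit_len
        inner_start = pos
        seq_parts.append(r.inner)
        pos += len(r.inner)
        if r.cargo and len(r.inner) >= 60:
            c0 = inner_start + len(r.inner) // 5
            c1 = inner_start + 4 * len(r.inner) // 5
            feats.append(Feature(f"RR{i + 1}_cargo", c0, c1, "+", "gene"))
        if direct:
            for u in right_units:
                feats.append(Feature(f"RR{i + 1}_unit", pos, pos + r.unit_len, "+", "repeat_unit"))
                cores.append((pos + off, pos + off + m))
                seq_parts.append(u)
                pos += r.unit_len
        else:
            for u in reversed(right_units):
                feats.append(Feature(f"RR{i + 1}_unit", pos, pos + r.unit_len, "-", "repeat_unit"))
                # core of a reverse-complemented unit sits mirrored
                cend = pos + r.unit_len - off
                cores.append((cend - m, cend))
                seq_parts.append(revcomp(u))
                pos += r.unit_len
        feats.append(Feature(f"RR{i + 1}", 0, pos, "+", "repeat_region"))
        return _Piece(seq="".join(seq_parts), feats=feats, cores=sorted(cores))

    def _fix_junctions(self, rng) -> None:
        """Resample module-edge bases until no piece junction of either
        subgroup arrangement spawns a chance core-motif match."""
        c = self.config
        motif, max_mm, gc = c.core_motif, c.core_mismatches_max, c.gc_target
        m = len(motif)
        probs = base_probs(gc)
        for _ in range(80):
            dirty = False
            for subgroup in SUBGROUPS:
                direct = self.direct_region_indices(subgroup)
                inverted_modules = set(SUBGROUP_INVERTED_MODULES[subgroup])
                pieces: list[tuple[str, int, bool]] = []  # (kind, index, flipped)
                seqs: list[str] = []
                for i in range(c.n_modules):
                    flip = i in inverted_modules
                    s = self.module_seq[i]
                    seqs.append(revcomp(s) if flip else s)
                    pieces.append(("module", i, flip))
                    seqs.append(self.region_piece(i, i in direct).seq)
                    pieces.append(("region", i, False))
                genome = "".join(seqs)
                offsets = np.cumsum([0] + [len(s) for s in seqs])
                L = len(genome)
                doubled = genome + genome[: m - 1]
                for b in offsets[1:-1].tolist() + [L]:
                    zone_start = max(0, b - m + 1)
                    zone = doubled[zone_start : min(b + m - 1, len(doubled))]
                    for h in _core_hit_starts(zone, motif, max_mm):
                        g = zone_start + h
                        if g + m <= b or g >= b:
                            continue  # does not span this junction
                        dirty = True
                        # resample the module-side bases of the window
                        for gpos in range(g, g + m):
                            gp = gpos % L
                            pi = int(np.searchsorted(offsets, gp, side="right")) - 1
                            kind, idx, flipped = pieces[pi]
                            if kind != "module":
                                continue
                            local = gp - offsets[pi]
                            if flipped:
                                local = len(self.module_seq[idx]) - 1 - local
                            s = self.module_seq[idx]
                            new = "ACGT"[rng.choice(4, p=probs)]
                            self.module_seq[idx] = s[:local] + new + s[local + 1 :]
            if not dirty:
                return
        raise RuntimeError("failed to clean piece junctions of core-motif look-alikes")


# ---------------------------------------------------------------------------
# Realization


def _module_protection(plan: _CohortPlan, mi: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Mutation-protected mask and planted-core intervals for one module."""
    L = len(plan.module_seq[mi])
    prot = np.zeros(L, dtype=bool)
    prot[:_FLANK_CONSERVED] = True
    prot[L - _FLANK_CONSERVED :] = True
    for s, e, _ in plan.scattered[mi]:
        prot[s:e] = True
    if mi == plan.config.n_modules - 1 and plan.gp047_offset is not None:
        o = plan.gp047_offset
        prot[o : o + 50] = True
        prot[o + GP047_LENGTH - 50 : o + GP047_LENGTH] = True
    return prot, list(plan.module_cores[mi])


def _realize_subgroup_modules(plan: _CohortPlan, subgroup: str, ss: np.random.SeedSequence) -> list[str]:
    """Subgroup ancestor: one divergence pass over each module background."""
    c = plan.config
    rng = np.random.default_rng(ss)
    out = []
    for mi, seq in enumerate(plan.module_seq):
        prot, cores = _module_protection(plan, mi)
        out.append(
            _mutate_clean(seq, c.subgroup_divergence, rng, c.gc_target, prot, cores, c.core_motif, c.core_mismatches_max)
        )
    return out


def _find_sites_str(seq: str, site: str, circular: bool) -> list[int]:
    hay = seq + seq[: len(site) - 1] if circular else seq
    out = []
    i = hay.find(site)
    while i != -1:
        if i < len(seq):
            out.append(i)
        i = hay.find(site, i + 1)
    return out


def _realize_member(
    plan: _CohortPlan,
    subgroup: str,
    ancestor_modules: list[str],
    genome_id: str,
    ss: np.random.SeedSequence,
    member_rate: float,
) -> tuple[Genome, TruthRecord]:
    c = plan.config
    rng = np.random.default_rng(ss)
    motif, max_mm, gc = c.core_motif, c.core_mismatches_max, c.gc_target
    n = c.n_modules
    inverted = set(SUBGROUP_INVERTED_MODULES[subgroup])
    direct = plan.direct_region_indices(subgroup)
    trna_labels = list(c.trna_labels or SUBGROUP_TRNAS[subgroup])

    # member-level module sequences
    module_pieces: list[_Piece] = []
    deletion = 0
    for mi in range(n):
        prot, cores = _module_protection(plan, mi)
        seq = _mutate_clean(ancestor_modules[mi], member_rate, rng, gc, prot, cores, motif, max_mm)
        feats: list[Feature] = []
        for s, e, strand in plan.scattered[mi]:
            feats.append(Feature("scattered_unit", s, e, strand, "repeat_unit"))
        if mi == 0:
            for (s, e), label in zip(plan.trna_intervals, trna_labels):
                feats.append(Feature(label, s, e, "+", "tRNA"))
        if mi == n - 1 and plan.gp047_offset is not None:
            o = plan.gp047_offset
            feats.append(Feature("gp047", o, o + GP047_LENGTH, "+", "gene"))
        piece = _Piece(seq=seq, feats=feats, cores=list(cores))
        if mi == n - 1 and plan.gp047_offset is not None and subgroup == "CP220like":
            size = c.gp047_deletion
            if size is None:
                size = int(rng.integers(200, 2501))
            o = plan.gp047_offset
            ds = o + plan.gp047_del_offset
            piece = _delete_slice(piece, ds, ds + size)
            deletion = size
        if mi in inverted:
            piece = _flip_piece(piece)
        module_pieces.append(piece)

    # assemble module-region alternation
    pieces: list[_Piece] = []
    module_meta: list[dict] = []
    region_meta: list[dict] = []
    offset = 0
    all_feats: list[Feature] = []
    seq_parts: list[str] = []
    scattered_global: list[dict] = []
    gp_start = gp_end = None
    for mi in range(n):
        mp = module_pieces[mi]
        orient = "-" if mi in inverted else "+"
        module_meta.append(
            {"id": chr(ord("A") + mi), "start": offset, "end": offset + len(mp.seq), "orientation": orient}
        )
        all_feats.append(
            Feature(chr(ord("A") + mi), offset, offset + len(mp.seq), orient, "module")
        )
        for f in mp.feats:
            g = Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind)
            all_feats.append(g)
            if f.label == "scattered_unit":
                scattered_global.append({"start": g.start, "end": g.end, "strand": g.strand})
            if f.label == "gp047":
                gp_start, gp_end = g.start, g.end
        seq_parts.append(mp.seq)
        offset += len(mp.seq)

        rp = plan.region_piece(mi, mi in direct)
        left_n = plan.regions[mi].n_left
        right_n = len(plan.regions[mi].units) - left_n
        region_meta.append(
            {
                "id": f"RR{mi + 1}",
                "start": offset,
                "end": offset + len(rp.seq),
                "inner_start": offset + left_n * plan.regions[mi].unit_len,
                "inner_end": offset + left_n * plan.regions[mi].unit_len + len(plan.regions[mi].inner),
                "n_left": left_n,
                "n_right": right_n,
                "left_strand": "+",
                "right_strand": "+" if mi in direct else "-",
                "orientation_class": "direct" if mi in direct else "inverted",
            }
        )
        for f in rp.feats:
            all_feats.append(Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind))
        seq_parts.append(rp.seq)
        offset += len(rp.seq)

    sequence = "".join(seq_parts)
    genome = Genome(id=genome_id, sequence=sequence, topology="circular", features=all_feats)
    truth = TruthRecord(
        genome_id=genome_id,
        subgroup=subgroup,
        genome_length=len(sequence),
        regions=region_meta,
        modules=module_meta,
        trna_labels=trna_labels,
        gp047_start=gp_start,
        gp047_end=gp_end,
        gp047_deletion=deletion,
        scattered=scattered_global,
        restriction_sites={
            "VspI": _find_sites_str(sequence, "ATTAAT", True),
            "SmiI": _find_sites_str(sequence, "ATTTAAAT", True),
        },
        signature=subgroup_signature(subgroup, n),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Public generators


def generate_genome(config: GeneratorConfig) -> tuple[Genome, TruthRecord]:
    """One genome plus its ground truth. Identical seed and config give
    identical output; different seeds change the sequence but not the
    subgroup architecture."""
    ss = np.random.SeedSequence(config.seed)
    plan_ss, sub_ss, mem_ss = ss.spawn(3)
    plan = _CohortPlan(config, plan_ss)
    ancestors = _realize_subgroup_modules(plan, config.subgroup_label, sub_ss)
    return _realize_member(
        plan, config.subgroup_label, ancestors, f"{config.subgroup_label}_1", mem_ss, member_rate=0.0
    )


def generate_cohort(
    n_per_subgroup: int,
    base_config: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[tuple[Genome, TruthRecord]]:
    """A cohort of ``n_per_subgroup`` genomes per subgroup sharing one
    ancestral plan: members of a subgroup share module order and marker
    states but differ in background sequence; cross-subgroup pairs differ in
    architecture signature."""
    if n_per_subgroup < 1:
        raise ValueError("n_per_subgroup must be >= 1")
    config = base_config or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    plan_ss, rest = ss.spawn(2)
    plan = _CohortPlan(config, plan_ss)
    out: list[tuple[Genome, TruthRecord]] = []
    sub_streams = rest.spawn(2 * len(SUBGROUPS))
    for gi, subgroup in enumerate(("CP220like", "CP21like")):
        anc_ss = sub_streams[2 * gi]
        member_root = sub_streams[2 * gi + 1]
        ancestors = _realize_subgroup_modules(plan, subgroup, anc_ss)
        for i, mss in enumerate(member_root.spawn(n_per_subgroup)):
            gid = f"{subgroup}_{i + 1}"
            out.append(
                _realize_member(plan, subgroup, ancestors, gid, mss, member_rate=config.member_divergence)
            )
    return out


# ---------------------------------------------------------------------------
# Host range


NON_HOST_SPECIES = [("C. lari", 5), ("C. fetus", 2), ("C. sputorum", 2), ("C. hyointestinalis", 1)]

DEFAULT_SUSCEPTIBILITY = {
    "CP220like": {"C. jejuni": 0.10, "C. coli": 0.56},
    "CP21like": {"C. jejuni": 0.06, "C. coli": 0.22},
}


def generate_hostrange(
    cohort_truth: list[TruthRecord],
    n_jejuni: int = 227,
    n_coli: int = 18,
    susceptibility: dict | None = None,
    seed: int = 0,
    profile_noise: float = 0.1,
) -> HostRangeMatrix:
    """Spot-assay matrix for a cohort's phages over a strain panel.

    Strains of host species draw a shared latent susceptibility per
    subgroup (z ~ Bernoulli(p)); each phage copies the latent state with
    probability ``1 - profile_noise`` and otherwise redraws Bernoulli(p),
    so same-subgroup lysis profiles correlate while each phage's marginal
    positive rate stays exactly p. Non-host species are never lysed.
    """
    susceptibility = susceptibility if susceptibility is not None else DEFAULT_SUSCEPTIBILITY
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    strains: list[tuple[str, str]] = []
    strains += [(f"Cj{i + 1:03d}", "C. jejuni") for i in range(n_jejuni)]
    strains += [(f"Cc{i + 1:02d}", "C. coli") for i in range(n_coli)]
    for sp, k in NON_HOST_SPECIES:
        code = sp.split(". ")[1][:3]
        strains += [(f"{code}{i + 1}", sp) for i in range(k)]
    phages = [t.genome_id for t in cohort_truth]
    subgroups = {t.genome_id: t.subgroup for t in cohort_truth}
    groups = sorted({t.subgroup for t in cohort_truth})
    values = np.zeros((len(strains), len(phages)), dtype=np.int64)
    for si, (sid, sp) in enumerate(strains):
        latent = {}
        for g in groups:
            p = susceptibility.get(g, {}).get(sp, 0.0)
            latent[g] = (rng.random() < p, p)
        for pi, ph in enumerate(phages):
            z, p = latent[subgroups[ph]]
            if rng.random() < profile_noise:
                values[si, pi] = 1 if rng.random() < p else 0
            else:
                values[si, pi] = 1 if z else 0
    return HostRangeMatrix(strains=strains, phages=phages, values=values.tolist())


# ---------------------------------------------------------------------------
# Truth-file round trip (TSV: genome_id, field, JSON value)


def truth_to_tsv(records: list[TruthRecord], path) -> None:
    rows = []
    for r in records:
        for k, v in asdict(r).items():
            rows.append({"genome_id": r.genome_id, "field": k, "value": json.dumps(v)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def truth_from_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for gid in df["genome_id"].unique():
        sub = df[df["genome_id"] == gid]
        kwargs = {row["field"]: json.loads(row["value"]) for _, row in sub.iterrows()}
        out.append(TruthRecord(**kwargs))
    return out
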