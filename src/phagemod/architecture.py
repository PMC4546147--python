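"""Modular genome architecture: segmentation, dot plots, inversions,
contig ordering.

Group II *Campylobacter* phage genomes consist of large (28-55 kb) modules
separated by repeat regions. Module homology between genomes is established
here by exact shared k-mers chained into collinear runs (a formalization of
dot-plot inspection); repeat-region sequence is masked before chaining since
the regions are near-identical genome-wide and would bridge unrelated
modules. The subgroup-defining object is the architecture signature: the
ordered list of reference-module identities with orientations (e.g.
``A+,B-,C-,D+`` for the CP21-like arrangement).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, hamming_scan, kmer_codes, revcomp
from .io_formats import Genome, PrimerEntry, PrimerPanel
from .insilico_assays import Amplicon, virtual_pcr
from .repeat_finder import RepeatRegion

_MODULE_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class ModuleSegment:
    """A genome segment between consecutive repeat regions. ``end < start``
    encodes a segment wrapping the origin of a circular genome."""

    id: str
    start: int
    end: int
    genome_length: int

    @property
    def wraps(self) -> bool:
        return self.end <= self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return self.genome_length - self.start + self.end
        return self.end - self.start

    def pieces(self) -> list[tuple[int, int]]:
        """Linear sub-intervals covering the segment."""
        if not self.wraps:
            return [(self.start, self.end)]
        out = []
        if self.start < self.genome_length:
            out.append((self.start, self.genome_length))
        if self.end > 0:
            out.append((0, self.end))
        return out


@dataclass
class DotPlotMatch:
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    orientation: str  # '+' | '-'
    matched_length: int  # union of query k-mer window coverage
    n_kmers: int


@dataclass
class DotPlot:
    query_id: str
    subject_id: str
    k: int
    matches: list[DotPlotMatch]


@dataclass
class SignatureEntry:
    query_module: str
    subject_module: str | None  # None = unassigned (matched fraction < min_cov)
    orientation: str | None
    matched_fraction: float
    ambiguous_with: str | None = None  # runner-up within 5% matched length


@dataclass
class ArchitectureSignature:
    reference_id: str
    query_id: str
    entries: list[SignatureEntry]

    def as_string(self) -> str:
        parts = []
        for e in self.entries:
            if e.subject_module is None:
                parts.append(f"{e.query_module}?")
            else:
                parts.append(f"{e.subject_module}{e.orientation}")
        return ",".join(parts)


@dataclass
class ContigOrder:
    order: list[tuple[str, str]]  # (contig id, orientation)
    gaps: list[int]  # per-junction gap estimates
    total_length: int
    circular: bool


# ---------------------------------------------------------------------------
# Module segmentation


def segment_modules(genome: Genome, regions: list[RepeatRegion]) -> list[ModuleSegment]:
    """Segments between consecutive repeat-region spans.

    n regions on a circular genome give n modules (one wraps the origin if a
    region does not abut it); n regions on a linear genome give n+1 (terminal
    segments may be fragments of one wrapped module). Modules are named
    alphabetically from the genome origin. Empty segments (abutting regions)
    are dropped after the overlap check.
    """
    L = len(genome.sequence)
    spans = sorted((r.start, r.end) for r in regions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"repeat regions overlap: [{s1},{e1}) and [{s2},{e2})")
    if not spans:
        return [ModuleSegment(id="A", start=0, end=L, genome_length=L)]

    segments: list[ModuleSegment] = []
    if genome.topology == "circular":
        for (s, e), (s2, _) in zip(spans, spans[1:]):
            segments.append(ModuleSegment(id="", start=e, end=s2, genome_length=L))
        # wrapping segment: after the last region, through the origin, to the first
        segments.append(ModuleSegment(id="", start=spans[-1][1] % L, end=spans[0][0], genome_length=L))
        segments = [m for m in segments if m.length > 0]
        # name from the origin: the segment containing position 0 first
        def from_origin(m: ModuleSegment) -> int:
            return 0 if (m.wraps or m.start == 0) else m.start

        segments.sort(key=from_origin)
    else:
        bounds = [0] + [x for span in spans for x in span] + [L]
        for s, e in zip(bounds[::2], bounds[1::2]):
            if e > s:
                segments.append(ModuleSegment(id="", start=s, end=e, genome_length=L))
    for i, m in enumerate(segments):
        m.id = _MODULE_NAMES[i]
    total = sum(m.length for m in segments) + sum(e - s for s, e in spans)
    assert total == L, "modules plus regions must tile the genome exactly"
    return segments


# ---------------------------------------------------------------------------
# Dot plot


def _mask_array(length: int, intervals) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals or []:
        mask[max(0, s) : min(length, e)] = True
    return mask


def compute_dotplot(
    query: Genome,
    subject: Genome,
    k: int = 31,
    chain_gap: int = 500,
    band: int = 50,
    min_run: int = 200,
    query_mask=None,
    subject_mask=None,
    max_kmer_occurrences: int = 10,
) -> DotPlot:
    """Exact shared k-mers (both strands) chained into collinear runs.

    Runs group matches of one orientation on nearby (anti)diagonals
    (within ``band``) with query gaps at most ``chain_gap``; runs covering
    fewer than ``min_run`` query bp are dropped. ``*_mask`` intervals
    (typically repeat-region spans) are excluded from seeding.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    q_arr = encode(query.sequence)
    s_arr = encode(subject.sequence)
    q_codes, q_valid = kmer_codes(q_arr, k)
    s_codes, s_valid = kmer_codes(s_arr, k)
    qm = _mask_array(len(q_arr), query_mask)
    sm = _mask_array(len(s_arr), subject_mask)
    # a k-mer is masked if any of its bases is masked
    if len(q_codes):
        q_valid = q_valid & ~np.array([qm[i : i + k].any() for i in range(len(q_codes))])
    if len(s_codes):
        s_valid = s_valid & ~np.array([sm[i : i + k].any() for i in range(len(s_codes))])

    index: dict[int, list[int]] = defaultdict(list)
    for i in np.flatnonzero(s_valid):
        index[int(s_codes[i])].append(int(i))

    rc_cache: dict[int, int] = {}

    def rc_code(code: int) -> int:
        # reverse complement of a 2-bit packed k-mer
        if code in rc_cache:
            return rc_cache[code]
        out = 0
        c = code
        for _ in range(k):
            out = (out << 2) | ((c & 3) ^ 3)
            c >>= 2
        rc_cache[code] = out
        return out

    plus: list[tuple[int, int]] = []  # (q, s)
    minus: list[tuple[int, int]] = []
    for qi in np.flatnonzero(q_valid):
        code = int(q_codes[qi])
        hits = index.get(code)
        if hits and len(hits) <= max_kmer_occurrences:
            for si in hits:
                plus.append((int(qi), si))
        rhits = index.get(rc_code(code))
        if rhits and len(rhits) <= max_kmer_occurrences:
            for si in rhits:
                minus.append((int(qi), si))

    matches: list[DotPlotMatch] = []

    def chain(pairs: list[tuple[int, int]], orient: str) -> None:
        if not pairs:
            return
        if orient == "+":
            keyed = sorted(pairs, key=lambda p: (p[0] - p[1], p[0]))
            diag = lambda p: p[0] - p[1]
        else:
            keyed = sorted(pairs, key=lambda p: (p[0] + p[1], p[0]))
            diag = lambda p: p[0] + p[1]
        run: list[tuple[int, int]] = []

        def flush(run):
            if not run:
                return
            qs = sorted(p[0] for p in run)
            # union of k-length windows over query
            covered = 0
            cur_s, cur_e = qs[0], qs[0] + k
            for q in qs[1:]:
                if q <= cur_e:
                    cur_e = max(cur_e, q + k)
                else:
                    covered += cur_e - cur_s
                    cur_s, cur_e = q, q + k
            covered += cur_e - cur_s
            if covered < min_run:
                return
            ss = [p[1] for p in run]
            matches.append(
                DotPlotMatch(
                    query_start=min(qs),
                    query_end=max(qs) + k,
                    subject_start=min(ss),
                    subject_end=max(ss) + k,
                    orientation=orient,
                    matched_length=covered,
                    n_kmers=len(run),
                )
            )

        for p in keyed:
            if run and (abs(diag(p) - diag(run[-1])) > band or abs(p[0] - run[-1][0]) > chain_gap):
                flush(run)
                run = []
            run.append(p)
        flush(run)

    chain(plus, "+")
    chain(minus, "-")
    matches.sort(key=lambda m: (m.query_start, m.subject_start))
    return DotPlot(query_id=query.id, subject_id=subject.id, k=k, matches=matches)


# ---------------------------------------------------------------------------
# Architecture comparison


def _overlap(a_start: int, a_end: int, pieces) -> int:
    return sum(max(0, min(a_end, e) - max(a_start, s)) for s, e in pieces)


def compare_architectures(
    query: Genome,
    query_modules: list[ModuleSegment],
    subject: Genome,
    subject_modules: list[ModuleSegment],
    k: int = 31,
    min_cov: float = 0.3,
    query_region_spans=None,
    subject_region_spans=None,
    **dotplot_kwargs,
) -> ArchitectureSignature:
    """Assign each query module its best-matching subject module and the
    majority orientation of the matched length.

    Modules with matched fraction below ``min_cov`` are reported unassigned;
    a runner-up subject within 5% matched length flags the entry ambiguous
    rather than being resolved silently.
    """
    dp = compute_dotplot(
        query,
        subject,
        k=k,
        query_mask=query_region_spans,
        subject_mask=subject_region_spans,
        **dotplot_kwargs,
    )
    entries: list[SignatureEntry] = []
    for qm in query_modules:
        qpieces = qm.pieces()
        scores: dict[str, float] = defaultdict(float)
        orient_scores: dict[str, dict[str, float]] = defaultdict(lambda: {"+": 0.0, "-": 0.0})
        for m in dp.matches:
            q_ov = _overlap(m.query_start, m.query_end, qpieces)
            if q_ov <= 0:
                continue
            for sm in subject_modules:
                s_ov = _overlap(m.subject_start, m.subject_end, sm.pieces())
                if s_ov <= 0:
                    continue
                w = min(q_ov, s_ov) * (m.matched_length / max(1, m.query_end - m.query_start))
                scores[sm.id] += w
                orient_scores[sm.id][m.orientation] += w
        if not scores:
            entries.append(SignatureEntry(qm.id, None, None, 0.0))
            continue
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best, best_score = ranked[0]
        frac = best_score / max(1, qm.length)
        if frac < min_cov:
            entries.append(SignatureEntry(qm.id, None, None, round(frac, 4)))
            continue
        ambiguous = None
        if len(ranked) > 1 and ranked[1][1] >= 0.95 * best_score:
            ambiguous = ranked[1][0]
        o = orient_scores[best]
        orientation = "+" if o["+"] >= o["-"] else "-"
        entries.append(SignatureEntry(qm.id, best, orientation, round(frac, 4), ambiguous))
    return ArchitectureSignature(reference_id=subject.id, query_id=query.id, entries=entries)


# ---------------------------------------------------------------------------
# Contig ordering across repeat gaps


def design_end_primers(contigs: list[Genome], primer_len: int = 30, offset: int = 600) -> PrimerPanel:
    """Primer panel anchored near contig ends for junction PCR.

    For each contig a forward primer ending ``offset`` bp before its right
    end and a reverse primer (reverse complement) starting ``offset`` bp
    after its left end. ``offset`` should exceed half the longest repeat
    region so primers sit in unique flanking sequence when contigs are cut
    inside repeat regions.
    """
    entries = []
    for c in contigs:
        L = len(c.sequence)
        if L < 2 * (offset + primer_len):
            raise ValueError(f"contig {c.id} too short for end-primer design at offset {offset}")
        fwd = c.sequence[L - offset - primer_len : L - offset]
        rev = revcomp(c.sequence[offset : offset + primer_len])
        entries.append(PrimerEntry(f"{c.id}__end_f", fwd, "forward"))
        entries.append(PrimerEntry(f"{c.id}__start_r", rev, "reverse"))
    return PrimerPanel(entries=entries)


def _locate_primer(contig: Genome, primer: str, max_mismatches: int = 2):
    """Occurrences of a primer on both strands of a contig:
    list of (start, end, strand)."""
    arr = encode(contig.sequence)
    out = []
    for strand, p in (("+", primer), ("-", revcomp(primer))):
        mm = hamming_scan(arr, encode(p, allow_n=False))
        for i in np.flatnonzero(mm <= max_mismatches):
            out.append((int(i), int(i) + len(p), strand))
    return out


def order_contigs(
    contigs: list[Genome],
    panel: PrimerPanel,
    amplicons: list[Amplicon],
    circular: bool = True,
    max_mismatches: int = 2,
    end_window: int = 2000,
) -> ContigOrder:
    """Order and orient contigs from junction amplicons.

    Each amplicon whose forward primer anchors near the end of one contig
    and whose reverse primer anchors near the start of another adds a
    directed edge between the two (oriented) contigs, with the gap estimate
    ``product length - distance(forward primer, contig end) -
    distance(contig start, reverse primer end)`` measured from the primer
    match positions on the contigs. A unique Hamiltonian path (or cycle in
    circular mode) is required; missing or conflicting junctions raise an
    error naming them.
    """
    by_id = {c.id: c for c in contigs}
    # primer -> possible (contig, contig orientation, distance to the relevant end)
    tail_anchor: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    head_anchor: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    for e in panel.entries:
        for c in contigs:
            for s, t, strand in _locate_primer(c, e.sequence, max_mismatches):
                L = len(c.sequence)
                if e.role == "forward":
                    # extension runs rightward from the match
                    if strand == "+" and L - s <= end_window:
                        tail_anchor[e.name].append((c.id, "+", L - s))
                    elif strand == "-" and t <= end_window:
                        tail_anchor[e.name].append((c.id, "-", t))
                else:
                    if strand == "-" and t <= end_window:
                        head_anchor[e.name].append((c.id, "+", t))
                    elif strand == "+" and L - s <= end_window:
                        head_anchor[e.name].append((c.id, "-", L - s))

    edges: dict[tuple[str, str], tuple[str, str, int]] = {}
    in_deg: dict[tuple[str, str], tuple[str, str]] = {}
    conflicts: list[str] = []
    for a in amplicons:
        tails = tail_anchor.get(a.forward_name, [])
        heads = head_anchor.get(a.reverse_name, [])
        if len(tails) != 1 or len(heads) != 1:
            continue  # primer not uniquely anchored at a contig end
        (xc, xo, dx), (yc, yo, dy) = tails[0], heads[0]
        if xc == yc:
            continue  # self edge: amplicon within one contig or around it
        gap = a.product_length - dx - dy
        key = (xc, xo)
        val = (yc, yo, gap)
        if key in edges and edges[key][:2] != val[:2]:
            conflicts.append(f"{xc}({xo}) -> both {edges[key][0]} and {yc}")
        edges[key] = val
        in_deg[(yc, yo)] = (xc, xo)
    if conflicts:
        raise ValueError("conflicting junction evidence: " + "; ".join(sorted(set(conflicts))))

    n = len(contigs)
    # walk the chain
    start = (contigs[0].id, "+")
    if start not in edges and (contigs[0].id, "-") in edges:
        start = (contigs[0].id, "-")
    if not circular:
        # find the unique head: a node with no incoming edge
        heads_set = {k for k in edges} | {v[:2] for v in edges.values()}
        starts = [k for k in heads_set if k not in in_deg and k[0] in by_id]
        if len(starts) == 1:
            start = starts[0]
    order = [start]
    gaps: list[int] = []
    seen = {start[0]}
    cur = start
    while len(order) < n:
        if cur not in edges:
            missing = f"after {cur[0]}"
            raise ValueError(f"no unique contig path: junction unresolved {missing}")
        yc, yo, gap = edges[cur]
        if yc in seen:
            raise ValueError(f"no unique contig path: contig {yc} reached twice")
        order.append((yc, yo))
        gaps.append(gap)
        seen.add(yc)
        cur = (yc, yo)
    if circular:
        if cur not in edges or edges[cur][0] != start[0]:
            raise ValueError(f"no unique contig path: closing junction after {cur[0]} missing")
        gaps.append(edges[cur][2])
    total = sum(len(by_id[cid].sequence) for cid, _ in order) + sum(gaps)
    return ContigOrder(order=order, gaps=gaps, total_length=total, circular=circular)


def dotplot_table(dp: DotPlot):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query": dp.query_id,
                "subject": dp.subject_id,
                "query_start": m.query_start,
                "query_end": m.query_end,
                "subject_start": m.subject_start,
                "subject_end": m.subject_end,
                "orientation": m.orientation,
                "matched_bp": m.matched_length,
                "kmers": m.n_kmers,
            }
            for m in dp.matches
        ]
    )


def plot_dotplot(dp: DotPlot, path) -> None:
    """Scatter rendering of chained matches (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for m in dp.matches:
        if m.orientation == "+":
            ax.plot([m.query_start, m.query_end], [m.subject_start, m.subject_end], "b-", lw=1)
        else:
            ax.plot([m.query_start, m.query_end], [m.subject_end, m.subject_start], "r-", lw=1)
    ax.set_xlabel(dp.query_id)
    ax.set_ylabel(dp.subject_id)
    fig.savefig(path, dpi=120)
    plt.close(fig)
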