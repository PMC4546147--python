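"""In-silico restriction digestion and PCR.

Both wet-lab typing assays used for *Campylobacter* group II phages —
digestion with AT-only restriction endonucleases (VspI, SmiI) and PCR with
long (up to 40 nt) primers spanning repeat-region junctions — are simulated
as deterministic sequence computations. Fragment-size patterns stand in for
gel lanes; a gel-style pattern distance (greedy fragment matching at a
relative size tolerance) and UPGMA clustering make the subgroup comparison
computable.

No thermodynamic primer model is used: specificity is controlled only by a
total mismatch budget and an exact-match requirement at the 3' terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._seq import encode, hamming_scan, revcomp
from .io_formats import Genome, PrimerEntry, PrimerPanel


@dataclass
class Enzyme:
    name: str
    site: str  # recognition sequence, top strand
    cut_offset: int  # bp from site start, top strand

    def __post_init__(self):
        self.site = self.site.upper()
        encode(self.site, allow_n=False)
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut offset must lie within the recognition site")


#: Built-in enzymes. Offsets follow the standard definitions (VspI AT^TAAT,
#: SmiI ATTT^AAAT); fragment sizes, not fragment ends, drive all comparisons.
ENZYMES = {
    "VspI": Enzyme("VspI", "ATTAAT", 2),
    "SmiI": Enzyme("SmiI", "ATTTAAAT", 4),
}


@dataclass
class DigestPattern:
    enzyme: str
    genome_id: str
    fragments: list[int]  # sorted descending, gel-style
    topology: str

    def __post_init__(self):
        self.fragments = sorted((int(f) for f in self.fragments), reverse=True)


@dataclass
class Amplicon:
    forward_name: str
    forward_start: int
    forward_end: int
    forward_mismatches: int
    reverse_name: str
    reverse_start: int
    reverse_end: int
    reverse_mismatches: int
    product_start: int
    product_length: int

    @property
    def product_end(self) -> int:
        """End coordinate on the (possibly extended) template; exceeds the
        genome length for origin-spanning products on circular templates."""
        return self.product_start + self.product_length


# ---------------------------------------------------------------------------
# Restriction digestion


def find_sites(genome: Genome, enzyme: Enzyme) -> list[int]:
    """Start positions of all top-strand occurrences of the recognition
    site (overlapping occurrences each count; N never matches). Circular
    genomes are scanned across the origin."""
    seq = genome.sequence
    L = len(seq)
    if genome.topology == "circular" and L > len(enzyme.site):
        seq = seq + genome.sequence[: len(enzyme.site) - 1]
    mm = hamming_scan(encode(seq), encode(enzyme.site, allow_n=False))
    return [int(i) for i in np.flatnonzero(mm == 0)]


def digest(genome: Genome, enzyme: Enzyme | str) -> DigestPattern:
    """Fragment-length pattern of a complete digest under the genome's
    topology. Linear genome with s sites -> s+1 fragments; circular with
    s >= 1 sites -> s fragments."""
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    L = len(genome.sequence)
    cuts = sorted((s + enzyme.cut_offset) % L for s in find_sites(genome, enzyme))
    if genome.topology == "linear":
        bounds = [0] + cuts + [L]
        frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
        if not cuts:
            frags = [L]
    else:
        if not cuts:
            frags = [L]
        else:
            frags = [b - a for a, b in zip(cuts, cuts[1:])]
            frags.append(L - cuts[-1] + cuts[0])
    pattern = DigestPattern(enzyme=enzyme.name, genome_id=genome.id, fragments=frags, topology=genome.topology)
    assert sum(pattern.fragments) == L, "digest fragments must sum to genome length"
    return pattern


def pattern_distance(a: DigestPattern, b: DigestPattern, size_tolerance: float = 0.05) -> float:
    """1 - Dice coefficient of greedily matched fragments.

    Two fragments match when their lengths differ by at most
    ``size_tolerance`` relative to the larger one (emulating gel
    resolution). Matching proceeds in descending size order, largest first,
    each fragment used once — the way a gel is read.
    """
    if a.enzyme != b.enzyme:
        raise ValueError(f"cannot compare patterns from different enzymes ({a.enzyme} vs {b.enzyme})")
    fa = sorted(a.fragments, reverse=True)
    fb = sorted(b.fragments, reverse=True)
    used = [False] * len(fb)
    matched = 0
    for x in fa:
        for j, y in enumerate(fb):
            if used[j]:
                continue
            if abs(x - y) <= size_tolerance * max(x, y):
                used[j] = True
                matched += 1
                break
    if not fa and not fb:
        return 0.0
    dice = 2.0 * matched / (len(fa) + len(fb))
    return 1.0 - dice


@dataclass
class Dendrogram:
    """UPGMA tree over digest patterns (or any labelled distance matrix)."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, average method

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6f},{right}:{dr:.6f})"

        return walk(tree) + ";"

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}


def cluster_patterns(patterns: list[DigestPattern], size_tolerance: float = 0.05) -> Dendrogram:
    """UPGMA (average linkage) dendrogram over pairwise pattern distances.

    Leaf order is deterministic (input order feeds scipy's deterministic
    agglomeration; ties resolve by index)."""
    if len(patterns) < 2:
        raise ValueError("clustering needs at least 2 patterns")
    enzymes = {p.enzyme for p in patterns}
    if len(enzymes) > 1:
        raise ValueError(f"patterns from multiple enzymes: {sorted(enzymes)}")
    n = len(patterns)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pattern_distance(patterns[i], patterns[j], size_tolerance)
    link = hierarchy.linkage(squareform(dm, checks=False), method="average")
    return Dendrogram(labels=[p.genome_id for p in patterns], linkage=link)


# ---------------------------------------------------------------------------
# Virtual PCR


@dataclass
class _PrimerMatch:
    start: int
    end: int
    strand: str
    mismatches: int


def _primer_matches(
    template_arr: np.ndarray,
    genome_len: int,
    primer: str,
    strand: str,
    max_mismatches: int,
    three_prime_exact: int,
) -> list[_PrimerMatch]:
    """Matches of a primer on one strand of a (possibly origin-extended)
    template. The 3'-terminal ``three_prime_exact`` bases must match exactly;
    on the plus strand these are the rightmost bases of the window, on the
    minus strand the leftmost."""
    p = primer if strand == "+" else revcomp(primer)
    pat = encode(p, allow_n=False)
    mm = hamming_scan(template_arr, pat)
    if len(mm) == 0:
        return []
    t = min(three_prime_exact, len(p))
    if strand == "+":
        tail = pat[-t:] if t else pat[:0]
        off = len(p) - t
    else:
        tail = pat[:t]
        off = 0
    mm3 = hamming_scan(template_arr, tail) if t else np.zeros(len(mm), dtype=np.int64)
    out = []
    for i in np.flatnonzero(mm <= max_mismatches):
        if i >= genome_len:  # wrapped duplicate of a start already seen
            continue
        if t and mm3[i + off] > 0:
            continue
        out.append(_PrimerMatch(int(i), int(i) + len(p), strand, int(mm[i])))
    return out


def virtual_pcr(
    template: Genome,
    panel: PrimerPanel,
    max_mismatches: int = 2,
    three_prime_exact: int = 3,
    max_product: int = 6000,
) -> list[Amplicon]:
    """All products of every forward x reverse primer combination.

    A product requires the forward primer on the plus strand and the reverse
    primer on the minus strand with its 3' end downstream of the forward 3'
    end, within the mismatch budget (3'-terminal bases exact) and at most
    ``max_product`` bp long. Circular templates allow origin-spanning
    products. Results are sorted by product length.
    """
    if not panel.entries:
        return []
    L = len(template.sequence)
    seq = template.sequence
    maxp = max(len(e.sequence) for e in panel.entries)
    if template.topology == "circular" and L > maxp:
        seq = seq + template.sequence[: maxp - 1]
    arr = encode(seq)
    fwd_matches = {
        e.name: _primer_matches(arr, L, e.sequence, "+", max_mismatches, three_prime_exact)
        for e in panel.forward
    }
    rev_matches = {
        e.name: _primer_matches(arr, L, e.sequence, "-", max_mismatches, three_prime_exact)
        for e in panel.reverse
    }
    amplicons: list[Amplicon] = []
    for f in panel.forward:
        for r in panel.reverse:
            for fm in fwd_matches[f.name]:
                for rm in rev_matches[r.name]:
                    if rm.start >= fm.end:
                        length = rm.end - fm.start
                    elif template.topology == "circular":
                        length = L - fm.start + rm.end
                    else:
                        continue
                    if length <= max_product:
                        amplicons.append(
                            Amplicon(
                                forward_name=f.name,
                                forward_start=fm.start,
                                forward_end=fm.end,
                                forward_mismatches=fm.mismatches,
                                reverse_name=r.name,
                                reverse_start=rm.start,
                                reverse_end=rm.end,
                                reverse_mismatches=rm.mismatches,
                                product_start=fm.start,
                                product_length=length,
                            )
                        )
    amplicons.sort(key=lambda a: (a.product_length, a.product_start))
    return amplicons


def typing_pcr(
    template: Genome,
    junction_panels: dict[str, PrimerPanel],
    max_mismatches: int = 2,
    three_prime_exact: int = 3,
    max_product: int = 6000,
) -> dict[str, list[int]]:
    """Per-junction amplicon lengths; a junction is positive when it yields
    at least one product within ``max_product``. The positive/negative
    profile over junctions is the PCR typing result."""
    profile: dict[str, list[int]] = {}
    for label, panel in junction_panels.items():
        amps = virtual_pcr(template, panel, max_mismatches, three_prime_exact, max_product)
        profile[label] = [a.product_length for a in amps]
    return profile


def design_typing_panels(
    reference: Genome,
    module_intervals: list[tuple[str, int, int]],
    primer_len: int = 30,
    offset: int = 60,
) -> dict[str, PrimerPanel]:
    """Junction primer panels for the two known modular arrangements.

    Primers are taken from the sequence just inside each module boundary of
    a reference genome with the all-forward (CP220-like) arrangement.
    For each inter-module junction two alternative primer pairs are built:
    one productive when the downstream module is in reference orientation
    ("CP220like" arrangement) and one productive when the modules flanking
    the junction are inverted in place ("CP21like" arrangement, modules B
    and C flipped). ``offset`` keeps primers clear of the repeat-region
    margins.
    """
    seq = reference.sequence
    mods = {label: (s, e) for label, s, e in module_intervals}

    def end_fwd(label: str) -> str:
        s, e = mods[label]
        return seq[e - offset - primer_len : e - offset]

    def start_seq(label: str) -> str:
        s, e = mods[label]
        return seq[s + offset : s + offset + primer_len]

    def end_seq(label: str) -> str:
        s, e = mods[label]
        return seq[e - offset - primer_len : e - offset]

    panels: dict[str, PrimerPanel] = {}
    # Junction A|B
    panels["A-B:CP220like"] = PrimerPanel(
        [PrimerEntry("A_end_f", end_fwd("A"), "forward"), PrimerEntry("B_start_r", revcomp(start_seq("B")), "reverse")]
    )
    panels["A-B:CP21like"] = PrimerPanel(
        [PrimerEntry("A_end_f", end_fwd("A"), "forward"), PrimerEntry("B_end_r", end_seq("B"), "reverse")]
    )
    # Junction B|C
    panels["B-C:CP220like"] = PrimerPanel(
        [PrimerEntry("B_end_f", end_fwd("B"), "forward"), PrimerEntry("C_start_r", revcomp(start_seq("C")), "reverse")]
    )
    panels["B-C:CP21like"] = PrimerPanel(
        [
            PrimerEntry("B_start_rc_f", revcomp(start_seq("B")), "forward"),
            PrimerEntry("C_end_r", end_seq("C"), "reverse"),
        ]
    )
    # Junction C|D
    panels["C-D:CP220like"] = PrimerPanel(
        [PrimerEntry("C_end_f", end_fwd("C"), "forward"), PrimerEntry("D_start_r", revcomp(start_seq("D")), "reverse")]
    )
    panels["C-D:CP21like"] = PrimerPanel(
        [
            PrimerEntry("C_start_rc_f", revcomp(start_seq("C")), "forward"),
            PrimerEntry("D_start_r", revcomp(start_seq("D")), "reverse"),
        ]
    )
    return panels


def typing_profile_vote(profile: dict[str, list[int]]) -> str | None:
    """Subgroup vote from a junction typing profile: the arrangement label
    with more positive junctions wins; ties (including all-negative) vote
    None."""
    counts: dict[str, int] = {}
    for label, lengths in profile.items():
        if ":" not in label or not lengths:
            continue
        arrangement = label.split(":", 1)[1]
        counts[arrangement] = counts.get(arrangement, 0) + 1
    if not counts:
        return None
    ranked = sorted(counts.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def pattern_table(pattern: DigestPattern):
    """One row per fragment, descending size."""
    import pandas as pd

    return pd.DataFrame(
        {
            "genome": pattern.genome_id,
            "enzyme": pattern.enzyme,
            "fragment_bp": pattern.fragments,
        }
    )


def render_gel(patterns: list[DigestPattern], width: int = 60) -> str:
    """Crude text rendering of fragment patterns as gel lanes (log scale)."""
    all_frags = [f for p in patterns for f in p.fragments]
    if not all_frags:
        return ""
    lo, hi = np.log10(min(all_frags)), np.log10(max(all_frags) + 1)
    lines = []
    for p in patterns:
        lane = [" "] * width
        for f in p.fragments:
            x = int((np.log10(f) - lo) / max(hi - lo, 1e-9) * (width - 1))
            lane[x] = "|"
        lines.append(f"{p.genome_id:>20s} {''.join(lane)}")
    return "\n".join(lines)
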