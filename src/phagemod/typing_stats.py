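"""Subgroup classification and host-range statistics.

Subgroup membership of a group II phage is triangulated from several
independent criteria — modular architecture signature, tRNA gene
identities, presence of the gp047 tail-fiber deletion, restriction-pattern
cluster, and junction-PCR typing profile — by majority vote; dissenting
criteria are surfaced as an "atypical" flag (the IBB_35 situation: CP220-like
architecture with deviant markers), never resolved silently. Host-range
statistics formalize the spot-assay table: percent-positive rates, Jaccard
similarity of lysed-strain sets, and a label-permutation test of subgroup
structure in lysis profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from ._seq import encode, revcomp
from .io_formats import Genome, HostRangeMatrix

#: Architecture signatures of the two prototype arrangements.
CP21_SIGNATURE = "A+,B-,C-,D+"
CP220_SIGNATURE = "A+,B+,C+,D+"

TRNA_VOTES = {frozenset({"Thr", "Pro"}): "CP21like", frozenset({"Arg", "Tyr"}): "CP220like"}

CALL_NAMES = {"CP21like": "CP21_subgroup", "CP220like": "CP220_subgroup"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention of printed percentage tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_from_counts(infected: int, tested: int) -> float:
    if tested == 0:
        raise ValueError("tested count is zero")
    return round_half_up(100.0 * infected / tested, 1)


# ---------------------------------------------------------------------------
# gp047 deletion detection


@dataclass
class Gp047Comparison:
    query_start: int | None
    query_end: int | None
    reference_length: int
    length_difference: int | None  # reference span - query span
    deletion: bool
    cterm_identity: float | None
    resolved: bool
    note: str = ""


def _unique_seed_hits(seq: str, seed: str) -> list[tuple[int, str]]:
    hits = []
    for strand, pat in (("+", seed), ("-", revcomp(seed))):
        i = seq.find(pat)
        while i != -1:
            hits.append((i, strand))
            i = seq.find(pat, i + 1)
    return hits


def detect_gp047_deletion(
    query: Genome,
    reference: str,
    seed_k: int = 21,
    deletion_window: tuple[int, int] = (200, 2500),
    cterm_length: int = 500,
) -> Gp047Comparison:
    """Locate the gp047 locus by exact end-anchored seeds and compare spans.

    k-mer seeds from the reference 5' and 3' ends must each place uniquely
    in the query; the length difference (reference minus query span) flags a
    deletion when it falls inside ``deletion_window``. C-terminal identity
    is the fraction of matching positions over the end-anchored last
    ``cterm_length`` bp. Ambiguous or absent seeds give an unresolved
    marker, not an exception.
    """
    if len(reference) < 1000:
        raise ValueError("reference gp047 must be at least 1 kb")
    head, tail = reference[:seed_k], reference[-seed_k:]
    h_hits = _unique_seed_hits(query.sequence, head)
    t_hits = _unique_seed_hits(query.sequence, tail)
    if len(h_hits) != 1 or len(t_hits) != 1:
        return Gp047Comparison(
            None, None, len(reference), None, False, None, resolved=False,
            note="locus seeds absent or not uniquely placed",
        )
    (hs, hstrand), (ts, tstrand) = h_hits[0], t_hits[0]
    if hstrand != tstrand:
        return Gp047Comparison(
            None, None, len(reference), None, False, None, resolved=False, note="seed strands disagree"
        )
    if hstrand == "-":
        # locus on the minus strand: flip coordinates to the locus frame
        q_start, q_end = ts, hs + seed_k
        locus = revcomp(query.sequence[q_start:q_end])
    else:
        q_start, q_end = hs, ts + seed_k
        locus = query.sequence[q_start:q_end]
    if q_end <= q_start:
        return Gp047Comparison(
            None, None, len(reference), None, False, None, resolved=False, note="seed order inverted"
        )
    diff = len(reference) - (q_end - q_start)
    deletion = deletion_window[0] <= diff <= deletion_window[1]
    n = min(cterm_length, len(locus), len(reference))
    a, b = encode(reference[-n:]), encode(locus[-n:])
    identity = float((a == b).sum()) / n if n else None
    return Gp047Comparison(
        query_start=q_start,
        query_end=q_end,
        reference_length=len(reference),
        length_difference=diff,
        deletion=deletion,
        cterm_identity=identity,
        resolved=True,
    )


# ---------------------------------------------------------------------------
# Subgroup classification


@dataclass
class SubgroupEvidence:
    """Per-criterion evidence for one phage; unknown criteria stay None."""

    phage_id: str
    signature: str | None = None
    trna_labels: frozenset | None = None
    gp047: Gp047Comparison | None = None
    digest_vote: str | None = None  # 'CP21like' | 'CP220like' (nearest prototype)
    pcr_vote: str | None = None


@dataclass
class SubgroupCall:
    phage_id: str
    call: str  # CP21_subgroup | CP220_subgroup | unresolved
    atypical: bool
    concordance: float
    votes: dict = field(default_factory=dict)


def _evidence_votes(ev: SubgroupEvidence) -> dict[str, str | None]:
    votes: dict[str, str | None] = {}
    if ev.signature is not None:
        if ev.signature == CP21_SIGNATURE:
            votes["architecture"] = "CP21like"
        elif ev.signature == CP220_SIGNATURE:
            votes["architecture"] = "CP220like"
        else:
            votes["architecture"] = None
    if ev.trna_labels is not None:
        votes["tRNA"] = TRNA_VOTES.get(frozenset(ev.trna_labels))
    if ev.gp047 is not None and ev.gp047.resolved:
        votes["gp047"] = "CP220like" if ev.gp047.deletion else "CP21like"
    if ev.digest_vote is not None:
        votes["digest"] = ev.digest_vote
    if ev.pcr_vote is not None:
        votes["pcr"] = ev.pcr_vote
    return votes


def classify_subgroup(evidence: SubgroupEvidence) -> SubgroupCall:
    """Majority vote over the computable criteria.

    A dissenting criterion under a clear majority marks the call atypical
    (retained in the evidence, the call itself stays the majority subgroup);
    a tie or no computable criterion gives ``unresolved``.
    """
    votes = _evidence_votes(evidence)
    cast = [v for v in votes.values() if v is not None]
    if not cast:
        return SubgroupCall(evidence.phage_id, "unresolved", False, 0.0, votes)
    counts = Counter(cast)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return SubgroupCall(evidence.phage_id, "unresolved", False, 0.0, votes)
    winner = ranked[0][0]
    agree = counts[winner]
    concordance = agree / len(cast)
    atypical = agree < len(cast)
    return SubgroupCall(evidence.phage_id, CALL_NAMES[winner], atypical, round(concordance, 4), votes)


# ---------------------------------------------------------------------------
# Host-range statistics


def percent_positive(
    matrix: HostRangeMatrix, phage: str, species: str | None = None
) -> tuple[int, int, float]:
    """(infected, tested, percent to one decimal, half-up) for one phage,
    optionally restricted to one species."""
    col = matrix.phage_column(phage)
    mask = np.array([species is None or sp == species for _, sp in matrix.strains])
    tested = int(mask.sum())
    if tested == 0:
        raise ValueError(f"no strains tested for species {species!r}")
    infected = int(col[mask].sum())
    return infected, tested, percent_from_counts(infected, tested)


@dataclass
class Similarity:
    value: float
    both_empty: bool = False


def profile_similarity(matrix: HostRangeMatrix, phage_a: str, phage_b: str) -> Similarity:
    """Jaccard index of the two phages' lysed-strain sets; two empty sets
    are defined as similarity 1.0 with a flag."""
    a = matrix.phage_column(phage_a).astype(bool)
    b = matrix.phage_column(phage_b).astype(bool)
    union = int((a | b).sum())
    if union == 0:
        return Similarity(1.0, both_empty=True)
    return Similarity(float((a & b).sum()) / union)


@dataclass
class PermutationTestResult:
    observed: float
    p_value: float
    n_permutations: int


def subgroup_hostrange_test(
    matrix: HostRangeMatrix,
    calls: dict[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of subgroup structure in lysis profiles.

    Statistic: mean within-subgroup minus mean between-subgroup Jaccard
    similarity of lysed-strain sets. Subgroup labels are permuted over
    phages; p = (1 + #{perm >= observed}) / (1 + n_permutations).
    """
    phages = [p for p in matrix.phages if p in calls]
    labels = [calls[p] for p in phages]
    counts = Counter(labels)
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("need at least 2 subgroups with >= 2 phages each")
    n = len(phages)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = profile_similarity(matrix, phages[i], phages[j]).value

    lab = np.array(labels)

    def stat(lab_vec) -> float:
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                (within if lab_vec[i] == lab_vec[j] else between).append(sim[i, j])
        return float(np.mean(within) - np.mean(between))

    observed = stat(lab)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        if stat(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(observed=observed, p_value=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Genome summaries and the tail-gene tree


@dataclass
class GenomeSummary:
    genome_id: str
    length: int
    gc_percent: float
    module_lengths: dict[str, int] | None = None


def genome_summary(genome: Genome, modules=None) -> GenomeSummary:
    """Length and G+C percent (one decimal, half-up; ACGT positions only),
    plus per-module lengths when a segmentation is supplied."""
    arr = encode(genome.sequence)
    acgt = int((arr < 4).sum())
    gc = int(((arr == 1) | (arr == 2)).sum())
    gc_pct = round_half_up(100.0 * gc / acgt, 1) if acgt else 0.0
    mod = {m.id: m.length for m in modules} if modules else None
    return GenomeSummary(genome_id=genome.id, length=len(genome.sequence), gc_percent=gc_pct, module_lengths=mod)


def _kmer_profile(seq: str, k: int = 8) -> dict[int, int]:
    from ._seq import kmer_codes

    codes, valid = kmer_codes(encode(seq), k)
    prof: dict[int, int] = {}
    for c in codes[valid]:
        prof[int(c)] = prof.get(int(c), 0) + 1
    return prof


def gene_kmer_distance(a: str, b: str, k: int = 8) -> float:
    """Cosine distance between k-mer count profiles of two gene sequences —
    the alignment-free distance behind the tail-gene dendrogram."""
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    keys = set(pa) | set(pb)
    va = np.array([pa.get(x, 0) for x in keys], dtype=float)
    vb = np.array([pb.get(x, 0) for x in keys], dtype=float)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 1.0
    return float(1.0 - np.dot(va, vb) / denom)


def tail_gene_tree(gene_seqs: dict[str, str], k: int = 8):
    """UPGMA dendrogram over k-mer cosine distances between tail-gene
    sequences (approximate, alignment-free)."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform
    from .insilico_assays import Dendrogram

    names = list(gene_seqs)
    if len(names) < 2:
        raise ValueError("need at least 2 gene sequences")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = gene_kmer_distance(gene_seqs[names[i]], gene_seqs[names[j]], k)
    link = hierarchy.linkage(squareform(dm, checks=False), method="average")
    return Dendrogram(labels=names, linkage=link)
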