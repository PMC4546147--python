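# Methods

This note documents the models, algorithms, parameters and design choices
behind `phagemod`, and what the synthetic-data tests do and do not show
about real data.

## The biological model

Group II *Campylobacter* phages (CP220-like viruses) carry ~150–190 kb
circularly permuted genomes of ~27 % G+C organised as four large modules
(A–D, 28–55 kb) separated by long repeat regions (1–2.9 kb). A repeat
region is bipartite: two arms of tandem repeat units (up to 18 per arm,
mostly 72–86 bp) flank a unique inner spacer that sometimes encodes
proteins. Every unit contains a degenerate 13-nt core,
`5'-AAACTTAAAGCAA-3'`, within one mismatch. Arms may repeat in the same
orientation (direct) or opposite orientations (inverted). Two modular
arrangements are known — the CP220-like reference order (all modules
forward) and the CP21-like arrangement with modules B and C inverted in
place — and they co-segregate with tRNA gene identities (Arg/Tyr vs
Thr/Pro), an internal 0.2–2.5 kb deletion in the gp047 tail-fiber gene
(present in the CP220 subgroup), VspI/SmiI restriction patterns, and host
range. Genomes are handled linearized at a conventional origin with a
circular-topology flag; all coordinates are 0-based half-open and
conversion happens only at format boundaries (GFF3 is written 1-based
inclusive).

## Repeat detection

`scan_core_motif` reports every window on either strand whose Hamming
distance to the core motif is at most `max_mismatches` (default 1, the
allowance under which the core was defined). `N` mismatches every base.
Circular genomes are scanned across the origin. The scan is anchored to a
user-supplied core; there is deliberately no de-novo all-repeats
enumeration.

`build_units` delimits one unit per core hit: hits closer than
`max_core_spacing` (300 bp) form a chain, interior boundaries sit at the
midpoint between neighbouring cores, and terminal units extend half the
chain's median core spacing (singletons get the default 80 bp). How unit
boundaries relate to the cores is not observable from the motif alone;
the midpoint rule is this package's definition. Coincident opposite-strand
hits keep the lower-mismatch hit, ties going to the plus strand, for
deterministic output.

`assemble_regions` groups units into arms (inter-unit gap ≤ `arm_gap_max`,
200 bp) and pairs adjacent arms of ≥ `min_units_per_arm` (2) units across a
spacer ≤ `inner_gap_max` (1500 bp) into one bipartite region; leftover arms
become single-armed regions, flagged rather than dropped, which is where
isolated scattered units and degenerate polymorphic clusters surface. The
two gap thresholds are tool parameters, not biological constants: they are
chosen so that default-parameter detection reproduces 1–2.9 kb regions on
default synthetic genomes, and all are exposed on the CLI. Arms may have
unequal unit counts; no symmetry is enforced. A per-region mean core
mismatch is reported so low-confidence regions can be filtered.

`classify_region` calls a bipartite region direct when the majority core
strand of both arms agrees and inverted when opposite; within-arm ties are
reported `ambiguous`, never silently resolved. `derive_consensus` finds the
longest sequence contained in every unit (units oriented by core strand)
within the mismatch allowance by exhaustive search over substrings of the
first unit — optimal relative to that seed; containment is monotone in
length, so a binary search over lengths is exact. Equal-length candidates
rank by total mismatches, then lexicographically. A result shorter than
8 bp carries a warning flag.

## Architecture comparison

`segment_modules` cuts the genome at repeat-region spans: n regions on a
circular genome give n modules (one may wrap the origin), n regions on a
linear genome give n+1 segments. Modules plus regions must tile the genome
exactly — asserted after every segmentation.

`compute_dotplot` matches exact shared k-mers (k = 31, both strands) and
chains them into collinear runs (same orientation, (anti)diagonal within a
50 bp band, query gap ≤ 500 bp); runs covering < 200 bp of query are
dropped. The defaults make 31-mers effectively unique at ~180 kb and 27 %
G+C while tolerating the generator's percent-level divergence. Because the
repeat regions are near-identical genome-wide, region spans are masked
before seeding so repeats cannot bridge unrelated modules. The published
analyses established module homology by visual dot-plot inspection; the
chaining procedure is this package's formalization.

`compare_architectures` assigns each query module the subject module with
the greatest summed matched length, with the majority orientation of that
matched length; modules with matched fraction < 0.3 are reported
unassigned and a runner-up within 5 % flags the entry ambiguous. The
CP220-like genome is the canonical reference, so the CP21-like arrangement
reads `A+,B-,C-,D+`.

`order_contigs` turns junction amplicons into directed edges between
oriented contigs: an amplicon whose forward primer anchors near the end of
contig X and whose reverse primer anchors near the start of contig Y
contributes edge X→Y with gap = product length − (distance of the forward
primer match to X's end) − (distance of Y's start to the reverse primer
match end). Gap sizes are measured from primer positions, never assumed
from predictions — junction gaps in real data have been found several
hundred bp larger than predicted. A unique Hamiltonian chain (cycle in
circular mode) is required; missing or conflicting junctions raise an
error naming them.

## In-silico assays

`digest` cuts at every top-strand occurrence of the recognition site
(VspI `AT^TAAT`, SmiI `ATTT^AAAT`; offsets follow the standard enzyme
definitions — only fragment sizes, not ends, feed any comparison).
Fragments respect topology: linear with s sites → s+1 fragments, circular
with s ≥ 1 sites → s fragments; fragment sums always equal genome length
(asserted). `pattern_distance` is 1 − Dice over greedily matched fragments,
two fragments matching when they differ by ≤ 5 % relative to the larger —
a gel-resolution emulation on the size scale a gel actually separates.
Greedy largest-first matching is deterministic and mirrors how lanes are
read; an optimal assignment would differ only on pathological size sets.
`cluster_patterns` is UPGMA (scipy average linkage) over those distances.

`virtual_pcr` reports every forward × reverse product with the forward
match on the plus strand, the reverse on the minus strand downstream, a
per-primer mismatch budget (default 2) with the 3'-terminal 3 bases exact,
and product length ≤ 6000 bp (a polymerase-time ceiling consistent with
the published cycling conditions). Circular templates allow origin-spanning
products. There is no thermodynamic model; the long (up to 40 nt) primers
of the real assay are represented purely by the mismatch/3' rules.
`design_typing_panels` builds, for each inter-module junction, one primer
pair productive under the reference arrangement and one productive when the
flanking modules are inverted in place; the positive/negative profile over
junctions is the PCR typing result.

## Subgroup classification and statistics

`detect_gp047_deletion` anchors the locus with exact 21-mer seeds from the
reference gene's 5' and 3' ends (unique placement required, either strand);
the span difference flags a deletion when it falls in the 200–2500 bp
window, and C-terminal identity is computed over the end-anchored last
500 bp. Failures return an unresolved marker, not an exception. The
bundled `GP047_REFERENCE` is a synthetic ~4 kb stand-in locus generated
from a fixed seed — a stable anchor for detection, not a published
sequence.

`classify_subgroup` takes a majority vote over the computable criteria
(architecture signature, tRNA labels, gp047 deletion, nearest-prototype
digest pattern, PCR typing profile). The vote is deliberately plural — the
published subgroup assignment itself triangulates several lines of
evidence — and a dissenting criterion under a clear majority marks the call
*atypical* while keeping the majority call (the IBB_35 situation); ties are
`unresolved`, never broken arbitrarily. tRNA evidence is consumed from
annotations only; tRNA prediction is out of scope.

Host-range statistics: `percent_positive` rounds half-up to one decimal
(the convention reproduced by every printed percent value in the published
host-range table, e.g. 17/255 → 6.7, 10/18 → 55.6, 13/227 → 5.7);
`profile_similarity` is the Jaccard index of lysed-strain sets (two empty
sets are defined as 1.0 with a flag); `subgroup_hostrange_test` permutes
subgroup labels over phages and reports
p = (1 + #{perm ≥ observed}) / (1 + n) for the statistic *mean
within-subgroup − mean between-subgroup Jaccard*. The published claim of a
subgroup host-range difference is qualitative; this permutation test is the
package's formalization, not a reproduction. With three phages per
subgroup the label-permutation group is small (20 partitions), so the
smallest attainable p is ≈ 0.1; at least four phages per subgroup are
needed for p ≤ 0.05.

## The synthetic-genome generator

`generate_genome`/`generate_cohort` plant the architecture exactly:

- **Sizes.** Defaults: genome target 180 kb, four modules of 28–55 kb
  (rejection-sampled to hit the target minus region spans), regions of
  1–2.9 kb, units 72–86 bp, 3–18 units per arm, G+C 0.272. `scale`
  multiplies the bp size ranges (never unit lengths, unit counts or the
  motif); scaled region windows are floored at the smallest feasible
  bipartite region (two minimal arms plus a 250 bp inner spacer).
- **Regions.** One unit template per region with the core centered;
  per-unit copies mutate flanks at 2 % (so sequences inside a unit stay
  related across units, as observed in the real regions) and the core by
  at most the allowed 1 mismatch. The inner spacer is ≥ 250 bp — above the
  default arm gap, so planted arms are never merged — and regions RR1/RR2
  carry an inner cargo-gene placeholder. Orientation classes: RR3 direct
  in both subgroups, RR1 direct only in the CP220-like arrangement.
- **Cohorts and divergence.** A cohort shares one ancestral plan; each
  subgroup ancestor takes an independent 1.5 % substitution pass (≈ 3 %
  between subgroups, the same ballpark as the published ~94–95 % identity
  between prototypes) and each member a 0.2 % pass (subgroup members'
  restriction patterns are near-identical in the real data). Substitution
  replacements are drawn from the background composition conditioned on
  change, so G+C is preserved (within ±1 point for genomes ≥ 50 kb).
- **Conserved anchors.** 300 bp at every module edge (the repeat-flanking
  primer zone — the real typing system was built on conserved
  region-flanking sequence), the planted repeat units, scattered units and
  the gp047 end seeds are exempt from divergence.
- **Markers.** CP21-like members get tRNA-Thr/Pro, intact gp047 and
  modules B,C reverse-complemented in place; CP220-like members get
  tRNA-Arg/Tyr and an internal gp047 deletion (size sampled in
  200–2500 bp unless fixed) at a plan-level breakpoint that always leaves
  the 3'-terminal ≥ 600 bp intact. tRNA loci are labelled intervals with
  arbitrary interior — identification is annotation-based throughout.
- **Motif hygiene.** Backgrounds, inner spacers, unit-template junctions,
  piece junctions of both arrangements and every mutation pass are scrubbed
  of chance core-motif matches (mutations that would create one are
  reverted). Without this the planted truth — in particular exact per-arm
  unit counts — would not be well-defined; "additional single units at
  other positions" are planted deliberately (`scattered_unit_count`,
  default 4, ≥ 1.6 kb from any region so default detection can never merge
  them).
- **Randomness.** One `SeedSequence` per cohort, spawned per subgroup and
  member, so cohorts are reproducible member-wise.
- **Host range.** Strain panel mirrors the published one (227 *C. jejuni*,
  18 *C. coli*, plus 5/2/2/1 strains of four non-host species, always
  negative). Block rates default to the published per-subgroup positives
  (CP220-like: jejuni 0.10, coli 0.56; CP21-like: jejuni 0.06, coli 0.22).
  Correlation model: per strain and subgroup a latent susceptibility
  z ~ Bernoulli(p); each phage copies z with probability 0.9, else redraws
  Bernoulli(p) — marginals stay exactly p while same-subgroup profiles
  correlate.

**What passing tests show — and don't.** The generator is substitution-only
(no indels, no rearrangement beyond the planted inversion, no gene content
evolution), its repeat regions are identical across cohort members, and its
flanks are perfectly conserved. Recovery at 100 % on synthetic cohorts
therefore demonstrates correctness of the algorithms under the published
architecture, not robustness to assembly errors, indel-rich divergence, or
repeat polymorphism like the degenerate cluster known in the real CP21
record (expected to surface as flagged low-confidence singletons, by
design untested here). Real accession-based checks require downloads and
are intentionally not part of the test suite.

## Problem sizes and numerical choices

The recovery study uses 20 seed-indexed cohorts of 3+3 members at
scale 0.25 (~45 kb genomes) — the architecture is scale-free above the
region-feasibility floor, and this size exercises every code path in about
a minute. Null calibration uses 50 seeds × 999 permutations of a 6-phage
panel over 78 host strains. Percent rounding is decimal half-up
everywhere percentages are printed. Ties in unit building (coincident
opposite-strand hits), consensus ranking, fragment matching and UPGMA leaf
order are all resolved deterministically as described above.

## Known limitations

- Repeat detection assumes the core motif is known; heavily diverged cores
  (> 1 mismatch) fall out of units and regions.
- Module assignment needs percent-level sequence homology between query
  and reference; beyond ~10 % divergence the k = 31 seeding thins out.
- `order_contigs` requires every junction to be covered by a uniquely
  anchored amplicon; repeat-internal primers are rejected only through the
  unique-anchor rule, so primers must be designed outside repeat arms
  (`design_end_primers` takes an offset for this).
- The gel-style pattern distance treats fragments independently; co-migrating
  fragments of equal size are matched one-to-one, unlike a real lane.
- The permutation test conditions on the observed matrix; with few phages
  its p-value grid is coarse (see above).
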