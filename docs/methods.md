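# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hsrcnv`. Coordinates are 0-based half-open throughout the
library; only the VCF layer converts to 1-based.

## Alignment scoring

Every alignment in the package — HSR scores, junction realignment,
expected-support comparisons, duplication-vs-insertion matching — uses one
affine-gap scheme: match +1, mismatch −4, gap open −6, gap extend −1 (the
first base of a gap costs −7). `N` never matches anything, including `N`.
A single scheme keeps scores comparable across modules; under it, one
avoided mismatch is worth +5, so score thresholds translate directly into
"mismatches' worth" of evidence.

Three kernels (numba-compiled) implement the scoring:

* **local** (Smith–Waterman): co-optimal alignments are resolved by
  smallest reference start, then smallest query start, then smallest
  endpoints, making results deterministic. Start coordinates are propagated
  through the DP so the tie-break is exact, not a traceback heuristic.
* **split totals**: for a query of length *n*, the best local score of
  every prefix `q[:i]` (and, via the reversed sequences, every suffix) is
  the running maximum of the DP row maxima; two passes give the split
  objective `score(q[:i]) + score(q[i:])` for all *i* at once. This is
  exactly equivalent to *n* separate alignments (property-tested against
  them) at a fraction of the cost.
* **glocal** (query-global, target-local): used by the simulator to model
  an aligner's preferred full placement of a read; returns a CIGAR.

## Evidence

* A read is **clipped** if it has a soft/hard clip ≥ 5 bp on a side;
  smaller clips are ignored as adapter/quality noise.
* A **candidate (strong) HSR** is an unclipped read with ≥ 3 differences
  from the reference, where a difference is a mismatched aligned base or
  one indel event of any length. The SAM `NM` tag, when present, is used
  only as an upper-bound prefilter (NM ≥ the difference count).
* The optimal split of a candidate is computed with the split-totals
  kernel over a window of the read's span ± max_IS. A split is emitted only
  when the HSR score is **≥ 8** (two avoided mismatches' worth): raw
  single-read HSR realignment is overwhelmingly noise, so a positive margin
  over the linear alignment is required. The anchored half is the one whose
  placement stays nearest the read's original coordinates; the virtual
  breakpoint mirrors a real clip (reference end of an anchored prefix for a
  right clip, reference start of an anchored suffix for a left clip).
* **Discordant pairs**: insert size strictly greater than
  max_IS = μ + 3σ (deletion type), or outward orientation — the
  forward-facing read mapped downstream of the reverse-facing read
  (duplication type). Pairs on different chromosomes are ignored.
* Large CIGAR indels (I/D ≥ 20 bp) are converted into junction evidence for
  both sides: realistic aligners represent short deletions/duplications as
  gapped full-length alignments rather than clips, and each such read
  observes both breakpoints. This is what makes the 30–50 bp small-indel
  mode (`--min-size 30`) work.

Library statistics (μ, σ, modal read length) are estimated from the first
100,000 forward–reverse same-chromosome pairs' absolute template lengths.
Inserts above twice the median are discarded before computing μ and σ:
pairs straddling large deletions otherwise inflate σ (and with it max_IS)
appreciably. The estimate requires ≥ 1000 usable pairs.

## Consensus piling and canonicalization

Same-side (virtual) clips within 5 bp of one another form a cluster
(single-linkage in 1-D); clusters need ≥ 3 members, at least one with
mapq > 0, and produce a per-column plurality consensus (ties go to the
lexicographically smallest base). Columns are indexed relative to the
cluster breakpoint, with each member shifted by its own clip-position
offset, so junction microhomology jitter does not smear the columns.

Before piling, each clip is **canonicalized** to its anchor-maximal
equivalent position: the anchor is extended while the first (last) tail
base still matches the reference. In a tandem repeat the same junction can
be represented at any equivalent copy boundary; canonicalization makes the
representation unique so reads from one junction pile together.

## Pairing, junction assembly and realignment

The opposite breakpoint range of a consensus is derived from its members'
mates: `[min mate start, max mate end + max_IS]` for a right clip, mirrored
for a left clip, with a degraded fallback window when no mate is mapped.
Pairing demands each consensus's breakpoint inside the other's range and is
greedy by descending combined support. The pipeline inflates ranges by
max_IS during pairing: for a tandem duplication longer than the insert
size, junction-read mates map *inside* the duplicated span, leaving the far
breakpoint up to about one insert size outside the mate-derived range.

A paired junction is merged at the offset implied by the two clip offsets
(both consensuses describe the same junction column system), validated by
requiring ≥ 20 bp implied overlap at ≥ 90% identity. A free suffix–prefix
search is deliberately avoided here: in a tandem repeat it can lock in one
unit out of phase and fabricate a chimeric junction. Each side keeps its
well-covered anchor bases across the overlap.

Unpaired consensuses take two routes, and the better-scoring junction wins:
(i) the consensus sequence itself is realigned directly — its tail already
spans the junction with plurality-corrected content; (ii) a greedy
overlap-layout-consensus extension (suffix–prefix overlaps ≥ 20 bp at
≥ 90% identity, seeded by an exact terminal 12-mer, novel growth capped at
2 read lengths, final length ≥ 1.5 read lengths), polished by re-anchoring
local reads at ≥ 98% identity and voting per column. The strict polish
identity admits same-allele reads (sequencing error ≈ 0.2%/bp) while
excluding sibling repeat copies (≥ 2% divergence).

Realignment splits the junction at every admissible position (each half
≥ 20 bp), ranks splits by the two-pass split totals, and verifies the top 8
(plus the assembly's own junction offset) with full half alignments, each
half anchoring with ≥ 90% of its length aligned. With the left half ending
at `e_l` and the right half starting at `s_r`: `s_r > e_l` is a deletion
`[e_l, s_r)`, `s_r < e_l` a tandem duplication `[s_r, e_l)`; events below
`min_size` (default 50 bp, 30 bp in small-indel mode) are dropped. Calls
are precise, carry the junction score, and are left-aligned (shift left
while the base before the start equals the base before the end). Near-
identical precise calls are deduplicated keeping the best-supported one.

Duplication copy number is not estimated: a DUP record denotes the
duplicated reference span only.

## Discordant module

Same-kind pairs whose anchors both lie within max_IS (single linkage) form
clusters; ≥ 3 pairs emit an imprecise candidate: deletions as
`[max forward-read end, min reverse-read start)`, duplications as
`[min upstream-read start, max downstream-read end)`, with
CIPOS/CIEND = ±(max_IS − read length). When an imprecise candidate matches
a precise one under the imprecise comparison parameters, the precise
coordinates are retained and the discordant support folded in.

## Features, statistics and filtering

For each candidate:

* **Insert-size test.** For a deletion, the insert sizes of forward–reverse
  pairs bracketing the interval are compared against Normal(μ, σ): the size
  estimate is `mean − μ`, the 95% CI is `±1.96 σ/√n`, and the p-value is
  the upper-tail probability of the observed mean under the null. For a
  duplication, outward-pair spans (forward start − reverse end) are used;
  the size estimate is `mean span + μ`, tested one-sided against a true
  size of zero. No pairs ⇒ p = 1 with an unbounded CI. This normal-theory
  test is the package's concrete instantiation of insert-size statistical
  testing; heterozygous events dilute the shifted-pair fraction (the
  mixture is ignored), trading power for simplicity. Calibration is
  verified by simulation: type-I error ≈ α and ~95% CI coverage. No
  genome-wide multiple-testing correction is applied — p-values are filter
  features, not discoveries. Note that for duplications much shorter than
  the fragment length outward pairs cannot form, so the statistical clause
  relies on the junction quality instead.
* **Depth.** Mean mapq ≥ 20 coverage over the event and over flanks of
  max(2·read_len, 300) bp; a flank truncated by a contig edge flags the
  value degraded.
* **Junction score ratio**: junction realignment score over junction
  length (1.0 = perfect).

**Hard filters** (used when no trained model is given): support (≥ 3
split/HSR reads or ≥ 3 discordant pairs); statistics (p ≤ 0.05, or a
precise call with junction score ratio ≥ 0.9); and, for events ≥ 300 bp,
depth consistency (DEL: event ≤ 0.75× mean flank; DUP: ≥ 1.25×). Failures
are reported as ordered FILTER reasons. The optional **random forest** (200
trees, class-balanced, fixed seed) is trained from the features table
labelled by repeat-aware truth matching and replaces the hard filters,
passing candidates at probability ≥ 0.5.

VCF output is v4.2 with symbolic `<DEL>`/`<DUP>` alleles: POS is the
1-based base preceding the event (REF = that base), END the 1-based
inclusive end, SVLEN negative for deletions, IMPRECISE+CIPOS/CIEND on
discordant-only calls, and the evidence/features in INFO. Float features
are quantized through htslib's six-significant-digit text representation
at record-creation time, so write → read is exactly lossless.

## Comparison and clustering

Two same-type events match when start and end distances, reciprocal
overlap of the shorter, and length difference pass the parameter set:
precise (100 bp, 0.8, 100 bp) or imprecise (500 bp, 0.5, 500 bp) — the
imprecise set applies when either call is imprecise. When both events fall
within the same tandem repeat (≥ 90% of each covered by one repeat
interval; ties to the shortest unit), only the length criterion applies,
because coordinates inside a repeat are representation-dependent. A
duplication matches an insertion record when the insertion site is within
max-distance of either duplication boundary and the inserted sequence
locally aligns over ≥ 80% of its length to the duplicated sequence
concatenated ⌈|I|/|D|⌉ times. Repeat-unit counts divide the event length
by the unit length, with a 0.05-copy tolerance for "integer multiple".
Both inputs are left-aligned before comparison.

Catalogue clustering covers the compatibility graph with cliques greedily:
events sorted by coordinate join the first open clique they are compatible
with **all** members of, so every cluster is a clique by construction;
representatives take member-wise median coordinates. Clustering uses the
non-repeat-aware match for efficiency.

## Expected support (ES)

For a CNV, `r_ref` is the event span plus 2000 bp flanks and `r_cnv` the
same window with the event applied. All positioned reads of length *l*
from `r_cnv` strictly containing a breakpoint (duplicates at distinct
offsets counted separately) are aligned to both windows; ES is the
fraction aligning strictly better to `r_cnv` (ties do not support — each
read is an exact substring of `r_cnv`, so its score there is *l*).
Enumeration is error-free: ES is a property of the alleles, not of a
sequencing run. ES = 0 for full-unit events in perfect repeats holds
exactly when the residual repeat span is at least the read length; shorter
residues let a read touch sequence beyond both junctions, and such reads do
support the event. ES = 1 for junctions with no homology requires the
junction-edge bases to differ from their reference continuations (otherwise
a one-base-overhang read aligns fully by chance).

## Simulator

The generator produces: a random background with embedded tandem repeats
(configurable unit length, copy number, and per-copy divergence — each copy
after the first is independently mutated from the first at the given
substitution rate); planted deletions/duplications (heterozygous events on
one haplotype, homozygous on both) with exact donor→reference coordinate
maps; and paired reads with Normal(μ, σ) fragment sizes, uniform substitution
errors (default 0.2%/bp), and constant base quality. Reads not crossing a
junction are placed directly through the coordinate map; junction-crossing
reads are aligned to a local reference window both fully (glocal) and
freely (local), and emitted clipped only when the free placement wins by
more than `clip_margin = 8` — the same margin as the caller's minimum HSR
score, so the simulated aligner's preference for full-with-mismatches
placements and the caller's HSR detection describe the same phenomenon.
Everything is driven by one seed and is byte-deterministic.

What the simulator does **not** model: indel sequencing errors, quality
score variation, GC/coverage bias, multi-mapping (all reads mapq 60),
optical duplicates, chimeric fragments, adapter read-through, or multiple
chromosomes per run. Passing tests on this data demonstrate algorithmic
correctness under the stated read model, not performance on real
sequencing runs — in particular, real repeat regions add mapping-quality
ambiguity and locally noisy sequencing that the negative results here
cannot capture.

## Validation studies and problem sizes

The standard studies (in `hsrcnv.benchmarks`, run by the test suite and by
`scripts/acceptance.py`) use: a 1-Mb contig with 30 deletions + 30
duplications (60–2000 bp, unique junctions, homozygous) at 30× for the
easy regime; a 600-kb contig with 20 tandem repeats (units 60–180 bp, 3–6
copies, divergence drawn uniformly from 2–5%) carrying one full-unit event
each at 50× for the hidden-split regime — 50× matching the depth at which
strong-HSR support is typically assessed on reference samples; an 80-kb
contig with one 4×80 bp perfect repeat for the negative control; and
1000/500 replicates for test calibration. These sizes were chosen to give
stable estimates on a single CPU in minutes.

## Known limitations

* Insertions of novel sequence, inversions and complex/multi-breakpoint
  events are out of scope; inter-chromosomal evidence is ignored.
* Somatic (tumour/normal) calling is not supported.
* Genotypes are emitted as `./.`; no genotype likelihood model.
* The insert-size test treats spanning pairs as a pure sample from the
  alternative allele; heterozygous events halve the effective shift.
* Events in repeats whose copies diverge by ≪ 2% produce too few strong
  HSR candidates (< 3 differences per read) and remain undetectable by
  design of the ≥ 3-difference rule — the same reads would also be
  invisible to any alignment-based caller.
* The greedy clique cover and greedy consensus pairing are heuristics;
  both are deterministic but not globally optimal.
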