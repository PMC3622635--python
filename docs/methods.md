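# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `interloc`, including the places where the design was
genuinely open and a choice had to be made.

## Coordinates and conventions

All coordinates are 1-based inclusive (SAM convention), in the input
BED/BEDPE files converted on read. A breakpoint is reported as the
**junction-adjacent retained reference base** on its side: for a fusion
joining a forward prefix of chromosome *i* to a forward suffix of
chromosome *j*, the call is (last retained base of *i*, first retained base
of *j*). The simulator's truth tables use the same convention, which makes
ABE = 0 attainable on error-free data: the soft-clip boundary of a
junction-crossing read coincides exactly with the truth coordinate on both
sides.

## Insert-size model and L

`L = mean + k·stdev` with `k = 3` by default bounds both cluster cohesion
and the breakpoint-search windows; with Gaussian inserts 3 standard
deviations cover ≈ 99.7 % of fragments, so a chimeric mate almost surely
maps within `L` of its junction. The insert distribution is estimated from
up to 200,000 concordant pairs using the SAM template length of the
leftmost forward mate (the 5′-most to 3′-most outer span of the pair);
chimeric pairs carry no mapped distance and contribute nothing. Fewer than
100 usable pairs is an error directing the user to supply `--mean/--stdev`.

## Clustering

Chimeric pairs are stratified by (canonical chromosome pair, strand pair)
and grouped under the pairwise-cohesion criterion: all leftmost mapping
positions on each side within `L`. Grouping is a deterministic greedy sweep
in sorted coordinate order followed by merging groups to a fixpoint.
The fixpoint guarantees *pairwise maximality* — no two emitted clusters of
one stratum could be united without violating cohesion — a property that a
single-linkage-then-split scheme does not have (a span split can leave two
mergeable fragments; our randomized contract test catches this). When
cohesion admits more than one maximal partition the sweep order decides,
deterministically. `min_pairs = 2` by default: a single stray chimeric
artifact never nominates a candidate.

Read mapping orientation encodes junction geometry: reads point into the
fusion, so the breakpoint side is right of a `+` cluster and left of a `−`
cluster. With a centromere BED the junction side of each cluster is mapped
to an arm (`p`/`q`) and the fusion labeled `p-q` etc.; clusters abutting a
centromere suppress the label with a warning. The arm call is cosmetic —
classification consumes only the strand/side signature — and the
strand/side-to-arm reconstruction is ours (the sequencing-technology
-specific lookup it mirrors is only published pictorially).

## Breakpoint windows

The window on each side is anchored at the terminus of the **outermost**
read — the cluster edge *farthest* from the junction — and extends `L`
bases toward and past the junction, truncated at chromosome ends. Cohesion
guarantees the outermost read lies within `L` of the junction, so the
window contains (a) the clip boundaries of the cluster's own
junction-crossing reads and (b) the first stretch of partner-derived
sequence beyond the flank, which is precisely where clipped subreads from
the partner side must land. An alternative reading — anchoring beyond the
junction-nearest read — leaves the window disjoint from both kinds of
evidence and kills every call on clean data; we verified this empirically
and use the geometry above.

## Clip harvesting and realignment

Terminal soft clips ≥ `min_clip = 20` bp facing the junction and with
boundary inside a window qualify; at most `max_clips = 5` per side are
kept (first in coordinate order) for efficiency. Hard clips are ignored —
their bases are absent from the record and cannot be realigned. The 20 bp
floor matches the shortest subread that aligns reliably; it is configurable
downward for short-read libraries with the caveat that sensitivity and the
false-placement rate both degrade.

Realignment is an end-free (infix) edit-distance alignment of the clipped
subread against the partner window only, via edlib, accepting the best
placement when its edit distance is at most ⌈0.1 · clip length⌉. The clip
is reverse-complemented first exactly when the cluster signature has both
sides on the same mapping strand, which is the geometric marker of an
opposite-orientation (inverted-segment) fusion; placements on the
non-demanded strand are not attempted. Restricting the search to the
window (rather than the whole genome) preserves the decision the call rule
actually needs — does the clip remap to `W`/`X`? — while keeping the null
rate tiny: a random 20-mer places in an unrelated 640 bp window in well
under 1 % of seeded trials (Monte-Carlo test in the suite).

## Calling

For chromosome *i* the coordinate set pools the boundaries of clips
harvested in `W` with the junction-adjacent termini of partner clips
realigned into `W`; the breakpoint is the modal coordinate, ties breaking
to the smallest (deterministic; the tie rule is our choice, as is defining
a subread's "aligned coordinate" as its junction-adjacent terminus). A
call requires ≥ 1 successful realignment into `W` or `X`; one-sided
evidence is allowed, and a side with no coordinates at all falls back to
the cluster's junction-proximal edge with zero recorded modal support so
downstream filters can see it. Unresolved clusters are counted and logged,
not emitted.

## Classification

Two calls on one chromosome pair are partner candidates when their
breakpoint sides are opposite on both chromosomes. The labels:

1. both calls carry same-strand signatures → `INSERTION_INVERTED`;
2. otherwise both per-chromosome separations ≤ `recip_tol` → `BALANCED`;
3. otherwise the smaller separation ≤ `insertion_site_tol` →
   `INSERTION_DIRECT`;
4. otherwise the calls are unrelated; unpartnered calls are `UNBALANCED`.

This rule set is a **reconstruction** derived from the simulator's junction
geometry: reciprocal exchanges and direct insertions both produce
opposite-strand calls, and a reciprocal exchange with a duplicated stretch
at the exchange point is *locally indistinguishable* from a small direct
insertion — the only separating quantity is the donor-side separation
against `recip_tol`. Inverted insertions alone produce same-strand calls,
so they are recognized before any distance test. `recip_tol` defaults to
1 Mb; the bundled toy studies pass 10 kb, the same tolerance scaled with
their ~1/100 coordinate scale. `insertion_site_tol` defaults to `L`: the
two recipient flanks arise from one physical site and should co-locate
within paired-end uncertainty. Partnering is greedy on summed breakpoint
proximity with a deterministic sort, each call joining at most one event;
whether an optimal matching would ever differ on real data is unexamined
(the greedy choice is stable and order-invariant, which we test). Events
touching a supplied centromere interval are flagged low-confidence, not
dropped.

## Simulator

The generator forges derived chromosomes as ordered lists of oriented
reference pieces: one-way fusions join a prefix/suffix pair; reciprocal
rows build both derivatives (duplicated or lost bases at the exchange point
are encoded by the row coordinates); insertion row pairs excise the donor
segment and splice it into the recipient, reverse-complemented when
inverted. Leftover arms are kept as residual contigs so reference coverage
stays uniform. The physical junction map (adjacent retained bases per
junction) is the evaluation truth; note that for an inverted insertion the
physical adjacencies pair the recipient's left flank with the donor
segment's *end*.

Reads follow a two-layer wgsim-like model: haplotype mutations first
(default rate 0.001, indel fraction 0.15, indel length 1 + Geometric with
extension probability 0.3; indels touching a piece edge are skipped so
they never perturb the splice junctions under study), then uniform
fragment placement with outer distance ~ Normal(400, 80) (draws ≤ read
length or longer than the contig are redrawn), then per-base substitution
errors (default 0.02, the conventional simulator default; the original
study states no value). Each read's derived interval maps deterministically
back to reference coordinates, so the simulator emits a *truth* SAM: a
junction-crossing read aligns its longest junction-free run (ties to the
left) and soft-clips the remainder — mirroring how a read aligner
represents breakpoint-spanning reads — while small indels become CIGAR
I/D ops (colinear gaps ≤ 100 bp), as an aligner would report them. Mates
on opposite junction sides become chimeric pairs. FASTQ is also written on
request so a real aligner can be substituted. All randomness is a single
`numpy` generator seeded from the config; reruns are byte-identical.

What the generator does **not** model: mapping ambiguity in repeats,
mapping-quality noise, PCR duplicates, GC bias, chimeric library
artifacts, and polymorphism between non-homologous chromosomes. These are
the dominant false-positive sources on real genomes, so the perfect
specificity seen on synthetic runs should not be extrapolated; the
`min_mapq` filter (default 20) exists precisely for real alignments and is
a no-op on truth SAMs (all records carry MAPQ 60).

Down-sampling keeps each pair with probability `rate`, decided by a hash
of (seed, read name), so samples at decreasing rates under one seed are
nested subsets — convenient for clean coverage-trend comparisons (indepen-
dent per-rate sampling would add binomial noise between rates).

## Bundled toy studies and problem sizes

Two presets reproduce the structure of the simulated experiments at desk
scale: preset 1 plants 12 breakpoint events (six one-way fusions, one
reciprocal pair with a 1,000 bp duplication, one direct 40 kb and one
inverted 80 kb insertion) on 18 random chromosomes of 400 kb and sequences
100 bp pairs at 40X (~1.4 M pairs); preset 2 plants 9 events (seven
one-way, one clean reciprocal pair) on 16 chromosomes with 75 bp reads
(~1.7 M pairs). The sizes were chosen so a full simulate–call–evaluate
cycle completes in minutes on one CPU while every event still attracts
tens of supporting pairs, the same per-junction statistics as a
genome-scale 40X run (coverage-determined quantities are scale-free).
Random uniform-ACGT chromosomes make cross-chromosome homology vanishingly
unlikely, which is what keeps specificity at 1 in the synthetic setting.

## Evaluation

A call may match a true junction when the chromosome pair agrees and both
coordinates are within `match_tol` (default `L`). Matching is one-to-one by
optimal assignment (maximum matches, then minimum summed error), which by
construction agrees with an exhaustive bipartite oracle. SE counts matched
junctions over all true junctions — each row of a truth table is one
junction, so a reciprocal pair contributes two. SP is call-denominated
(a precision); true negatives are not defined for this task. ABE averages
|predicted − true| over both sides of each matched junction and is
undefined when nothing matched.

## Known limitations

* Short-read libraries whose clips rarely reach 20 bp will trigger
  clustering but not resolution; the caller reports such clusters as
  unresolved rather than guessing.
* No assembly of clipped subreads is attempted, so accuracy on
  mutation-dense junctions relies on the coordinate mode being robust.
* Intra-chromosomal rearrangements (deletions, inversions, tandem
  duplications) are out of scope by design, as are germline/somatic
  subtraction and read-depth corroboration of insertions.
* The classifier's thresholds make "balanced with a large duplication" and
  "small direct insertion" formally indistinguishable near `recip_tol`.
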