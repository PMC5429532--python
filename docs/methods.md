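# Methods

This note documents the models, algorithms and design choices behind
`methylsplit`: what is computed, under which assumptions, and where the
open choices were resolved.

## Bisulfite alignment model

Directional MethylC-seq libraries sequence the bisulfite-converted top
(OT) and bottom (OB) genomic strands. Conversion turns unmethylated C into
T on the read's own strand, so alignment is performed in reduced
three-letter space: a read is compared C→T-collapsed against the
C→T-collapsed genome (top-strand origin) and, after reverse
complementation, G→A-collapsed against the G→A-collapsed genome
(bottom-strand origin). In collapsed space a genomic C matched by a read T
is *not* a mismatch — and, symmetrically, a genomic T matched by a read C
is not either; mismatch counts are defined entirely in collapsed space.
CTOT/CTOB complement strands (non-directional/PBAT protocols) are not
supported.

The mapper is an ungapped seed-and-verify engine. The index stores sorted
k-mer tables of both collapsed genome texts at two seed lengths (defaults
13 and 8). A query of length *L* with mismatch allowance *m* (default 2)
is searched with the largest stored *k* satisfying (*m*+1)·*k* ≤ *L*, and
*m*+1 disjoint seeds (plus the final window) are queried: *m* mismatches
cannot destroy all *m*+1 disjoint seeds, so every locus within the
allowance is found — the search is provably equivalent to scanning every
genomic offset, which the test suite asserts against an independent
brute-force oracle. This guarantee is why the long seed is 13 rather than
something larger: a single 16-mer seed cannot guarantee recovery of a
25-nt segment carrying two mismatches. Verification is a vectorised
window comparison; chromosomes are concatenated with sentinel spacers that
can never match, so boundary-crossing candidates eliminate themselves.

Alignment is ungapped by design: junction detection needs the two halves
of a read placed exactly, not gapped alignments of either half. Indels
near a junction therefore surface as unmapped halves and cost sensitivity
rather than accuracy.

A read maps "uniquely" when its best full-length alignment is strictly
better than the runner-up. Unique full-length alignments feed the
un-split coverage track and a genome-wide methylation accumulator;
multimapped reads are excluded from both; unmapped reads enter the
split-read engine.

## Split-read engine

**Discordant ends.** The first and last `end_len` (25) bases of each
unmapped read are mapped independently. A read is a candidate when both
anchors map and some anchor pair is discordant: different chromosomes,
incompatible strands, or a same-strand separation outside [0, 2·read
length]. The 2·L bound is this package's operationalisation of
"concordant"; it cleanly separates contiguous fragments from junction
reads without excluding short-range rearrangements. Reads with an unmapped
end are not candidates — requiring both anchors suppresses unalignable
sequence at the cost of junctions flanked by truly unmappable DNA.

**Breakpoint location.** Every split position *b* with both halves ≥
`min_split_len` (25) is enumerated — *L* − 2·25 + 1 candidates. Because
`end_len` ≤ `min_split_len`, each half contains its end anchor as a
subsequence, so every genome-wide alignment of a half lies on the diagonal
of one of its anchor hits. The engine therefore evaluates, for every
anchor-diagonal pair, the cumulative collapsed-space mismatch profile
along the read and reads off both halves' mismatch counts for all *b* at
once. This is exactly equivalent to re-mapping both halves at every
split (asserted against brute force) at a fraction of the cost. All
splits tied at the minimal total mismatch count are retained; pairs lying
on a single diagonal are excluded (they are full-length alignments, not
splits).

**TE-edge filtering.** A retained split must have exactly one half whose
junction-adjoining boundary abuts an annotated TE terminus within
`edge_tol` (10 bp, absorbing annotation imprecision); that half becomes
the TE half and the terminus identity (5′/3′) follows from the geometry,
for either orientation of the inserted element. Among a read's tied
splits, the one whose TE half lands closest to an annotated terminus wins
(then the longer flank half): junctions are ambiguous up to the
micro-homology between flank continuation and TE edge, and only the
edge-exact choice recovers the TSD precisely. Reads whose two halves
overlap TE copies of one family are discarded — frequent TE-internal
deletions produce exactly such reads and are not transpositions (this
also makes insertions *into* a copy of the same family undetectable, a
documented blind spot). The flank half must additionally be uniquely
placed genome-wide; the TE half may multimap within one family (all
abutting copies are recorded for parental assignment) but is discarded if
it multimaps across families.

**Junction snapping.** A read whose true junction lies closer than
`min_split_len` to one end cannot legally split at the junction; its best
split steals a few bases across the boundary, and the TE half then falls
short of (or overshoots) the annotated terminus by exactly that amount.
The signed shortfall is recorded and the read's junction position is
corrected by it. Without this correction a single such read inflates the
TSD, because the TSD is derived from extremes over reads (below).

## Insertion calling

Junction reads are clustered per chromosome by single linkage on the
corrected junction positions (`cluster_window` 30 bp — larger than any
plausible TSD so both junction sides co-cluster). Mixed-family clusters
are split by family before filtering. A cluster becomes a call when

1. it holds more than 5 reads (`min_support` = 6),
2. both termini of the family are represented, with at least one read on
   each flank side, and
3. the flank overlap p1 − p2 + 1 — where p1 is the rightmost reference
   base covered by 5′-side flank halves and p2 the leftmost covered by
   3′-side halves — does not exceed `max_tsd` (20 bp; plant TSDs are ≤
   ~11 bp, with margin).

The overlap is reported as the TSD with its reference sequence; a small
negative overlap (gap ≤ 10 bp, from trimming losses or target-site
deletions) is tolerated as a zero-length TSD, larger gaps are rejected.
The insertion coordinate is the first TSD base (1-based in the TSV,
0-based in the BED). Element orientation follows from which terminus
joins which flank side.

**Parental copy.** If the intersection of the TE halves' edge-abutting
copy hits across the cluster is a single copy, that copy is reported; a
strict majority of members resolves a single contradicting read;
otherwise `ambiguous`. Hits whose TE half overshoots the terminus are
excluded from voting: the overshooting bases are insertion-site flank
sequence, so any copy they single out is chance homology with the
parental flank, not signal. Identical-copy families are therefore
honestly ambiguous; copies distinguished by internal variants are
resolved by the mismatch-best hits.

## Methylation at the new allele

Methylation is read from the call's own junction reads: on the aligned
strand, an unconverted C is methylated, a C→T transition unmethylated.
Flank-half observations are keyed by (junction side, distance from the
junction); TE-half observations by (abutted terminus, distance inward
from it) — measuring from the terminus keeps offsets comparable across
copies of unequal length. Contexts (CG, CHG, CHH; H = A, C or T) are
classified against the reconstructed inserted allele — flank + TSD + TE
end — because within two bases of the junction the reference context is
wrong by construction; farther away the allele and reference agree, which
a cross-module consistency test (simulator mutant-genome contexts vs
methylome allele contexts) verifies site by site. Both strands fold into
one context class at their own positions, as in standard MethylC-seq
reporting. With read length *L* the flank is resolved over *L* −
`min_split_len` bases per side: 60 bp at 85 nt, 75 bp at 100 nt.

**Meta-profiles.** Within 10-nt windows, each insertion contributes one
pooled level (methylated/total); the profile reports the across-element
mean with a 95% interval. The interval is the envelope of (a) the t
interval on the across-element standard error and (b) the Wilson interval
on the window's pooled counts, clipped to [0, 1]. The paper-level
prescription fixes only that across-element variation enters the
interval; the distributional form was open. The plain t interval is badly
anti-conservative here: with a handful of observations per element at a
3% rate, windows where every element happens to be unmethylated get a
zero-width interval at 0, and empirical coverage fell to ~69% (CHH).
The binomial envelope restores honest calibration (measured 95–99%
across contexts on the benchmark) while preserving the across-element
component wherever real between-insertion variation dominates. Windows
seen in fewer than two elements carry an undefined (NaN) interval.

Two companion views reuse the genome-wide accumulator of uniquely mapped
full-length reads: the same flanks in the reference (pre-insertion) state,
and the parental copy's terminal 60 bp with its own flanks (only for
calls with a resolved parental copy).

## Coverage verification

Fragments of a carrier chromosome that span the junction contain TE
sequence and cannot map full length to the empty reference locus, so
un-split coverage dips around a true insertion. Per call the mean depth
over ±5 bp (core) is compared against the ring [30, 80] bp on both sides:
z = (site − background mean) / background sd, supported when z ≤ −1. The
5/30/80 geometry operationalises an "±80 bp" neighbourhood: the inner
radius keeps the ramp of partially-overlapping fragments out of the
background, the outer stays inside the locally-flat region. A degenerate
background (sd = 0) yields an undefined score, reported unsupported with
a reason. The check is a per-call verification annotation, not a call
filter.

Known limitation: the dip can be masked at repetitive sites. If the host
region's family has other copies — in the reference or newly inserted —
their reads map (uniquely) onto the same reference span and fill the dip
in. On the benchmark one TE-context insertion shows z ≈ −0.3 for exactly
this reason; the same effect caps coverage-based support on real data at
repetitive loci. Somatic insertions, present in a fraction of cells,
likewise produce little or no dip and are outside this tool's scope.

## Simulation framework

`simulate.make_reference` builds the benchmark genome: ~500 kb, AT-rich
(64%), with 30 TE copies — 12 long (1.2–2 kb) single-copy families and 6
short (300–600 bp) multi-copy families whose copies are identical,
providing the repetitive fraction that makes real TE detection hard — and
25 gene intervals used purely as context labels. Insertion sites are
drawn uniformly within each context (genic / intergenic / TE; TE label
wins on overlap), at least one read length from chromosome ends and ≥
300 bp apart so neighbouring calls stay resolvable. Donors are annotated
copies; at TE-context sites the donor's family must differ from the
host's, because a same-family insertion is removed by the same-family
filter by construction and is a documented blind spot rather than a
benchmark case.

`insert_tes` duplicates the `tsd_len` bases 5′ of each site around the
inserted element (flank…TSD + TE + TSD…flank) with canonical
superfamily-specific TSD lengths (Copia/Gypsy 5, Mutator 9, hAT 8,
EnSpm/CACTA 3, LINE and Helitron 0 — LINE TSDs vary in nature; a fixed 0
keeps truth checking deterministic), all overridable.

Reads are single-end, drawn uniformly from both strands of the mutant at
the requested depth. Each cytosine of a read is methylated independently
with its context-specific probability (defaults 20% CG, 3% CHG, 3% CHH —
a single CH rate split equally, typical of plant genome-wide averages)
and emitted as T otherwise; contexts come from the mutant genome, so
junction-proximal draws reflect the new allele. Optional per-read SNPs
are placed anywhere except as C→T changes, which would be
indistinguishable from conversion — keeping the SNP and methylation axes
of the benchmark independent. Base qualities are constant Phred 40 with
an optional uniform error rate; no quality model, PCR duplicates or
paired ends are simulated, so the benchmark exercises the junction logic
and methylation bookkeeping, not read-quality robustness. Passing tests
on this generator demonstrate correctness of the method under its stated
model — clean directional libraries from a closely related reference —
not performance on degraded or contaminated real libraries.

Evaluation matches calls to truth greedily one-to-one (closest first,
deterministic tie-breaks) within 100 bp and the same family, then applies
sensitivity = TP/(TP+FN), FDR = FP/(TP+FP).

## Benchmark scale and defaults

The bundled benchmark — 500 kb, 20 insertions, 20x, 100-nt reads, fixed
seed — runs the full pipeline in well under a minute per replicate and
reproduces the expected behaviour: sensitivity ≥ 0.90 with zero false
discoveries, exact TSD sequences for all true positives, zero calls on
insertion-free reads, monotone degradation as depth drops (20x → 5x → 2x)
or SNP load rises (0 → 2 → 4 per read), and calibrated methylation
intervals. Genome-scale inputs (tens of Mbp) are outside the default test
envelope but limited only by memory for the k-mer tables (~64 bytes/bp)
and linear mapping time.

All defaults live in `pipeline.RunConfig` and are serialised verbatim
into every run manifest; identical inputs and configuration give
byte-identical reports.
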