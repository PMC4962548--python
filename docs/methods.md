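# Methods

## Scope and model of the data

The package analyzes two-condition (WT / mutant) chromatin data around
transcription start sites: factor ChIP-seq, total RNA-polymerase ChIP-seq,
matched input, MNase-seq and a replicate expression matrix. All positional
arithmetic is 0-based half-open on the forward strand; GFF3 (1-based
closed) is converted on load. Strand enters only when coordinates are made
TSS-relative: relative position r sits at genomic `tss + r` on the plus
strand and `tss − r` on the minus strand, with `tss = start` (+) or
`end − 1` (−). Coverage construction itself never consults gene strand.

## Gene universe

A gene is analyzable when its promoter and body signal are attributable to
it alone: single annotated TSS, no other gene contained in its interval,
nearest neighbour ≥ 2 kb away on both sides, and body length ≥ 700 bp.
The last criterion is an artifact of the gene-body window (+500 to the
gene end): 700 bp guarantees ≥ 200 bp of body. Overlap without containment
is handled by the distance criterion (gap 0 < 2 kb). Rejection reasons are
assigned in the priority order multi_tss → internal_gene → too_close →
too_short.

## Normalization, enrichment and occupancy scores

Raw pileups are scaled to reads-per-million (`× 10⁶ / total fragments`).
Any constant rescaling would do — every downstream quantity is a ratio or a
rank — so depth invariance is exact by construction and is asserted to
1e−9 in the tests. Per-base fold enrichment is
`(chip + pc) / (input + pc)` with pseudocount pc = 0.5 per-million units;
pc only matters where the input is sparse, and the promoter score uses
`pc × window length` in numerator and denominator so the score of an empty
window is 1. The promoter occupancy score is a ratio of window sums
(not a mean of per-base ratios): robust to zero-input positions, and equal
to the per-base formulation up to weighting.

Enriched regions are maximal runs of per-base enrichment ≥ 2.0, merged
across gaps < 20 bp, then width-filtered at 50 bp, summit = leftmost
argmax. This is deliberately simple plumbing: the downstream statistics
use per-base sums, and peaks serve only to categorize genes
(promoter-only / promoter+genic / genic-only / intergenic-neighbour /
none). An intergenic peak is booked to its nearest-TSS gene only if that
gene has no peak of its own.

Scored genes at or above 2.0-fold are ranked by splitting the ascending
score order into contiguous groups of near-equal size, earlier groups
taking the extras (365 genes → 92/91/91/91). Printed score ranges of any
particular dataset are outcomes, not definitions; ties break by gene id so
the split is deterministic and order-invariant.

## Pausing statistics

Region A is TSS-relative [−100, +151) — both printed endpoints −100 and
+150 included, 251 bp. Region B is [+500, gene length). Densities are
per-bp means so region-length differences cancel across genes; a raw-sum
mode exists for sensitivity analysis. PI = d_A / d_B; genes with d_B = 0
are excluded (and counted) rather than pseudocounted, because a planted or
real body signal of exactly zero says "no information", not "infinite
pausing". The paused classification uses the strict inequality PI > 4.

Gene detection tests each gene's 2×2 fragment-count table
[[chip_in, chip_out], [input_in, input_out]] with the one-sided Fisher
exact test, computed as the exact hypergeometric upper tail
P[X ≥ chip_in] (vectorized survival function — mathematically identical to
Fisher "greater"; the test suite proves agreement with an exhaustive
integer enumeration over all tables with row margins ≤ 50 and with
`scipy.stats.fisher_exact`). Benjamini–Hochberg is applied across tested
genes; detected ⇔ q < 0.05 and p < 0.01.

Occupancy correlations are Spearman with average ranks on ties and the
large-sample t approximation for p. Rank-wise WT/mutant PI comparisons use
the two-sided Mann–Whitney U: exact null for ≤ 8 per group without ties,
otherwise the tie-corrected normal approximation with continuity
correction; 5th/95th percentile whiskers (linear interpolation) are
reported per condition.

## Nucleosome profiles and section tests

Mononucleosome fragments are size-selected at 120–180 bp inclusive; the
midpoint `⌊(start + end)/2⌋` of each fragment represents one nucleosome
position. Metagenes average the per-million midpoint track strand-aware
over [−500, +500); genes whose window leaves the chromosome are dropped
and counted, and total midpoint mass is conserved (asserted exactly).

Condition comparison is a two-sample KS test per section — the 1 kb window
split into four 250-bp quarters, or the upstream half split into distal
[−500, −250) and proximal [−250, 0) — on the pooled TSS-relative midpoint
coordinates restricted to the section. KS needs sample observations;
midpoint coordinates are the natural observations and pooling across the
gene set follows the metagene logic. KS is location/shape only, so each
section also reports per-million midpoint mass per condition, making pure
occupancy-level shifts visible alongside. Sections with < 10 midpoints in
either condition are reported as skipped. The exact section boundaries are
configurable; equal 250-bp quarters are the default.

The SS-dinucleotide profile is the cross-gene frequency, per TSS-relative
dinucleotide start, of GG/GC/CC/CG — two strong bases, the composition
that favors nucleosome formation. The set is closed under reverse
complement, so minus-strand genes (whose windows are reverse-complemented)
contribute identically to testing the reference directly; this closure is
what makes every sequence profile exactly strand-symmetric. N bases drop
out of the denominator. A centered 50-bp moving average is applied for
display (heat-map-like resolution); raw values are always retained.

The random non-target control samples n genes (default 1900) stratified
near-equally across chromosome arms: quotas `n // k` with the remainder to
the first arms in sorted name order, deficits passed deterministically to
later arms, sampling without replacement under a fixed seed.

## Differential expression

Welch's t on log2 intensities (unequal variances, two-sided), fold change
on linear condition means. Significant ⇔ mean WT intensity > 100 and
p < 0.05 and |fold| > 1.5. No multiple-testing correction by default —
the filtering criterion is a raw-p threshold — with Benjamini–Hochberg
available as a flag. Direct targets are significant genes whose best
promoter peak exceeds 2-fold enrichment strictly; the summary reports their
down/up split and the global down-fraction.

## The synthetic-data generator

The generator's defaults are the emulated study conditions, chosen once:

* 2000 genes on five fly-like arms (2L, 2R, 3L, 3R, X), bodies 1.4–3 kb,
  gaps 2.4–4.4 kb; 10% of genes deliberately violate a selection criterion
  (extra TSS, nested gene, 500-bp gap) so the selection stage is exercised.
* 20% of clean genes are targets with occupancy s_g log-uniform on
  [2, 300] — the ~2–300-fold promoter enrichment span the analysis must
  resolve — divided into quartile ranks I–IV in the truth table.
* Factor ChIP: uniform background (0.015 fragments/bp, slightly below the
  0.02/bp input so the input baseline is the higher of the two) plus
  Poisson(30 · s_g) fragments per target at an upstream offset drifting
  from −10 (low occupancy) to −100 (high), SD 50 bp; (GA)n repeats of
  3–8 units are planted at the same offset, longer for higher occupancy.
* Polymerase ChIP: a uniform gene-body component (0.05 fragments/bp) plus
  a promoter component at +50 ± 30 bp with Poisson weight `2 · s_g^0.7`
  in WT. In the mutant the target weight collapses to the low-occupancy
  baseline (`2 · 2^0.7`), severing the occupancy coupling while leaving
  the body untouched.
* MNase: ~120 dyads per gene from a mixture of phased downstream
  nucleosomes at +130, +305, +480 (SD 18 bp for non-targets, 30 bp for
  targets — sharper arrays where no factor binds), a 10% uniform
  background, and upstream mass on [−250, 0) placed proportionally to the
  strong-dinucleotide propensity profile. Where the factor is bound the
  proximal part of that profile is suppressed by a Gaussian clearance
  footprint centred at −60; in the mutant's inflated ranks (default:
  rank IV, factor 1.5) the clearance is lifted, so upstream occupancy
  reverts toward the sequence-intrinsic propensity in both mass and shape.
  A scalar mass change alone would be invisible to a section-restricted
  KS on positions; the clearance model is also what the biology says the
  factor does. Fragment lengths are Normal(147, 15) rounded to odd values
  in [81, 249]: protection is symmetric about the dyad, so the floor
  midpoint recovers the planted dyad exactly and every TSS-relative
  statistic is exactly mirror-symmetric. (For real, even-length input
  fragments the floor convention carries an inherent 1-bp reflection
  asymmetry; a known limitation.)
* Expression: log2 baselines Normal(9, 2) — typical intensities well above
  the 100 floor — with triplicates at noise SD 0.25; half the targets
  receive a ±1.5 log2 mutant shift, downward with probability 0.8.
* Sequence: base GC 0.40; target windows get a strong-base enrichment
  peaking near −50 (flanking the TSS), non-targets an upstream depletion
  (an NFR) and a downstream enrichment past +130, with a contrast knob
  that can be set to 0 for null profiles.

All randomness derives from one seed through fixed per-stage streams
(genome 0, each assay×condition 1–8, expression 9), so regeneration is
byte-identical and the truth table — every planted quantity — is fixed at
genome construction. Recovery tests read truth only from the truth table.

What the generator does *not* emulate: mappability and GC bias, duplicate
reads, fragment-length/position coupling, chromatin-state heterogeneity
between cells, isoform structure, or array probe effects. Passing recovery
tests therefore demonstrates the correctness and sensitivity of the
statistical chain under the planted model, not robustness to those real-
data artifacts.

## Problem sizes and determinism of the verification runs

The verification suite and the acceptance script use 2000-gene genomes
(~11 Mb, ~1M fragments per ChIP sample) for recovery statistics — large
enough that the planted correlations and KS shifts are measured with
comfortable margins — and 120–150-gene genomes for exact invariance checks,
where size is irrelevant. Null checks (rank-I proximal KS, downstream
sections, type-I error) are honest hypothesis tests at fixed seeds; across
seeds they fail at their nominal rates (~5–10% jointly), which is the
expected behaviour of correct tests, not flakiness of the implementation.

## Known limitations

* Peak calling is threshold-run merging, not probabilistic inference; no
  fidelity to model-based callers is claimed.
* The Fisher detection treats fragments as independent draws; duplicate
  or overlapping fragments inflate counts.
* KS p-values use the asymptotic two-sample distribution; for tiny
  sections (just above the 10-midpoint floor) they are approximate.
* Exact parity with any particular published per-gene value is not
  claimed: such values depend on unreleased data and unstated
  normalization details; the package's guarantees are the invariances and
  recovery properties its tests compute.
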