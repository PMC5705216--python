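# Methods

## Data model and coordinates

The pipeline consumes per-read cytosine-conversion calls, not raw sequence:
one row per aligned read with its interval, the genomic strand carrying its
assessed cytosines (`conversion_strand`), and the coordinates of converted
and unconverted cytosines. All internal coordinates are 0-based half-open;
GTF input is converted on read, BED/bedGraph pass through unchanged. A
best-effort adapter summarizes methylation-extractor-style per-cytosine
tables into read records, since upstream aligners differ in their
intermediate layouts. Inputs are assumed already trimmed for 3'-end
conversion bias; no residual positional trimming is applied.

## Background rate and read scores

The background conversion probability p is estimated per sample: the global
per-cytosine conversion fraction is computed, reads whose own conversion
fraction exceeds 2.5× that value are excluded, and the fraction is
recomputed once. The fold threshold is interpreted on conversion *fractions*
(converted/original cytosines) rather than counts because reads differ in
cytosine content. Two degenerate regimes are handled explicitly:

* When the exclusion pass removes every converted read — routine when reads
  carry ~20 cytosines and p ≈ 1%, since a single conversion is already 5%
  — the model falls back to the pre-exclusion estimate rather than using
  p = 0, which would put all probability mass at c = 0 and void the model.
  The bare estimator (`estimate_background_rate`) still returns the
  post-exclusion value, including 0, so its contract stays simple.
* Reads with zero cytosines score 0 and contribute nothing to the
  denominator.

Scores follow the binned observed/expected construction described in the
README. Numerical conventions: bins are scanned in ascending conversion
count; the cumulative-tail rule activates at the first bin with expected
count ≤ 5 (strict comparison, so E = 5 pools) and applies to all larger
counts; a tail with expected mass ≤ 5 inherits the previous count's score
(count 0 scores 0 if reached). Groups at or below 1000 reads inherit per
conversion count from the nearest smaller scored group, recursing past
unscored groups; a conversion count exceeding the donor group's range takes
the donor's highest-count (tail) score; with no scored group below, the
score is 0. Scores are compared at 1e-9 relative tolerance in tests; the
model itself is deterministic given the input multiset.

Two normalizations are provided: the standard rescaling of each sample's
scores to a 1,000,000 total, and an optional cytosine-content normalization
that first multiplies each cytosine-count group by a constant equalizing
group means (groups whose scores are all zero cannot be rescaled and are
left at zero, with the per-group factors reported).

### Replicate-level enrichment QC

At desk-scale depth (~2000 reads/sample) the score chain for a
cytosine-count group hinges on its anchor bins: if the observed count at the
last bin with expected count > 5 falls at or below expectation, the
cumulative-tail rule propagates a zero score through every higher conversion
count, and the sample reports no enrichment anywhere regardless of how many
heavily converted reads it contains. Such a replicate is a failed
measurement, not evidence of absence, so condition-level analyses (metaplot
condition means, promoter ranking, the pipeline driver) exclude control
replicates whose model scores zero for every bin with ≥ 3 conversions. The
predicate is a zero/nonzero test with no tunable threshold. At realistic
sequencing depth the anchor bins hold thousands of reads and the predicate
never triggers.

## Tracks, region scores, strand attribution

A read's effective strand is the strand of its converted cytosines;
conversion-free reads fall back to the aligner strand, which is numerically
inert since their score is zero in background-dominated samples. Tracks
accumulate each read's normalized score over every covered position on its
effective strand, stored as boundary deltas and exported as run-length-
merged bedGraph. Region scores weight each overlapping read by
overlap/length, which makes them exactly additive over any partition of the
genome and ties the genome-wide total to the per-sample normalization
constant. Condition-level tracks and metaplots are across-replicate means.

## Annotations

TSS deduplication keeps, greedily by priority, at most one site per 1000 bp
(inclusive) on a chromosome: CAGE-supported candidates first (a candidate
matches the *strongest* CAGE site within 25 bp, a choice the data cannot
settle — the nearest-site alternative differs only when several sites fall
in range), then annotation confidence, then a seeded random tiebreak, so the
reference is reproducible from its seed. Gene-oriented windows are inclusive
of both endpoints ("TSS to +1000 bp" spans 1001 positions; the ±1000
promoter spans 2001), and "+N bp" on a minus-strand gene runs toward
decreasing coordinates. Promoter activity is the fractional-overlap count of
sense-strand nascent-transcription reads in the stated window; promoters
below the 80th activity percentile are inactive, with ties at the cutoff
counted active (conservative toward signal). Junction references keep one
record per distinct first exon-intron boundary, drop inactive promoters and
named exclusions, and carry the gene-oriented TSS-to-junction distance as
the first-exon length; quantile binning by that length uses equal-count
splits (sizes differing by at most one).

## Metaplots, R-loop signal, boundaries

Each read is assigned to its proximal reference point by midpoint distance
(ties to the smaller coordinate), and its score is added at the
gene-oriented offset of every covered nucleotide within the ±W window
(W = 1000 by default, 2001 offsets), split into non-template (effective
strand equals the gene's coding strand) and template series. The default
reducer sums over regions; a mean reducer is available. The R-loop signal is
(ctrl_NT − tpl_NT) − (ctrl_T − tpl_T) per offset. The conversion-count
asymmetry profile subtracts inhibited-condition mean conversion counts from
control means per strand (negative corrected counts clamped to zero) and
reports log2((NT+1)/(T+1)); the +1 pseudocount follows the package-wide
log2(x+1) convention.

Boundary detection takes the outermost offset at which the signal reaches
half its maximum. Two search modes exist because the natural reading of the
rule presumes a smooth unimodal profile: `global` (the literal rule, for
aggregate metaplots) and `main_peak`, which returns the crossing of the
contiguous above-half-maximum run containing the global maximum. On
single-locus profiles, where one read spans ~100 offsets and a couple of
high-scoring background reads can stack into a detached bump that brushes
the half-maximum level, `main_peak` is the appropriate mode; the two agree
whenever the above-half set is contiguous. Single-locus signals are
additionally smoothed with a read-length moving average (edge-corrected)
before the search — the half-maximum crossing of a smoothed plateau stays
centered on the plateau edge, while narrow spikes are attenuated by
width/window.

Because a read's whole interval receives its score, signal bleeds up to one
read length past a true boundary; boundary estimates at the default
synthetic depth carry errors of a few tens of nucleotides with occasional
excursions beyond 100 nt. This is a resolution limit of the measurement at
that depth, not of the estimator.

## Promoter ranking

Region scores for ranking are measured gene-orientedly over TSS..+250.
Candidates must be active (top 20th percentile of activity in that window)
and show positive non-template score in every QC-passing control replicate;
survivors are ordered by 2·Δlog2(NT) − log2(T+1) as in the README. The
printed form of this expression has unbalanced parentheses in its source
description; the implemented reading is the only arithmetically coherent
one. The derived "R-loop formation" quantity is the sum of the strand
asymmetry and the inhibitor sensitivity. A promoter-versus-matched-region
enrichment test (exon-centered windows ≥ 2 kb downstream within the same
gene, genes > 2 kb only) is provided on top of the unpaired rank test.

## Monte Carlo nulls

The genome is tiled into 1 kb regions. The random-regions null reassigns
each read uniformly among same-chromosome regions that held at least one
read in the real data, placing it at the region start (clipped to the
chromosome end) and carrying its score; the shuffled-scores null permutes
scores within each chromosome. Both conserve per-chromosome totals exactly.
Per-chromosome RNG streams are spawned deterministically from a single seed.

## Statistics

Group comparisons use the two-sided rank test; the unpaired two-sample
(rank-sum) form is the default — matching the stated paired=FALSE usage of
the signed-rank-named procedure, a discrepancy resolved in favor of the
stated call — with the paired signed-rank form available per analysis.
Correlations use Spearman's rho with the asymptotic t approximation.
Metaplot p-values are Bonferroni-multiplied by the number of offsets
(2001 at W = 1000) and capped at 1.

## Synthetic data

The generator emits the complete input set — conversion tables per
replicate, GTF gene models, candidate TSS BED, nascent-transcription reads,
and a truth table — from a parameterized toy genome. Default study
conditions: one 1 Mb chromosome, 20 genes (20% intronless, first-exon
lengths uniform on 150–400 nt), 4 implanted sense-strand R-loops spanning
TSS to the first junction (500 nt for intronless genes), background
conversion probability 0.01 versus 0.8 on the displaced strand in the
control condition only, 100 nt reads uniformly tiling each ±1000 promoter
window at 100 reads per promoter and replicate, and 13 control plus 2
transcription-inhibited replicates — the replicate structure of the
emulated study design. Antisense-strand implants (displaced template strand
upstream of the TSS) are available via configuration.

Cytosines sit on a fixed lattice (every 5 bp per strand, phase-shifted
between strands) rather than being drawn from a sequence model: the scoring
method depends only on counts, and the lattice gives every read the same
cytosine count, which concentrates all reads into one scored group — the
only configuration in which the >1000-read group threshold is satisfiable
at desk scale. Implanted genes receive the largest activity draws times a
2× margin, encoding the transcription dependence of the phenomenon and
keeping implants above the activity-percentile cutoff despite Poisson
sampling of the activity reads. The inhibited condition generates background
conversions only; a nuclease-treated condition would be statistically
identical and is represented by the same analog.

What the generator does not emulate — immunoprecipitation enrichment bias,
fragmentation structure, sequence-dependent cytosine density, conversion
heterogeneity within an R-loop, partial or nested R-loops — bounds what
passing tests show: they validate the inference machinery against the
stated statistical model of the assay, not robustness to every artifact of
real libraries.

## Validation experiment sizes

The closed-loop tests run the default 20-gene conditions above (~30,000
reads per dataset); the scoring oracle comparison uses randomized samples up
to 5000 reads and 20 cytosines across 50 seeds; Monte Carlo calibration uses
600 uniform reads on a 200 kb chromosome plus 100 null draws against the
clustered control sample; rank-test calibration enumerates all inputs up to
8 observations and checks null uniformity over 1000 replicates. The whole
suite and the acceptance script each complete in well under a minute of CPU.

## Known limitations

The background estimator is biased downward when the outlier threshold cuts
inside the background distribution (its discreteness makes the bias
depth- and cytosine-count-dependent), which inflates low-count bin scores;
the published procedure is reproduced as stated rather than corrected. The
score chain's anchor-bin fragility at low depth is mitigated by QC, not
removed. Paired-end mates are scored as independent reads. Reads with
converted cytosines on both strands are not representable; the data model
carries one conversion strand per read.
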