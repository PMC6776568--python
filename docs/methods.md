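# Methods

## Coordinate model

All intervals are 0-based half-open `[start, end)` (BED-native), including
the gene table; interval length is `end − start` everywhere.  A single
convention across peaks, promoters, gene bodies, coverage steps and
interaction anchors eliminates off-by-one drift between stages.  Overlap
means an intersection of at least `min_overlap_bp` (default 1 bp); no
minimum overlap *fraction* is imposed anywhere.  All interval outputs are
written sorted by (chrom, start, end) so runs reproduce byte-for-byte.

## Chromatin states and compartments

A TF peak's state is a pure function of its overlap with the active mark
(H3K4me3) and the repressive mark (H3K27me3): active / bivalent /
repressive / unmarked.  Peaks overlapping neither mark are retained as a
fourth, explicitly reported "unmarked" class rather than silently dropped,
so peak counts are conserved; a three-class report is a downstream filter,
not a classification change.

Promoters are TSS ± `halfwidth` windows (default 3000 bp, i.e. a 6 kb
window), clipped to chromosome bounds.  Compartment annotation uses strict
precedence promoter > gene body > intergenic; a peak overlapping two genes'
features takes the first matching category but records *all* overlapping
promoter genes.  The minus-strand gene body is the interval between
min(tss, tes) and max(tss, tes) with the promoter window excluded by
precedence.  The co-binding reporting scheme maps the same partition to
promoter / other / intergenic.  Target genes are all genes whose promoter
window overlaps the peak (many-to-many, with the inverse map returned).

## Signal density and metaprofiles

Region density is `(Σ signal in region / total_signal × 10⁶) / length` —
reads per million per base — where `total_signal` is the track's
value-times-width integral (a library-size proxy).  Metaprofiles anchor at
the peak midpoint `floor((start+end)/2)` (a summit is not recoverable from
BED3), average per-bin normalized signal across peaks (default radius
2000 bp, bin 50 bp), and report per-million-per-bp units in the output
metadata.  Bins that would cross a chromosome edge are dropped for that peak
(truncation, not NaN-padding), keeping every reported bin a mean over fully
covered windows.  The SE vs TE contrast uses the median fold and a two-sided
Wilcoxon rank-sum test — a distribution-free test matching a box-plot style
comparison of densities.

## Enhancer taxonomy and SE calling

Classes are mutually exclusive with precedence: **super** (overlaps a
supplied SE catalogue — a published list always overrides local mark
logic), then **active** (H3K27ac⁺), **poised** (H3K27me3⁺ with H3K4me1,
H3K27ac⁻), **intermediate** (H3K4me1 only), else **unclassified**.  The
mark convention for "intermediate" is a design choice of this package:
the community literature characterizes these classes with H3K27ac, H3K4me1
and H3K27me3 but does not pin down a unique boolean rule, so the rule above
is documented here as the package's convention rather than a settled fact.

`stitch_and_rank` (for users without a published SE catalogue) merges
candidate peaks within `stitch_distance` (default 12.5 kb; candidates
overlapping an optional TSS-exclusion set are removed first), ranks stitched
regions by total track signal ascending, and cuts at rank
`i* = argmax_i (m·i − y_i)` with `m = (y_max − y_min)/n` — the tangent point
of a line of that slope on the ranked curve.  Regions strictly above the
cutoff signal are SEs.  With all-equal signals the geometry degenerates;
the result is zero SEs plus a `degenerate` flag.  Fewer than three stitched
regions is an error (the inflection is undefined).

SE-to-gene assignment maps each SE to the gene with the nearest TSS
(distance 0 when the TSS lies inside the SE; otherwise base distance to the
nearest covered base), skipping SEs whose nearest TSS exceeds
`max_distance` (default 100 kb).  Exact ties go to the lexicographically
smaller gene id and are flagged.

## Co-binding and the resampling confidence interval

Overlap is counted at the interval level by default — a query interval
counts once no matter how many reference features it touches — matching
percentage-of-peaks reporting; a base-pair mode is available as a flag.
The null model re-places each query interval uniformly at random over valid
start positions (length preserved; chromosome preserved by default; no
mappability or blacklist exclusion, since none is defined for the synthetic
genome — an exclusion list can be emulated by pre-filtering).  The 95% CI
is the 2.5th–97.5th percentile interval of the null counts; the default
`n_draws=100` matches the source procedure, while calibration experiments
in the tests use 1000 draws for stable percentiles (documented divergence).
The empirical p-value uses the add-one rule `(1 + #{draws ≥ obs})/(n+1)` and
is therefore never 0.  The coverage experiment uses 200 query × 200
reference intervals on a 10 Mb chromosome so the null count (mean ≈ 28,
sd ≈ 5) is fine-grained enough for a percentile interval over an integer
statistic to achieve near-nominal coverage; with coarse counts the discrete
lattice would distort coverage regardless of implementation.

## Interaction classification

Other ends are tested against promoters first, then classified enhancers
(the "unclassified" class does not count); promoter-over-enhancer precedence
reflects the promoter-centric bait design.  When an other end overlaps
several classified enhancers the largest overlap wins, ties broken by class
precedence.  "Mediated by" a factor means the factor has a peak at either
anchor (anchor choice is a parameter).  Upstream caller scores are passed
through untouched; intra- vs inter-chromosomal status is preserved as a flag
and inter-chromosomal distances are reported as unbounded.  The
second-factor enrichment contrast (fraction of mediated vs all interactions
carrying the factor) uses a two-proportion z-test.

## Differential expression rule

Fold changes are knockdown/control on the linear scale.  Up requires
`fc > 1.3` and `p < 0.05`; down requires `fc < 1/1.3` and `p < 0.05`; both
inequalities strict, so `fc = 1.3` is not significant.  The reciprocal
threshold makes the rule symmetric under `fc → 1/fc`.  No multiple-testing
correction is applied by default (the rule filters on raw p); a
Benjamini–Hochberg flag is available.  The package starts from a supplied
DE table and never re-derives p-values from counts.  Gene-set enrichment is
the one-sided hypergeometric tail `P[X ≥ k]`.

## The synthetic study generator

`simulate_study` emulates the statistical structure of a
factor-at-super-enhancers study: a 3 × 10 Mb genome; 300 fixed-stride genes
with alternating strands; 2000 TF peaks with planted composition 50/20/20/10
(active/bivalent/repressive/unmarked) and 1/29/70
(promoter/gene-body/intergenic); a second factor co-binding 70% of active
and 50% of other peaks (overall 60% — the per-state rates are chosen so
their composition-weighted mean is exactly the overall rate); 30 SEs and 30
TEs in inter-gene gaps with coverage amplitude fold 3 (SE over TE); 500
interactions split 60/30/10 into promoter-promoter / promoter-enhancer /
other with 40% mediated; and a 1000-gene DE table with 120 up and 80 down.
These defaults are the study conditions for all recovery tests.  Where a
magnitude had to be invented (amplitudes 2/5 signal units, Poisson noise at
rate scale 1 over 50 bp bins, peak width 400 bp, ≥1 kb peak spacing,
interaction score range), values were chosen once to resemble a
well-powered ChIP-seq/PCHi-C study at miniature scale and are recorded in
the config.

Entities are *placed by construction* to satisfy their labels — an
"active" peak is physically given an overlapping H3K4me3 interval and no
H3K27me3; a mediated interaction's other end is placed over a planted TF
peak; an SE's nearest TSS is unambiguous by layout — so full-pipeline
recovery of every planted composition is exact, not statistical.  Coverage
is rectangular bumps plus optional per-bin Poisson noise
(`Poisson(v·w·scale)/(w·scale)`, unbiased; scale 0 disables noise, making
the SE/TE density fold exactly the planted value).  `degrade` provides a
robustness fixture: uniform ±jitter of interval positions and Bernoulli
dropout, with dropped entities recorded in the manifest; because planted
mark overlaps exceed 100 bp and peak spacing exceeds 1 kb, jitter ≤ 20 bp
provably cannot flip a state call.

What the generator does **not** emulate: read-level noise (FASTQ),
irregular gene structure, peak-width and signal heterogeneity, mappability
gaps, fragment-level Hi-C resolution, or correlated biological replicates.
Passing recovery tests therefore demonstrates correctness of the analysis
logic under clean planted conditions, not robustness to every artefact of
real data — the `degrade` fixture probes the first-order perturbations only.

## Pipeline and reproducibility

Stages run in a fixed dependency order (cobind needs classify; interactions
need enhancers; de needs classify + annotate); requesting a stage without
its dependencies fails before anything executes.  One seed from the run
config feeds every stochastic step; reports echo the full config, carry no
timestamps, and serialize with sorted keys, so identical configs reproduce
identical output trees bit for bit.  Percentages are always accompanied by
raw numerators/denominators in the per-stage outputs.

## Problem sizes used in the shipped experiments

Recovery runs use the default study (2000 peaks, 500 interactions, 1000 DE
genes).  CI calibration: 200 replicates × 1000 draws (null and enriched).
Density-fold recovery: 200 noisy replicates of 30 SE + 30 TE regions.
Stitch-and-rank recovery: 100 replicates of 100 background peaks + 5
planted clusters.  These sizes give the binomial success criteria (≥95%,
93–97%, ≥99%) enough resolution to be meaningful while keeping the whole
suite fast.

## Known limitations

- The interval engine is a per-chromosome sorted sweep with binary-search
  pruning: worst-case quadratic for pathological all-overlapping inputs,
  ample for the 10³–10⁴-interval scale it targets.
- The shuffle null has no mappability/blacklist model.
- The percentile CI inherits the granularity of a 100-draw null; use more
  draws when the interval's endpoints matter.
- `assign_se_genes` is nearest-TSS only; it does not use expression or
  contact data to pick among candidate genes.
- The two-proportion z-test treats the mediated subset as independent of
  its universe, as in the source procedure; for small counts prefer the
  hypergeometric overlap instead.
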