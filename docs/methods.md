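# Methods

This note documents the models, estimators and design choices behind
`isletsplice`, and what the synthetic-data experiments do and do not show.

## Coordinates and event structure

All intervals are 0-based half-open (BED convention).  A cassette-exon
event stores the two constitutive flanking exons and the alternative exon;
"upstream"/"downstream" are transcript-relative, so minus-strand events
have their upstream exon at higher genomic coordinates, and all extracted
sequences read 5'→3' in transcript orientation.

## ψ quantification

Inclusion of a cassette exon is supported by two splice junctions, skipping
by one, so inclusion reads are halved before normalization:
ψ = (I/2)/(I/2 + S).  Coverage is defined as the raw read sum I + S (not
junction-normalized); an entry is quantifiable at I + S ≥ 20 reads.  This
raw-sum convention is configurable (`min_junction_coverage`), since
junction-normalized coverage is an equally defensible reading.  Cell QC
keeps cells detecting 2500–10000 genes (detected = count > 0; removal is
strictly below/above, so boundary cells stay), applied before the
event-level filter, which keeps events quantifiable in ≥ 10% of cells
(closed ≥ comparison fixes the tie at exactly 10%).

## Synthetic-data generator

The generator is a stand-in with a fully specified generative model — the
real studies it emulates analyze sequencing data and define no such model —
so all distributional choices here are explicit package choices:

* Cells: K = 3 types ("beta", "alpha", "dual"; proportions 0.45/0.40/0.15)
  under ND/T2D (0.6/0.4), echoing the composition of a deeply sequenced
  islet cohort at toy scale.  Default 300 cells.
* Inclusion levels: per event a baseline ψ₀ ~ Beta(2, 2) restricted to
  [0.02, 0.98]; `type_specific` and `condition_specific` events shift by
  ±0.3 in their target group (infeasible shifts are rejected before
  sampling).  Cell-level ψ ~ Beta(cψ̄, c(1−ψ̄)) with concentration c = 200,
  i.e. within-group ψ spread ≈ 0.035 at ψ̄ = 0.5 — cells of one type and
  condition share most of their splicing program.
* Coverage: total junction reads per cell/event are zero-inflated negative
  binomial (mean 30, size 5, dropout 0.3), giving ≈ 50% quantifiable
  entries at the 20-read filter — missingness is the central nuisance the
  imputation stage exists for.  Inclusion reads are
  I ~ Binomial(T, 2ψ/(1+ψ)) and S = T − I; the 2ψ/(1+ψ) probability makes
  the generator consistent with the two-junction estimator.
* Expression: negative binomial (size 2) around log-normal gene means with
  a per-cell depth factor; 20 marker genes per type (8-fold), a 20-gene
  maturity set scaled continuously by each cell's maturity scalar
  m ∈ [0, 1] (4-fold range; "mature" cells are the top quartile), and a
  20-gene T2D expression set (2-fold) kept disjoint from the genes carrying
  condition-specific splicing, so the splicing and expression layers are
  independent by construction.
* Sequence: events are laid out on a synthetic contig (100-nt flanking
  exons, 300-nt introns, 80-nt cassette, random strand) with i.i.d. uniform
  bases.  The focal motif (default GGGAGGG) is planted uniformly in the
  exon-proximal 250 nt of the upstream intron at rate 0.8 for regulated
  events and 0.05 otherwise, and in downstream introns at the background
  rate.
* Reproducibility: one global seed; independent sub-streams per component
  (events, cells, ψ, coverage, expression, sequence) so changing one model
  does not perturb the others.

What the generator does *not* emulate: batch/donor effects, library-size
confounding with cell state, realistic sequence composition, linked
dropout between expression and junctions, and missing-not-at-random ψ
(missingness is independent of ψ given coverage).  Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated model, not robustness to those real-data pathologies.

## Imputation

`bpca_impute` fits probabilistic PCA (isotropic noise) by EM over observed
entries only, per-row posteriors over latent scores and batched per-feature
updates of loadings, mean and noise variance; convergence is declared at a
relative observed-data log-likelihood change below 1e-4 (cap 200
iterations, warning on non-convergence).  This is the isotropic-noise
member of the Bayesian-PCA family: it shares the latent-factor imputation
mechanism while dropping per-component relevance priors, which matters
little here because the component count is fixed at the 10 PCs used
downstream.  Missing entries are replaced by conditional means clipped to
[0, 1]; observed entries are never altered, and a complete matrix passes
through bit-identical.  Preconditions: no all-missing row/column, every
event observed in ≥ 2 cells, components < min(cells, events).

`sentinel_fill` (default −1) is the alternative "missingness as its own
state" mode.  Which order — sentinel flagging versus model-based imputation
of "remaining" exons — the original analyses used is not recoverable from
their descriptions; imputation of all missing entries is the default here
because it is self-consistent and testable, and both modes are exposed.

## Embedding and clustering

Events are centered (no unit scaling by default — ψ is already bounded);
top-10-PC scores feed a k-nearest-neighbor graph (k = 20, Euclidean),
reweighted by the Jaccard overlap of neighbor sets (self-inclusive, size
k+1) over all overlapping pairs, pruned below 1/15, and partitioned with
Leiden on the RB-configuration quality at resolution 1.2 with a fixed seed.
Labels are renumbered 1..K by decreasing size.  Note that modularity never
merges disconnected components, so the resolution → 0 limit of a single
cluster holds only for connected graphs.

## Differential splicing

Groups are compared as pseudo-bulk: junction counts pooled within group,
Δψ = ψ_B − ψ_A from pooled ψ.  The test is a two-sided Fisher exact test on
[round(I_A/2), S_A; round(I_B/2), S_B] (rounding half-up), i.e. the
standard count-based mode of junction-level differential-splicing tools.
The two-sided p sums hypergeometric probabilities of all tables with the
observed margins that are no more probable than the observed one, computed
from log-gamma pmfs over the full support with a 1e-10 relative tie
tolerance — agreeing with exact rational enumeration to < 1e-13 over all
tables with margins ≤ 30, and fast enough for pseudo-bulk margins in the
tens of thousands.  Events enter the BH family only when quantifiable in
≥ 10% of cells of both groups with pooled coverage ≥ 20 in both; calls use
strict q < 0.05 (the stricter of the two conventions "≤ 0.05" / "< 0.05")
and |Δψ| > 0.1.  Per-cell mean Δψ is available behind a flag
(`per_cell_delta`) without any equivalence claim to the pooled estimate.

Pseudo-bulk Fisher testing is exact for binomial sampling but
anticonservative under strong cell-level overdispersion: the effective
variance inflation is roughly 1 + (reads per cell)/(c+1).  At the default
depth (30 reads, c = 200) this is ≈ 1.2, and the all-null calibration
experiment measures a raw type-I error of ≈ 0.035–0.05 with zero
(q, |Δψ|)-calls; at much deeper per-cell coverage the raw p-values would
need a dispersion-aware replacement (out of scope here).

One-vs-rest contrasts report label-minus-rest.  A planted type-specific
shift δ dilutes into the rest group of other contrasts by roughly
δ·(target fraction)/(rest fraction); when that dilution approaches the 0.1
threshold, off-target calls are genuine properties of the contrast, not
errors.

Signature genes: Wilcoxon rank-sum (normal approximation) on
log-normalized expression, Bonferroni adjustment, log2FC of group means
with a 1e-9 pseudocount; calls at log2FC > 0.25 and adjusted p < 0.05.

## RNA maps

IUPAC scanning reports all overlapping matches; a sequence `N` matches only
the pattern letter `N`.  Window scores are covered-base fractions over
50-nt windows at step 1; each region grid has length (region length − 50
+ 1), with truncated sequences anchored at the exon-proximal edge
(upstream intron and exon 3' right-aligned, the other two left-aligned)
and sub-window sequences skipped.  Position 0 is the first base adjacent
to the exon boundary on the intron side.  Per position, a two-sided
rank-sum test (tie-corrected normal approximation; p = 1 for degenerate
all-tie columns) compares target and background sets (≥ 5 sequences each).
No multiple-testing correction is applied across positions: the enrichment
rule is min raw p < 0.05 in ≥ 1 region *and* max mean target score > 0.01
in ≥ 1 region, with the best region taken at the smallest p.  The score
criterion is what keeps chance p-value dips over ~400 positions from
producing calls for motifs with negligible coverage.

## Module scores and KS contrasts

Normalization: counts per cell scaled to 10000 and log1p-transformed.
Scores use 24 average-expression bins and 100 controls per gene-set gene,
sampled with replacement and pooled before averaging; the control
subtraction cancels global shifts.  The bin count and control count are
the conventional defaults of this procedure; the seed is a required
parameter.  Group comparisons use the asymptotic two-sample KS test —
adequate for the tens-to-hundreds of cells per group in scope, and
measured at a 0.047–0.06 type-I error at n = 100 per group.

## Validation experiment sizes

The acceptance experiments run at: 300 cells × 200 events (ψ consistency,
deep coverage λ = 2000); all 246016 tables with margins ≤ 30 (exact-test
oracle); 20 seeds × 200 null events (calibration); ~50 planted exons at
λ = 500 with 150 cells/group (power); 20 seeds of 100×60 rank-3 matrices
with 10% masking (imputation); 300 cells with 60% type-specific events
(clustering); ~100 target vs ~100 background events, 20 control replicates
(motif maps); 1000 KS replicates at n = 100 (calibration); 20 replicates of
the independence summary over 200 genes.  These sizes give stable
pass/fail behavior across seeds while keeping a full run within a few
minutes on one CPU.
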