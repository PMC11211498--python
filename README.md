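# isletsplice

Single-cell cassette-exon alternative-splicing analysis for full-length
scRNA-seq, built around the questions that arise in pancreatic-islet studies
of type 2 diabetes: do splicing profiles alone distinguish endocrine cell
types, which exons change between non-diabetic (ND) and diabetic (T2D)
cells, which RNA-binding proteins (RBPs) plausibly drive those changes, and
how do maturity/identity scores shift across splicing-defined subsets?

The package is a library: import it from Python, or start from the short
narrative scripts in `examples/`.  A ground-truthed synthetic-data generator
(`isletsplice.simulate`) emulates the statistical structure of such a study
so that every stage can be validated end to end without any download.

## What it computes

**Exon inclusion (ψ).**  For a cassette exon with summed inclusion-junction
reads *I* (two supporting junctions) and skipping-junction reads *S*,

    ψ = (I/2) / (I/2 + S),

quantifiable only when *I* + *S* ≥ 20 reads.  Cells are kept when they
express 2500–10000 genes; events are kept when quantifiable in ≥ 10% of
cells.

**Splicing-profile clustering.**  Missing ψ entries are imputed by
probabilistic PCA fitted with EM over observed entries only (a sentinel-fill
mode is also available); cells are embedded with the top 10 PCs and
clustered on a Jaccard-weighted shared-nearest-neighbor graph with Leiden
modularity optimization at resolution 1.2.

**Differential splicing.**  Pseudo-bulk per group: counts are pooled, and
the 2×2 table `[round(I_A/2), S_A; round(I_B/2), S_B]` is tested with a
two-sided Fisher exact test; Benjamini–Hochberg correction over tested
events; calls require q < 0.05 and |Δψ| > 0.1.  One-vs-rest contrasts give
cell-type-specific exons.  Signature genes use a Wilcoxon rank-sum test with
Bonferroni correction (log2FC > 0.25, adjusted p < 0.05), and a summary
reports the overlap and Spearman correlation between Δψ and log2FC.

**RNA maps.**  IUPAC motifs are scanned over four regions per event
(250 nt upstream intron, exon 5'/3' ends, 250 nt downstream intron); a
50-nt sliding window gives positional coverage profiles, compared between
regulated and background exons by rank-sum tests.  A motif is enriched when
min p < 0.05 and max mean score > 0.01 in at least one region.

**Module scores.**  Per-cell gene-set scores with expression-matched bin
controls (24 bins, 100 controls per gene), compared across groups with the
two-sample Kolmogorov–Smirnov test.

## Worked example

`examples/03_differential_splicing.py` simulates 300 cells under ND/T2D
with 18 exons carrying a planted Δψ = 0.3 condition shift, runs the
differential test and the expression comparison, and prints:

```
events tested: 200   called (q<0.05, |dpsi|>0.1): 18
planted condition-specific events: 18   recovered: 18   false calls: 0
genes changing splicing only: 18   expression only: 17   both: 0
Spearman rho(delta_psi, log2FC) over 200 genes: -0.121 (p=0.09)
```

Every planted exon is recovered with no false calls, and — because the
splicing and expression effects were planted on disjoint gene sets — the
called gene sets do not intersect and Δψ is uncorrelated with log2FC: the
two regulatory layers stay statistically separate.  The other examples
cover simulation/quantification, splicing-only clustering (adjusted Rand
index 1.0 against true types), RNA maps (planted motif enriched in the
upstream intron, control motif rejected) and maturity scoring (KS
p ≈ 1e-34 between mature and immature cells).

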