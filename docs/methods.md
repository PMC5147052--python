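# Methods

This note documents the statistical models and the design choices behind
`cnvphylo`, and what the synthetic-data tests do and do not establish.

## Expression-based CNV genotyping

**Premise.** DNA copy number is reflected in RNA-seq read counts once
expression is averaged over large, adjacent genomic regions; single-gene
expression noise cancels in the sum. The method therefore only
re-genotypes *bulk-called* CNV candidate regions (typically hundreds of
genes each) and makes no attempt at de novo CNV discovery from
expression, allele-specific states, or per-cell integer copy numbers.

**Score and test.** For region *r* and cell *c*, S(r,c) = Σ_{g∈r}
CPM(g,c). The null distribution of S(r,·) is taken from a CNV-free
control cell population measured on the same platform. The per-cell
p-value is a one-tailed add-one empirical rank, p = (1 + #{controls ≤
S})/(n+1) for losses and the upper-tail analogue for gains; ties count as
"as or more extreme". The add-one convention keeps p ≥ 1/(n+1), so the
procedure's resolution is set by the control count — with n controls and
m tests, BH at level α can only ever reject when enough tests share the
minimum p (roughly m/(α(n+1)) of them). In practice this makes the
classifier conservative exactly when evidence is scarce.

Two readings of the "5% significance level of the control distribution"
are possible for a gain (5th vs 95th percentile); the direction-consistent
tail is used, since the lower tail cannot separate gain carriers from
controls. BH is applied over all cell×region tests jointly as one family,
and the call threshold is adjusted q < α with α = 0.05; α ≥ 1 is treated
as the degenerate "call every assessable test". The cross-validated
false-call rate is (positive calls)/(total tests) per fold, the only
non-degenerate reading on all-null control tranches.

**Known bias.** Calls use CPM, so a cell's true gains deflate the CPM of
every other region (and losses inflate them) by roughly the gained
fraction of the transcriptome. With default simulation settings (300-gene
regions in a 6,000–20,000-gene transcriptome) this distortion is 1–3% of
a region score, an order of magnitude below the 50% dosage effect, and is
the dominant source of the ~1% residual genotyping error seen in tests.

**Smoothing track.** The visualization track is log2((CPM+1)/(control
median CPM+1)) per gene, denoised per chromosome by single-level discrete
wavelet shrinkage (Haar basis, soft thresholding at the universal
threshold σ√(2 log n), σ from the median absolute detail coefficient),
then z-scored per cell. The Haar basis and single level were chosen as
the simplest shrinkage consistent with block-shaped CNV signal; genotype
calls are insensitive to applying the same smoothing to the expression
itself (checked in tests at strong effect sizes).

**Stromal triage.** A cell is putative-stromal only if it has zero CNV
calls, zero expressed somatic variants, and sits in a
hierarchical-clustering cluster (correlation distance, average linkage,
log2(CPM+1) over a user-supplied marker panel) whose majority is
zero-CNV cells. Correlation distance is invariant to uniform log-shifts,
so the marker panel must differ in *shape* between cell types, and should
include genes that structure the malignant cells too; with an empty panel
the clustering criterion is skipped with a warning.

## Phylogeny

Genotype classes (cells with identical call sets) are the taxa; the
distance is the Jaccard distance between class genotypes, with a CNV-free
"normal" out-group appended. The Fitch–Margoliash objective
Σ_{i<j} w_ij (d_ij − p_ij)², w_ij = 1/d_ij², is minimized over unrooted
binary topologies with exact weighted non-negative least-squares branch
lengths per topology (path-membership design matrix). Zero distances get
the weight of the smallest positive distance to keep the objective
finite. Search is exhaustive through 8 leaves ((2n−5)!! topologies);
beyond that, stepwise addition in label order followed by
nearest-neighbor-interchange refinement, which never increases the
objective. Ties resolve to the first topology in enumeration order, so
fits are deterministic. The root bisects the out-group's pendant edge.
Cells lacking the founding CNV are *not* filtered; they simply form
classes near the root.

## Clonal pseudotime

The backbone path descends from the root, at each fork following the
clade whose newly acquired region is carried by the most cells (ties:
larger clade, then lexicographic leaf). Genotyping errors scatter a few
spurious low-frequency classes around the true chain, and least-squares
fitting may attach them as cherries off the backbone; every class whose
genotype is nested in the terminal genotype is therefore assigned to the
path, ordered by genotype size. Bins (early/mid/late) are terciles of
*cell-weighted* path position — each class joins the bin containing the
midpoint of its cumulative cell span — so a handful of one-cell outlier
classes cannot displace the dominant clones across bin boundaries; with
equal class sizes this reduces to plain position terciles. Monotone genes
are those whose per-bin means are strictly ordered; with three bins a
null gene passes by chance with probability 1/6, which the permutation
calibration in the tests reproduces. No minimum effect size is imposed;
downstream enrichment is expected to operate on the ranked list.

## Dose–response and classifiers

Dose–response is Spearman rank correlation (average-rank ties) of each
gene against the focal transcript's per-cell expression, after the
standard prefilter dropping genes below 1 CPM in more than 80% of cells.
"Top 5%" is read per tail — the positive and negative sets each take
ceil(0.05·G) genes — since both directions are analyzed downstream. The
four-centroid classifier regresses the cell's standardized log2(CPM+1)
profile over the signature genes on the four standardized centroids
without intercept (standardization makes the intercept ≈ 0) and labels by
the largest |coefficient|; the two-module classifier compares mean
log2(CPM+1) across the module gene sets and labels only on a more than
twofold margin. Signature and module gene lists are user-supplied files;
tests use synthetic centroids, so nothing third-party is redistributed.

## Exon-level deletion detection

Per sample, the statistic is the fraction of the gene's reads on the
target exons; it is invariant to sequencing depth. Tumors are tested
lower-tailed (deletions only) against the blood-control fractions with
add-one empirical p-values and BH across tumors at the permissive
adjusted p < 0.25, alongside a fixed call at the controls' 10th
percentile. For *cohort prevalence*, the raw BH-significant fraction is
biased upward by construction — at FDR level α with prevalence π₁ the
step-up fixed point rejects ≈ m·π₁/(1 − α(1−π₁)) tests, e.g. ≈ 0.20 at
π₁ = 0.16, α = 0.25 — so the primary estimator background-corrects the
threshold call rate: π̂₁ = (rate − q)/(1 − q) with q = 0.10, which is
unbiased whenever truly depleted samples fall below the threshold with
near certainty (strong suppression). Both numbers are reported. A single
400-tumor cohort's estimate carries SD ≈ 0.03 (binomial noise plus
control-quantile noise), so calibration tests average replicate cohorts.

## Synthetic data generator

The generator emulates: a clone tree with cumulative (nested) CNV
acquisition; regions as contiguous, disjoint blocks of `genes_per_region`
genes (default 300, matching the gene content of the large CNVs the
method targets); linear dosage — the expected count of an in-region gene
is multiplied by 1.5 per gained region and 0.5 per lost region (three and
one copies against a diploid baseline; the simplest law consistent with
the dosage premise); negative-binomial counts via a gamma–Poisson mixture
with shared size parameter (default 2) and log-normal library factors
(σ = 0.2); a CNV-free control population from the identical law; and
per-exon Poisson coverage with per-sample depth factors and partial
target-exon suppression for deletion carriers (heterozygous or subclonal
deletions deplete, not erase, coverage). Defaults for the effect size are
configurable model choices, not measured values — no generative
calibration exists in the source setting.

It does **not** model: doublets, ambient RNA, dropout beyond NB
sampling, gene-specific expression levels or dispersions, overlapping
CNVs, cell-type expression programs (control cells share the tumor
baseline law), or GC/mappability structure in exon coverage. Passing
tests therefore demonstrate the statistical machinery — calibration of
empirical p-values and BH, recovery under the stated dosage model, exact
tree fitting — not robustness to every artifact of real scRNA-seq.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a laptop-class single core:
200-cell control populations for cross-validation, 200–480 tumor cells
over 6,000–20,000 genes for recovery and pseudotime, 20 replicate 5–6
leaf trees for the tree oracle, 5,000 null tests (100 fresh-reference
batches of 50) for p-value uniformity, and 400-tumor/170-control cohorts
for the depletion test. Uniformity is checked in fresh-reference batches
because, conditional on any single finite reference, empirical p-values
are not uniform (the reference's own ecdf error, ~n^{-1/2}, is shared by
all tests against it). Degenerate inputs are handled explicitly:
zero-library cells are flagged and excluded from metrics, gene-free
regions are excluded from calling, all-zero distance matrices produce a
star tree with a warning, and empirical-p ties count conservatively.
Fixed seeds make every simulation reproducible; generators derive
independent streams for truth, tumor counts, controls, and coverage.
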