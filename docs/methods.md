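# Methods

This note documents the models, statistics and design decisions behind
`scregnet`, the way they are implemented, and what the synthetic benchmark
does and does not establish about real data.

## Quality control and annotation consistency

Cells are gated per modality. RNA: 200 ≤ detected genes ≤ 6000 (inclusive
bounds), UMI > 1000, mitochondrial fraction ≤ 0.10. ATAC: 1000 <
peak-region fragments < 20 000, FRiP > 0.15, blacklist ratio < 0.05,
nucleosome signal < 4, TSS enrichment > 3. All gates except the gene-number
bounds are strict inequalities. High-mitochondrial cells are treated as
low-quality and removed; the boundary value 0.10 itself is kept. Each
decision is attributable: the audit tables record, per cell, which gate
failed. Agreement between two annotations of the same cells is summarized
by the Jaccard matrix J(x, y) = |cells(a=x) ∩ cells(b=y)| / |union|.

## Gene activity and peak annotation

A peak contributes its counts to a gene when the peak midpoint lies in the
gene body extended 2 kb upstream of the TSS (strand-aware). Midpoint
assignment avoids ambiguity for peaks straddling region boundaries. Peaks
are annotated promoter (midpoint within 1 kb of any TSS; takes precedence),
gene_body, or distal; the ±1 kb promoter rule is the same one used for cCRE
linkage, keeping the two analyses consistent.

## Differential features

One-vs-rest per cell type on depth-normalized values (counts per 10 000 per
cell, log1p for the test), two-sided Wilcoxon rank-sum, Bonferroni over all
(feature, group) tests; reported log2 fold change is
log2((m_in + 1)/(m_out + 1)) on group means of the counts-per-10k scale, so
a pseudocount of 1 stabilizes sparse means. Differential features are
called at adjusted P < 0.05 and log2FC > 0.25. The rank-sum test replaces a
hurdle-model test sometimes used for droplet RNA data: it is dependency-free
and well-defined for both modalities, and the thresholds — not the test
family — carry the procedure. Groups with fewer than 3 cells on either side
are skipped with a warning.

The DAR–DEG association statistic counts, per cell type, the fraction of
differentially accessible regions whose peak is a promoter/gene-body peak of
a same-type differentially expressed gene or is linked to one through a
cCRE; the exact association rule is a declared interpretation (the field
uses several), and the linkage set is an explicit argument so callers can
substitute their own.

## Motif deviations

For motif m and cell j, X_mj is the cell's total counts over the motif's hit
peaks; the expected value under no motif effect is E_mj = f_m t_j with
t_j the cell total and f_m the hit peaks' share of all counts, so depth
normalization is built into the expectation (raw deviations are exactly
invariant under uniform count rescaling, and invariant to single-cell depth
up to the aggregate's recomputation). Background iterations re-draw each hit
peak from its k = 50 nearest neighbors (Euclidean, z-scored GC fraction and
log1p mean accessibility; a peak never draws itself), n_iter = 50 by
default. Bias-corrected deviation = raw − background mean; Z = that
difference over the background SD (sample SD, ddof = 1). Entries with
E = 0 are reported missing and excluded from group summaries.

Differential TF activity is one-vs-rest on the deviation **Z-scores** by
default (a `score="deviation"` switch exists). The default matters: the
activity gates (difference > 1 for ordinary differential activity, > 4 for
tumor specificity) are only commensurate with standardized scores — a
k-fold accessibility effect bounds the raw bias-corrected deviation near
k/ē − 1 (ē the population-average effect), which never reaches 4 for
realistic k. Because deviations are signed, "fold change" is ill-defined;
the reported `activity_delta` is the difference of group means and is
flagged as such in the table metadata.

## Tumor-specific TF filter

Per TF, per-type means of bias-corrected deviations are reduced to their
population SD across types. The SD distribution is asymmetric, so the
outlier gate uses the upper side of the double-MAD scheme:
threshold = median + 4 × median(|x − median| for x ≥ median), computed over
**all** TFs' SDs, with no 1.4826 consistency constant (the threshold is
stated directly as "median plus 4 MAD"; the choice is recorded in the
output metadata). Selected TFs additionally need activity_delta > 4 with
adjusted P < 10⁻⁴ in the target type and activity_delta < 1 in every other
type. Even-length medians are the mean of the central pair.

The drug screen returns approved compounds whose perturbation Z-score for
the TF's gene is strictly below −2, sorted by ascending Z.

## Cis-regulatory linkage and networks

Accessibility is densified by pooling cells within each annotated type into
seeded random metacells of 10 cells (remainder merged into the last pool).
This replaces embedding-based k-NN metacells: it needs no latent coordinates
and preserves the covariance structure the estimator uses, at the cost of
ignoring within-type substructure. Co-accessibility is estimated in 500 kb
windows advancing by 250 kb; within a window, standardized log1p metacell
counts enter a graphical lasso whose elementwise penalty is
ρ_ij = 0.2·(1 + (d_ij/window)²) — the distance-increasing penalty shrinks
implausibly long-range partial correlations. The estimator is implemented
here as Friedman block-coordinate descent because available library
implementations only accept a scalar penalty; at a constant penalty it
reproduces scikit-learn's `graphical_lasso` to < 1e-4 (tested). The score
of a pair is the negative rescaled partial correlation
−Θ_ij/√(Θ_iiΘ_jj), averaged over windows containing the pair; pairs with
score ≥ 0.2 are retained. Degenerate windows (constant peaks) are skipped
with a warning.

A candidate link requires exactly one peak of a pair to be a promoter peak
(midpoint ≤ 1 kb from a TSS). The other peak's per-type mean accessibility
is Pearson-correlated with the gene's per-type mean expression (both log1p
counts-per-10k means; a switch to raw means exists), two-sided t-test with
n_types − 2 df, Benjamini–Hochberg across all candidate links, q < 0.05.
With few cell types this test has little power (df = 2 at four types), so
only near-collinear links survive — an intrinsic property of the procedure,
not of the implementation.

TF targets in a cell type: a gene is a target when a promoter peak of the
gene, or a cCRE linked to it, carries the motif and is accessible —
operationalized as detected in ≥ 5% of the type's cells (the literature
leaves "accessible" unquantified). Targets form a directed TF→gene network
(networkx) with per-edge evidence records (promoter_motif / linked_ccre)
and per-node differential-expression flags.

Module scores follow the binned-control construction: genes are ranked into
24 mean-expression bins; each signature gene draws 100 seeded controls from
its bin; score = mean(signature) − mean(controls) per cell on
log-normalized data. Scores are exactly invariant to adding a constant to
all log-expression values.

## Intratumoral NMF programs

Per sample, tumor-cell log-normalized expression is gene-centered and
clamped at zero ("relative expression"); NMF with the multiplicative-update
solver (Frobenius objective, random init) runs at k = 2..6 with 30
restarts; the best-reconstruction run is kept per rank. Rank selection uses
the consensus of cell co-assignments (argmax program per run): the
cophenetic correlation between consensus dissimilarity and its
average-linkage hierarchy, choosing the k before the largest drop (argmax
of the coefficient when no drop is positive). A program is its 30
top-loading genes, ties broken lexicographically; programs padded with
zero-loading genes are flagged degenerate.

Cross-sample consolidation scores every program's top genes on every
sample's tumor cells, averages the per-sample Pearson correlation matrices
of those score vectors, Ward-clusters 1 − avg corr, and cuts the dendrogram
at the largest merge-height gap **capped at distance 0.3**. The cap is this
package's design decision where the procedure is otherwise open: members of
one meta-program must be highly correlated (r ≥ 0.7, the conventional bar),
so no gap higher up the tree can force weakly coupled programs into one
cluster. Clusters whose members span less than half of the samples are
dropped; a meta-program's signature is the 30 genes with the highest mean
L2-normalized loading over its members.

## Ligand–receptor inference

Triples (pair, source type, target type) are testable when the ligand has a
nonzero count in ≥ 10% of source cells and the receptor in ≥ 10% of target
cells (clusters under 10 cells are excluded). The strength is the average
of the two cluster means of log-normalized expression (the ≥ 1 significance
gate applies to this scale; a raw-mean switch exists). P-values come from
n_perm = 1000 cluster-label shuffles with the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm) — conservative and never
zero; the observed statistic is computed through the identical code path as
the permuted ones so exact ties compare as equal. Multi-subunit complexes
are out of scope; the pair table is flat gene–gene pairs.

## Synthetic multiome generator

The generator is first-class, tested code; its defaults are the study
conditions of the test-suite: 3 samples × 4 cell types (one tumor) × 100
cells, 300 genes, 200 peaks on two synthetic chromosomes, 20 motifs of
which 3 are tumor-specific with a 3× accessibility effect, 20 planted
cCREs, 2 shared intratumoral programs plus one private program per sample,
and 6 planted ligand–receptor channels. Counts are Gamma–Poisson with
lognormal per-cell depth (RNA dispersion 0.3; ATAC dispersion 0.1 —
fragment counts are near-Poisson); GC content is simulated from a
Beta(6, 6), not computed from sequence; coordinates are 0-based half-open.

Design choices that matter, with reasons:

* **Planted effects are disjoint and attributable.** Marker promoters,
  planted cCRE peaks and tumor-motif peaks come from separate pools, and
  non-planted motifs sample hit peaks only from unplanted peaks, so every
  recovery test has an unambiguous ground truth.
* **Tumor-specific motifs share one binding-site pool** (1.6× one motif's
  hit count) placed in the gene deserts at the chromosome tails. Co-active
  TF modules sharing sites are biologically standard; at desk scale the
  alternative (separate pools) would put over a fifth of all peaks under
  the tumor effect, contaminating matched background draws and the
  double-MAD null, and gene-desert placement keeps tumor coactivity out of
  promoter-containing co-accessibility windows, where it would otherwise be
  (correctly, but unhelpfully for benchmarking) reported as linkage.
* **Planted peaks keep a typical mean accessibility**: their baselines are
  lowered by log1p((effect − 1)/n_types) so the tumor multiplier does not
  push them all to the top of the accessibility spectrum, which would bias
  accessibility-matched background sampling toward other planted peaks.
* **cCREs are fully coupled by default** (`ccre_effect = 1`): each planted
  element shares a per-type log-factor (sd 0.8) and a per-cell latent
  (sd 0.8) between its distal peak, promoter peak and gene. With four cell
  types the linkage test has df = 2 and needs near-collinearity; the
  coupling dial exists to study weaker elements. Because 30-gene programs
  occupy a large fraction of a 200–300 gene genome (unlike 30 of ~20 000 in
  real data), program/marker load would dilute cCRE genes' relative
  abundance type-dependently; the generator compensates their rates by each
  type's mean relative row sum so the planted correlation survives
  normalization, honoring the stated coupling contract.
* **Programs are independent axes**: membership is an independent Bernoulli
  draw per (cell, program) (default fraction 0.15; effect 4×). A partition
  would make every sample's "private" program share one anti-shared-program
  profile, which consolidation then reports as a spurious third
  meta-program. A per-sample continuous intratumoral axis (log-sd 0.2 over
  all genes except planted cCRE genes) models patient-specific
  stress/dissociation gradients; it gives over-factorized NMF runs a
  sample-specific factor whose gene composition matches the genome, so
  bin-matched control genes neutralize it in program scoring.

What the generator does **not** emulate: fragment-level Tn5 insertion,
doublets, batch effects, ambient RNA, sequence-derived GC, within-type
substructure beyond the planted programs/axis, or genome-scale sparsity
(counts per feature are far denser than real droplet data). Passing the
recovery tests therefore shows the statistics are implemented correctly and
behave as designed under their intended signal model — not that they are
powerful or calibrated on real tumor atlases; in particular the df = 2
linkage correlation and the desk-scale DAR–DEG association proportion are
not comparable to values from genome-scale data.

## Numerical choices and degenerate inputs

Medians of even-length lists are central-pair means. Bonferroni multiplies
by the number of tests actually performed; BH uses the standard step-up.
Background SDs of zero yield missing Z-scores. Constant peaks are dropped
per co-accessibility window; windows with < 2 usable peaks are skipped.
NMF ranks ≥ min(matrix dims) are skipped with a warning. All randomness
flows from explicit integer seeds; the pipeline derives per-stage seeds as
seed + stage index, and the run manifest (parameters, seeds, SHA-256 of
every output) is byte-identical across repeated runs.

## Problem sizes

The test-suite and the acceptance script run at the generator's default
scale (1200 cells × 300 genes × 200 peaks; NMF consolidation at 3 × 150
tumor cells × 200 genes with 30 restarts at k = 2..6; permutation
calibration at 600 cells × 300 genes × 1000 permutations), chosen so the
full suite exercises every stage end to end in minutes on one CPU.
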