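# Methods

This note documents the models and procedures `brmtme` implements, the
numerical choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Targeted-expression preprocessing and scoring

**Sample QC.** A sample is retained iff the geometric mean of its
housekeeping-gene counts is ≥ 50 (removal is strictly-below, so a geometric
mean of exactly 50 is kept). Technical duplicates are identified by a shared
base id with a `_2` suffix; the member with the higher housekeeping geometric
mean is kept and renamed to the base id.

**Normalization.** Three ordered steps per cohort: (1) background
thresholding — every count below the per-sample maximum of the negative
controls is raised to that maximum; (2) positive-control scaling — each sample
is multiplied by (cohort mean of per-sample positive-control geometric means)
/ (its own positive-control geometric mean); (3) the same with housekeeping
geometric means, recomputed after step 2. `NanostringNormalizer` is
fit/transform-shaped so a fitted cohort reference can be applied to held-out
samples. The log2 transform uses `log2(x)` directly; thresholding guarantees
values ≥ the negative-control maximum, which in practice is ≥ 1 — if any
value < 1 remains, `log2(x + 1)` is used and logged, since no pseudocount
convention is otherwise imposed.

**Enrichment score.** Per signature: z-score each member gene across patients
(sample standard deviation, ddof = 1), average over member genes, then
min–max rescale across patients to [0, 1]. The score is therefore invariant
to any positive affine transform of an individual gene, and a single-gene
signature is a rank-preserving transform of that gene. Design choices:
ddof = 1 (cohort-level convention; the min–max step makes the worked example
invariant to this choice); absent or zero-variance genes are dropped with a
warning and the signature size reduced, because targeted panels routinely
contain undetected genes; if the mean z is constant across patients, all
scores are set to 0.5 with a warning ("no information" rather than a
division-by-zero failure).

**Stratification.** Ward-linkage agglomerative clustering (Euclidean
distance) on the patients × 7 cell-type score matrix, cut at k = 3. The
inflammation (IFN-γ) signature is scored but excluded from the clustering
features, mirroring its display-only role. Scores are already min–max scaled,
so no further standardization is applied before the linkage. Cluster names
(low / intermediate / high) are assigned by ranking cluster mean enrichment
across the clustering signatures.

**Statistics.** Strata comparisons default to the pooled-variance Student t
(two-sided) with a Welch flag, since only "t-test" is specified upstream.
The Pearson correlation CI is a patient-level percentile bootstrap
(2.5/97.5 percentiles of `n_boot = 1000` pair resamples); the original
"multilevel" bootstrap scheme is not further specified, so the plain
patient-level version is used and named as such. Survival uses lifelines'
product-limit estimator and log-rank test (multivariate form for > 2 groups);
a table with zero events or a single stratum is an error.

## Single-cell pipeline

**QC.** genes_detected and pct_mito (gene-name prefix `MT-`) are recomputed
from the count matrix. Removal conditions are strict inequalities —
`< min_genes`, `> 2500` genes, `> max_pct_mito` — so boundary cells (exactly
100 genes or exactly 10.0% mitochondrial under tumor rules) are kept.
Defaults: tumor 100 / 2500 / 10%, CSF 70–100 / 2500 / 20%. The CSF
`min_genes` is chosen on a 70..100 grid maximizing (fraction of
erythrocyte-like cells removed) − (fraction of other cells removed), where
erythrocyte-like means any hemoglobin count (HBB/HBA1/HBA2) > 0; ties break
to the smallest threshold so as few intact cells as possible are lost.

**Normalization and features.** `ln(1 + 10^4 · count / cell_total)` per cell.
Variable genes are ranked by the residual of log10 variance against a
degree-2 polynomial trend in log10 mean (the named upstream method is not
re-specified, so an explicit, reproducible trend fit is used); constant genes
are never selected.

**Clustering.** Variable genes are z-scaled; PCA retains components with
standard deviation ≥ 2.0 (minimum 2); a k = 20 nearest-neighbor graph with
Jaccard edge weights feeds modularity-based community detection
(Leiden, RBConfiguration) at resolution 0.4 with a fixed seed. A practical
note on the dimension rule: with p features and n cells the sampling-noise
PCs have sd near the Marchenko–Pastur edge $(1+\sqrt{p/n})$, so the sd ≥ 2
cut separates signal from noise only when n is comfortably larger than p — at
cohort scale this holds; on very small subsets the retained dimensionality,
not the rule, controls granularity. For the same reason, when T cell clusters
(> 10% of cells with mean normalized CD3D/CD3E > 0, strict) are pooled and
re-clustered, the re-run caps the variable-gene count at half the subset's
cell count. Clusters dominated by cell-cycle signal can be flagged and are
re-clustered alone without cycle adjustment.

**Annotation.** Three evidence layers vote per cluster: (1) curated-marker
expressing fractions (vote = cell type with the highest mean fraction);
(2) the count of each type's markers among the top-20 DE genes by log2 fold
change from one-vs-rest Wilcoxon rank-sum tests with Benjamini–Hochberg
adjustment within cluster (ties cast no vote); (3) the lowest-FDR positive
preranked-GSEA enrichment at FDR < 0.25. A 2-of-3 majority labels the
cluster; otherwise it stays "unassigned" with the evidence emitted for
review. Clusters where > 25% of cells co-express T (CD3D/CD3E) and myeloid
(CD68) markers are flagged as suspected doublets. The shipped marker YAML and
cell-cycle gene lists are pragmatic working defaults, not the original
expert-curated lists, and should be replaced for real analyses.

**GSEA.** Weighted Kolmogorov–Smirnov running sum (weight exponent 1,
extremum by absolute deviation), gene-label permutation null, NES by
same-sign mean normalization, FDR by the standard positive/negative pooled
ratio. The enrichment score is verified against gseapy's prerank in the test
suite; the in-package implementation exists because the calibration tests
need hundreds of vectorized replicates with explicit seeding. Default
`n_perm` is 1000 (100 in the fast pipeline profile).

**Cell-cycle scores.** Mean over set genes of gene-wise z-scored normalized
expression, so scores are invariant to per-gene affine rescaling and a
constant dataset scores exactly 0. The per-cluster comparison flags a cluster
only when the one-vs-rest Mann–Whitney p < 0.05 AND the mean score difference
exceeds 0.1; "fold change" is implemented as a difference of means because
the scores are signed.

## TCR repertoire

Chains are kept iff `is_cell`, `productive` and `full_length`. A clonotype is
a distinct (chain, CDR3 amino-acid) pair — chain-scoped, so the same string
on TRA and TRB is two clonotypes, and a cell with both chains contributes to
two clonotypes (this matches counting alpha and beta sequences separately;
paired-chain clonotyping is deliberately not used). Supporting cells are
distinct barcodes (duplicate contigs count once). A clonotype is expanded iff
supported by ≥ 2 cells (threshold configurable); a cell is expanded iff it
carries any expanded sequence — expansion takes precedence when its chains
disagree. Per-cluster enrichment uses the two-sided conditional Fisher exact
test on [expanded-in, singleton-in; expanded-out, singleton-out] with the
sample cross-product odds ratio (±inf at zero cells, no continuity
correction). Compartment overlap is exact Venn-region counting over clonotype
identity. Clonal trajectories normalize clone frequencies by the TCR-bearing
cells at each timepoint (repertoire-internal normalization, stated in the
output); a clone is persistent when present at every sampled timepoint from
its first appearance on; the fish-plot table is flat (parent = none) because
clonal ancestry is not inferred.

## Abundance and TMB

Cell-type proportions are per-sample fractions; the PAN column is recomputed
from pooled counts (not a mean of proportions). The tumor-vs-CSF volcano uses
log2 of the ratio of arithmetic mean proportions (tumor over CSF), a
pseudo-proportion of 1e-6 for absent types (flagged), and a two-sided
Mann–Whitney p; classes at p < 0.05 follow the sign of the fold change, and
the orientation is declared in the output metadata. The CD8/CD4 ratio drops
samples with zero CD4 cells (logged) and compares paired tumor/CSF samples
with the exact two-sided Wilcoxon signed-rank test.

TMB intersects two callers' variants on (chrom, pos, ref, alt) after
splitting multi-allelic records; consequence labels are normalized through a
configurable synonym map and taken from the first caller on disagreement
(logged). TMB = nonsynonymous consensus mutations / 47 Mb (configurable
library size); indels, when present in the input, are counted by default.

## Synthetic cohorts

The generator's defaults are the study conditions: 48 patients on a 730-gene
immune panel with 40 housekeeping genes and 6/8 positive/negative controls;
three equal infiltration groups with signature genes shifted by
2^(effect·level), level ∈ {0, ½, 1}, and effect 2.0 log2 units; one injected
low-quality sample and one duplicate pair (cohorts ≥ 10). Single-cell samples
draw negative-binomial counts (shared dispersion 0.1) with near-on/off
lineage markers (baseline weight 0.2, overexpressed 2^6-fold); tumor samples
are macrophage-dominated and CSF lymphocyte-dominated; planted artifacts are
4% low-complexity cells, 4% high-mitochondrial cells (25–45%), 3% T×myeloid
doublets whose library depth guarantees > 2500 detected genes on the panel,
and (CSF only) 10% hemoglobin-positive erythrocyte-like barcodes below 100
genes. TCR clone sizes are geometric (p = 0.85, ≈ 85% singletons, near the
observed singleton fraction in repertoires of this kind); expanded-clone
membership weights cytotoxic cells by the expansion-bias odds multiplier
(default 5); 30% of expanded tumor clones are shared into CSF t0; CSF clones
persist to the next timepoint with probability 0.6 (each carried clone gets
at least one cell so persistence = 1 is exactly representable). CDR3s are
random C…F amino-acid strings — identity, not biology, is what downstream
stages test. Variant callers share round(n_true · 0.8) variants plus private
true calls and 15% private false positives; survival is exponential with a
geometric hazard ladder between strata (baseline median ≈ 38 months) and
independent censoring.

What the generator does **not** emulate: correlated gene programs and
transcriptome-wide covariance, batch effects, UMI/sequencing error, ambient
RNA, V(D)J segment usage, and non-proportional hazards. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
idealized noise, not that it is robust to every artifact of real data.

## Problem sizes and determinism

Tests and the acceptance script run at reduced sizes chosen to keep the
planted signals comfortably detectable: bulk cohorts of 12–48 patients,
single-cell samples of a few hundred to ~1700 cells on 3000–4000-gene panels,
TCR repertoires of a few hundred T cells, 50-seed detection-rate estimates,
GSEA calibration at 100 permutations × 100–200 replicates. Every stochastic
stage derives its generator from one integer seed through hashed, named
substreams, so identical configurations produce byte-identical outputs and
adding a stage never perturbs existing ones.

## Known limitations

- The curated markers, IFN-γ signature and cell-cycle gene lists ship as
  clearly non-canonical defaults; real analyses must supply their own.
- Batch/anchor integration, UMAP, pseudotime, flow-cytometry gating, IHC
  quantification and driver-consequence annotation are out of scope; the
  pipeline consumes their outputs as tables where relevant.
- The bootstrap CI is patient-level (not multilevel); with few patients it
  can be anti-conservative.
- Community-detection granularity depends on the retained PCA dimensionality
  and graph size as noted above; the resolution default (0.4) is tuned for
  cohort-scale runs.
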