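# Methods

## Quantification and normalization

A molecule is identified by the tuple `(cell barcode, gene, UMI)`; reads
sharing a tuple are sequencing duplicates and count once. Deduplication is
exact string identity — no edit-distance collapsing of near-identical UMIs
— so a UMI collision (two molecules of one gene in one cell drawing the
same tag) under-counts by one. At the default UMI length of 8 the collision
probability per molecule pair is 4⁻⁸ ≈ 1.5 × 10⁻⁵; tests that compare
distinct-UMI counts to planted molecule counts allow a handful of
collisions per 10⁴ molecules.

Cell QC retains a cell iff detected genes ≥ 1,000 **and** total UMIs ≥
20,000 **and** mapping ratio ≥ 0.20 — the removal rules are phrased as
"fewer than", so equality retains. An optional upper guard on raw reads
(against doublet-like cells) can be a fixed number or `"auto"` (the 99.5th
percentile). It is **off by default**: a percentile guard unconditionally
removes ~0.5% of cells even from a perfectly clean dataset, and the right
cut-off is protocol-dependent.

Expression is `log2(TPM/10 + 1)` with TPM = count / cell total × 10⁶ and no
gene-length term (UMI counts are molecule counts). The /10 reflects that
plate-based cells rarely reach 10⁶ molecules; without it each transcript
would be counted several times. Per cell, `Σ (2^expr − 1) · 10 = 10⁶`
exactly — a conservation identity the tests verify to 10⁻⁶ relative.

## Highly variable genes

Two selectors, both taking the normalized matrix:

* **Inverse CV² fit.** Per-gene mean μ and squared coefficient of variation
  CV² = σ²/μ² are computed on the **de-logged linear scale** (2^expr − 1,
  i.e. TPM/10). On that scale pure sampling noise gives CV² ≈ 1/μ, so the
  two-parameter model CV² = a₀ + a₁/μ fit by least squares describes the
  technical trend; a gene is selected when its CV² exceeds the fitted value
  by more than one residual standard error (n − 2 degrees of freedom).
  Computing the moments on the log scale instead destroys the inverse-in-
  mean relationship and, measured on planted data, drops sensitivity from
  ~100% to ~20% — hence the linear-scale choice. Genes with zero mean are
  excluded from fit and selection; variances below 10⁻²⁴·μ² are treated as
  exactly zero (de-logging jitter). The residual-SE criterion is a
  pragmatic reading of "beyond one standard error"; a chi-square band
  around the fit would be the main alternative.
* **Mean/dispersion thresholds.** Mean expression > 1 and dispersion
  (variance/mean of the log-scale values) > 1, both strict, so a gene at
  exactly 1 is excluded.

An optional pre-filter (expression > 1 in ≥ 3 cells) precedes HVG selection
inside the clustering recursion.

## Iterative random-forest cluster refinement

Each round operates on one group of cells:

1. HVGs are re-selected on that group (inverse CV² fit with the
   pre-filter).
2. Cells are bisected by cutting an **average-linkage** hierarchy on the
   distance 1 − Pearson correlation (over the HVGs) into two clusters.
   Average linkage is a deliberate choice; the distance family is fixed but
   the linkage is configurable in principle (complete, Ward on an
   embedding) and average was kept as the least shape-biased default.
3. One pass of stratified 10-fold cross-validated random forests yields
   (a) out-of-fold vote fractions for each cell's provisional label and
   (b) fold-averaged feature importances. Feature genes are those with
   importance above mean + 1 SD, capped at the top 200 (top 10 as a floor).
4. Cells voted > 0.6 form the training set; a forest trained on them (over
   the feature genes) re-predicts the remaining cells. An empty training
   class signals an unstable split, which the recursion treats as a
   rejection.
5. Vote probabilities are finalized as the mean out-of-fold vote fraction
   over `reps` repeats of 10-fold cross-validation on the refined labels;
   cells below 0.55 are abandoned at this node and excluded from deeper
   levels.
6. The split is **accepted** iff both refined subgroups have ≥
   `min_cluster_size` (default 20) cells and ≥ `min_deg` (default 10) genes
   pass the marker gates between them (either direction). Otherwise the
   node becomes a leaf with a recorded stop reason. Accepted children are
   recursed into; leaves are labelled depth-first.

Forest settings: `class_weight="balanced"`, scikit-learn defaults
otherwise, `n_trees` = 100 by default. The published procedure this
follows specifies "100 runs of 10-fold cross-validation" but neither tree
counts nor importance criteria; those are declared choices here, all
seeded. The acceptance benchmarks run at desk scale — `reps=10`,
`n_trees=50`, K = 5 × 120 cells × 2,000 genes — sizes at which vote
fractions are already stable for well-separated groups; everything is
configurable upward.

Seeding: a `SeedSequence` per node, spawned along the tree, makes the whole
recursion deterministic given the input and one integer seed — the
acceptance suite checks byte-identical output files across runs.

## Markers

For gene g and cluster k vs rest: AUC = P(X > Y) + ½P(X = Y) over all
between-group pairs, computed via midranks (rank-sum identity), and
power = 2·|AUC − 0.5| maps it onto 0 = random, 1 = perfect. Fold change is
taken on the de-logged linear scale with pseudocount ε = 0.01:
(mean_in + ε)/(mean_out + ε). A marker needs fold change ≥ 2 or ≤ 0.5
**and** power ≥ 0.4. Passing genes sort by power, then |log2 FC|, then gene
id — a total order, so output is reproducible. The DEG count used by the
clustering stop rule is the size of this list for one child vs the other
(the gates are two-sided, so this already counts both directions).

## Cell cycle and regional statistics

* **Phase rule.** Scores are unweighted means of the G1/S and G2/M gene
  sets (absent genes dropped with a warning; an entirely absent set is an
  error). quiescent iff both scores < 2; otherwise G2/M iff
  G2/M score > G1/S score, else G1/S. The published rules are strict
  inequalities and do not cover the exact tie ≥ 2; ties go to G1/S here
  (configurable in principle; the grid test pins the behavior).
* **Interneuron dominance.** Positivity is expression > 1 (strict; a cell
  at exactly 1.0 is negative). Ratio = nA/(nA + nB); doubly positive cells
  count in both tallies. Regions with nA + nB < 15 are `insufficient`;
  ratio > 0.6 → A-dominant, < 0.4 → B-dominant, the closed interval
  [0.4, 0.6] → balanced (the boundaries land in `balanced` because the
  dominant calls are strict).
* **Maturity.** Per region: fraction of excitatory neurons with marker
  expression > 1, and the mean over neurons of the per-neuron synapse
  gene-set score; regions with fewer than 50 neurons are excluded. Gene-set
  membership (cycle sets, synapse GO terms, disease sets) is configuration
  supplied as GMT files, never computed.
* **Enrichment AUC.** Per cell, genes are ranked by expression descending
  with exact ties broken by a seeded random permutation (one per cell); the
  recovery curve counts set genes among the top ⌈0.05·G⌉ ranks and the
  score normalizes its area by the best achievable area. The score is
  monotone in any set gene's expression and equals 1 iff the set occupies
  the top ranks.
* **Heterogeneity.** For each sub-cluster with > 200 cells, HVGs are chosen
  by the mean/dispersion rule on that sub-cluster and cell-cell Pearson
  correlations computed over them. For each ordered region pair (A, B) the
  off-diagonal within-A distribution (self-correlations excluded — exactly
  n of them) is compared with the A×B cross distribution by a two-sided
  rank-sum test (SciPy's exact enumeration for small tie-free samples,
  normal approximation with tie correction otherwise).

### A caveat on the heterogeneity test

The correlation "samples" are not independent: two pairs sharing a cell
are positively dependent through that cell's realized expression, and all
pairwise correlations share the gene-mean direction of expression data.
The rank-sum test assumes independent samples, so the comparison is
**anticonservative**: on a homogeneous population split into two random
"regions", the measured rejection rate at α = 0.05 is ≈ 0.07–0.10 at 60
cells/300 genes and grows (0.15–0.33) when strong per-cell biological
variability is present. P-values from this procedure should be read as
rough evidence ordering, not calibrated error rates; the acceptance suite
measures and reports this inflation rather than hiding it.

## Synthetic data

The generator emulates what the pipeline assumes and nothing more:

* Counts are gamma-Poisson (negative binomial), variance μ + μ²·d, with
  per-gene baseline abundances (lognormal, σ = 1.5), per-cell library-size
  factors (lognormal, σ = 0.3, unit mean) around `mean_library_size`
  (default 100,000 UMIs), and dispersion d = 0.1.
* K clusters carry disjoint marker blocks (default 25 genes/cluster,
  `marker_fold` = 8). 25 is the realistic scale of a cell-type program and
  keeps a valid planted split above the `min_deg = 10` acceptance floor.
* Planted overdispersed genes receive a mean-preserving per-cell lognormal
  factor adding `hvg_bio_cv2` (default 0.5) of squared biological CV —
  about a tenfold count-variance inflation for a typically expressed gene
  at the default dispersion.
* Regions differ **only** in cluster mixing proportions; no region-specific
  genes exist by default, so regional statistics can build explicit nulls.
* Low-quality cells get a library below 20,000 UMIs and/or a mapping ratio
  below 0.2 (both QC criteria exercised); healthy cells sit safely on the
  passing side of every threshold, so QC recovery can be checked exactly.
* Tagged reads assign each molecule a random UMI (length 8) and re-emit
  duplicates with a geometric copy count at rate `umi_dup_rate`; collisions
  occur naturally.

What it does **not** model: sequencing errors in barcodes or UMIs, ambient
RNA, doublets, batch effects, gene–gene correlation structure beyond the
planted blocks, or realistic gene-length/GC biases. Passing recovery tests
therefore demonstrates algorithmic correctness under the stated generative
model, not robustness to every artifact of real libraries.

## Problem sizes and determinism

Recovery benchmarks: K = 5 × 120 cells × 2,000 genes (10 seeds) for
clustering; 100 planted among 1,000 genes × 300 cells (10 seeds) for HVGs;
1,000 replicates of 60 cells × 300 genes for the null rejection rate;
10⁴+ reads for dedup. All randomness flows from explicit integer seeds
(NumPy `SeedSequence`, scikit-learn `random_state`), and the end-to-end
pipeline writes byte-identical files when re-run with the same
configuration and seed.
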