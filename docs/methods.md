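# Methods

This note documents the models, parameter choices and known limits of the
shellstrata pipeline. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The classification model

The unit of inference is the **orthogroup presence pattern**: a boolean
vector over the leaves of a rooted species tree with uniquely labeled
internal nodes. A pattern containing the focal species is mapped to a
stratum as follows. Let `M` be the MRCA of the present leaves.

* **strict** (default): the pattern is assigned `M`'s label iff *every*
  leaf under `M` is present; otherwise `SCATTERED`. The rationale is that
  a family attributed to a node should be observed throughout that node's
  descendants; incomplete clades are indistinguishable (without a loss
  model) from diffuse patterns.
* **relaxed**: assigned `M` iff `|present| / |leaves under M| ≥
  coverage_threshold` (default 0.7). This tolerates genuine gene loss and
  annotation gaps at the cost of over-attributing deep nodes.

Presence restricted to the focal leaf — or membership in no orthogroup, or
in an orthogroup whose members are all focal-species genes — is
`LINEAGE_SPECIFIC`. Strict assignments are stable under relaxation (a
complete clade has coverage 1), and the strict rule is provably equivalent
to exhaustively scanning all clades for an exact leaf-set match; the suite
verifies this equivalence against an independent brute-force oracle on
every rooted binary tree shape with ≤ 8 leaves and every presence vector.

`SCATTERED` is an operational, not biological, category: it means "fails
the completeness/coverage test at its MRCA", nothing more.

**Denominators.** Summaries report percentages over genes and over
orthogroups side by side, because the two disagree whenever orthogroups
hold several focal genes. Genes in focal-only orthogroups count as
*not* in orthogroups: "in orthogroups" means shared beyond the focal
lineage. Rounding follows a configurable precision rule
(default: ≥ 10% to the integer, below to one decimal; a `fine` rule prints
two decimals under 3%); unrounded values are always emitted alongside.

## Marker detection

Counts are normalized per cell to `ln(1 + count / cell_total × 10⁴)`
(zero-count cells dropped with a warning). For each cluster (one-vs-rest),
each gene gets a two-sided Wilcoxon rank-sum test on normalized values,
using the normal approximation with tie correction and a 0.5 continuity
correction — the exact test is reserved for the unit-test oracle, where
group sizes ≤ 8 are enumerated in full. Fold change is
`log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))` (pseudocount 1 on
the expm1 scale; natural-log mode available). Benjamini–Hochberg correction
runs over all tests performed. Records are kept when detected in ≥
`min_pct` of cells in at least one of the two groups (the conventional
reading; a stricter both-groups mode is available), fold change >
`logfc_threshold`, and adjusted p < `alpha`. Defaults: 0.1 / 0.6 / 0.05,
the values used for the shell-field gene set. The source analysis does not
state the fold-change log base, the number of PCs, k, or the community
algorithm; log₂, 20 PCs, k = 20 and label propagation are recorded here as
configurable defaults, not inferred intent.

Clustering, when labels are not supplied, is: PCA (all genes; variable-
feature selection is deliberately collapsed into PCA, since the upstream
recipe is not the contribution), Euclidean kNN, shared-nearest-neighbor
Jaccard weights over self-inclusive neighbor sets, then weighted label
propagation with seeded sweep order and ties broken toward the smaller
label, relabeled by decreasing cluster size.

## Orthology at desk scale

The full orthology stack (DIAMOND, MAFFT/FastTree gene trees,
reconciliation-based ortholog/paralog splitting) is **not** reimplemented.
Every downstream statistic consumes orthogroup-level presence/absence
only, so the package infers orthogroups as connected components (or
MCL-lite: expansion 2, inflation 2, ≤ 100 iterations) of a shared-k-mer
similarity graph: score = number of distinct shared k-mers (k = 5),
normalized by the smaller distinct-k-mer count (this denominator makes
identical sequences score exactly 1 even with internal k-mer repeats).
Candidate pairs come from an inverted k-mer index, which is exactly
equivalent to all-vs-all scoring (pairs sharing no k-mer score 0) but
near-linear in practice. Default acceptance threshold 0.2 normalized
score. Genes with no retained edge become single-member orthogroups
flagged `unassigned`, so orthogroup membership always partitions the gene
universe. For real data, the standard `Orthogroups.tsv` layout is the
fidelity path and round-trips losslessly.

Best-hit annotation from 12-column BLAST tables defaults to the lowest
(most significant) E-value, with ties broken by higher bitscore then
subject ID; a literal `highest_evalue` mode exists because the source
phrasing ("hit with the highest E-value") is ambiguous and is almost
certainly intended as "most significant".

## Synthetic data generator

The generator produces the statistical structure the analysis assumes —
not biologically realistic data.

* **Families.** Each family is born at a tree node drawn from
  `origination_weights` and lost independently on each branch below with
  probability `loss_prob` (per-branch Bernoulli, not continuous-time
  rates: the simplest model with closed-form leaf-presence probabilities
  for testing). All-lost families are redrawn with the same birth node,
  i.e. the process conditions on survival so `n_families` is exact; tests
  against closed forms use the conditional expectation accordingly.
  Within-species paralog counts are 1 + Poisson(`paralog_rate`).
  Defaults: 500 families, weights spread over the eight reporting strata,
  loss 0.15, paralog rate 0.2.
* **Sequences.** One uniform-random length-120 protein per family at its
  birth node; per-site substitution with probability 0.03 per branch to a
  uniform other residue (a 20-state symmetric chain whose two-leaf
  identity has a closed form via the transition-matrix eigenvalue, used
  as the test oracle). Sequence realism is deliberately not load-bearing;
  at these settings within-family similarity is far above the orthogroup
  threshold and between-family similarity far below it.
* **Single cells.** i.i.d. negative-binomial baseline (mean 1.0,
  dispersion 2.0 — sparse, droplet-like detection ~0.4); a planted marker
  with effect `e` and expressed fraction `f` has its target-cluster
  counts redrawn at mean `2^e ×` baseline and gated so the detected
  fraction is `f` (zero effect is the identity, so null markers are
  byte-identical to baseline). Defaults plant 25 markers at log₂FC 1.5,
  f = 0.8 in cluster 0 ("shell field"). Planting many markers in one
  cluster shifts library sizes and visibly compresses fold changes —
  a real composition effect that the defaults keep small by planting
  markers in ≤ 10% of genes.
* **Time course.** Per-gene Gaussian bump over ordered stages (width 1.5
  stages, floor 1.0) scaled by effective length, with multiplicative
  lognormal noise of coefficient of variation `noise_cv` (mean-one
  parameterization).

What passing tests show: the statistics are implemented correctly and the
pipeline recovers planted truth under its own generative assumptions. What
they do not show: robustness to ambient RNA, doublets, UMI saturation,
codon-level evolution, domain shuffling, or real orthology ambiguity.

## Numerical and bookkeeping choices

* One global seed is split with `numpy.random.SeedSequence` into
  independent per-stage streams; identical configs give byte-identical
  report bundles.
* Wilcoxon variance uses the tied-rank correction
  `n1 n2/12 · ((n+1) − Σ(t³−t)/(n(n−1)))`; zero-variance genes get z = 0,
  p = 1.
* PCA uses the deterministic sign convention of scikit-learn's `svd_flip`.
* Cluster labels from label propagation are renumbered by decreasing size,
  ties by smallest member index.
* TPM of an all-zero count vector is all zeros, not NaN.
* 3′ extension may create overlaps with downstream genes; they are left in
  place (the source procedure does not resolve them).
* The TM scan merges every window with mean Kyte–Doolittle hydropathy
  ≥ 1.6 (window 19, the classical setting) into maximal segments;
  sequences shorter than the window report the full-sequence mean.
  The signal-peptide rule requires a K/R in the first 5 residues and a
  ≥ 6-residue hydrophobic core starting after position 1 within the first
  30. Both are labeled heuristics; parsed predictor outputs take
  precedence for real data (`provenance` column).

## Problem sizes

The default test and acceptance runs use 300–500 families on the 31-leaf
fixture tree, 300–500 genes × 300–600 cells, and 20 simulation seeds for
the power/error measurements — sizes at which every headline quantity is
stable to the reported precision while the whole suite completes in well
under a minute of compute per stage.

## Known limitations

* Orthogroup inference is k-mer based and untested beyond the low
  divergences the simulator produces; real proteomes should come in
  through `Orthogroups.tsv`.
* No gene-tree reconciliation: within-orthogroup ortholog/paralog
  structure is invisible, which the classification does not need but
  downstream users might expect.
* The strict/relaxed dichotomy brackets, but does not resolve, the
  underdetermined completeness criterion of the original node scheme; both
  are first-class and reported side by side.
* The published-count reproduction uses the printed per-stratum totals as
  input (the 31-genome dataset itself is not redistributable); two
  unprinted cells of that table are reconciled from the printed totals and
  flagged in the packaged TSV.
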