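# Methods

This note documents the statistical model, the numerical conventions, and the
default parameters of every stage, including where defaults come from and
what was deliberately left out.

## 1. Mutation score matrix

**Inputs.** Per-patient variant calls (VCF), a variant annotation table
(CADD raw deleteriousness score and dbSNP minor allele frequency per
chrom/pos/ref/alt), and a clinical table (patient, AJCC stage).

**Filter cascade.** A variant contributes to the matrix iff it is
(1) a single-nucleotide variant, (2) somatic, (3) nonsynonymous
(stop-gain/loss optionally included via `include_stop`), (4) in a coding
region, and (5) rare: dbSNP MAF strictly below `maf_threshold` (default
0.05), with variants absent from dbSNP treated as rare. Variants lacking an
annotation record are dropped by default (`on_missing_annotation="drop"`) or
rejected (`"error"`). Every stage of the cascade is counted in a filter
audit that the pipeline logs and stores.

**Scores.** CADD raw scores can be negative; all passing scores are shifted
by a single cohort-wide constant `offset = max(0, −min(score))` so the matrix
is non-negative as NMF requires. The matrix entry (gene g, patient p) is the
sum of shifted scores of passing variants of g in p; patients with no passing
variants in g contribute exact zeros (real cohorts of this kind are ~96%
zeros). The applied offset is recorded in `score_meta.json` and the run
manifest. Genes with no mutation in any patient are dropped before
clustering.

## 2. Gene selection

Genes are ranked by sample variance (ddof = 1) of their row across patients,
ties broken lexicographically by gene name for determinism. The scan takes
the top-N genes for each N in `gene_grid`.

## 3. NMF and consensus clustering

**Objective.** Generalized Kullback–Leibler divergence
D(A‖WH) = Σ (a·log(a/âh) − a + âh), with the convention 0·log 0 = 0 and an
ε = 1e−12 floor inside logs and denominators.

**Updates.** Multiplicative updates, W first, then H using the updated W.
Both factors are initialized i.i.d. uniform on (ε, max(A)]. Each update is
provably non-increasing in the divergence; the run aborts with
`FloatingPointError` if any entry becomes non-finite.

**Convergence.** Patients are assigned to the metagene with the largest
coefficient in their column of H (argmax, 1-based; an all-zero column maps to
cluster 1 and triggers a warning). Every `check_interval = 10` iterations the
patient connectivity matrix is compared to its previous value; the run stops
when it is unchanged for `stop_window = 40` consecutive checks, or at
`max_iter = 2000`.

**Consensus.** For each (N, k) grid cell, `runs_per_cell` randomly
initialized runs (default 100) are averaged into a consensus matrix whose
entries estimate co-clustering probability. Final labels come from
average-linkage hierarchical clustering of the dissimilarity 1 − consensus,
cut at k clusters.

**Model selection.** Silhouette width on 1 − consensus:
s(i) = (b(i) − a(i)) / max(a(i), b(i)), with s(i) = 0 when a(i) = b(i) and
for singleton clusters. The grid cell with the highest average silhouette
wins; ties prefer smaller k, then smaller N. Cell seeds are derived as
`SeedSequence([seed, n_top, k, run])`, so results are invariant to grid
enumeration order.

## 4. Subgroup characterization

**Stage enrichment.** Stages I–II are dichotomized as early, III–IV as late;
patients with unknown stage are excluded (and counted). The cluster × {early,
late} table is tested with the Freeman–Halton exact test: all tables with the
observed margins are enumerated in log space, and the two-sided p-value sums
the multivariate hypergeometric probabilities of every table at most as
probable as the observed one (relative tolerance 1e−7, matching standard
implementations). The implementation agrees with R's `fisher.test` on r×2
tables and with `scipy.stats.fisher_exact` on 2×2 tables.

**Differential mutation.** Between the most early-enriched and most
late-enriched clusters (largest vs smallest early:late ratio), each gene is
tested with the two-sided Wilcoxon rank-sum test — exact null when the
smaller group has ≤ 25 patients and the pooled scores are tie-free, otherwise
the normal approximation with midranks, tie correction and continuity
correction. P-values are adjusted by Benjamini–Hochberg step-up; genes with
FDR < `fdr_threshold` (default 0.1) are flagged significant.

## 5. Classification

**Feature selection.** Information gain with Fayyad–Irani MDL supervised
discretization: binary splits are accepted recursively only when the gain
exceeds `(log2(n−1) + log2(3^c − 2) − (c·H − c1·H1 − c2·H2)) / n`; features
never passing the criterion score 0. The top `k_top_features` genes are
selected **inside each training fold only** — a leaked-feature canary test
asserts this by construction.

**Evaluation.** Stratified k-fold cross-validation (default 10 folds,
reduced with a warning when the smallest class is smaller). The default
classifier is a random forest (100 trees) behind a pluggable
fit/predict/predict_proba factory. Reported: pooled confusion matrix,
per-class one-vs-rest TPR/FPR/precision/F1/ROC/AUC, macro averages, and
per-fold accuracies (overall accuracy equals their fold-size-weighted mean).

**Permutation null.** The entire procedure (including per-fold feature
selection) is re-run on `permutations` label-shuffled copies (class sizes
fixed). p = (#permutations with strictly greater accuracy)/N; when the count
is 0 the p-value is reported as the bound "< 1/N".

## 6. Synthetic cohort generator

`SyntheticConfig` plants `n_clusters` disjoint signatures of
`signature_genes_per_cluster` genes each. A patient hits each gene of their
own cluster's signature with probability `signature_hit_prob` and any other
gene with a background probability derived to make the expected matrix
sparsity equal `background_sparsity` (default 0.96, the regime of real
cohorts). Hit counts get Poisson(`extra_variants_lambda`) extra co-occurring
variants; raw scores are `min_raw_score + Gamma(shape, scale)`, so a negative
tail exercises the shift. Stage labels follow per-cluster early:late odds
log-spaced from 5.0 to 0.4 across clusters; a small `unknown_stage_prob`
plants stage-unknown patients. `generate_variant_records` emits the exact
same true variants as VCF-level records plus decoys (germline, synonymous,
non-coding, common-MAF) that the filter cascade must remove; feeding them
through the scoring stage reproduces the cohort matrix bit for bit.

Draws use independent `SeedSequence` substreams per concern (events, scores,
stages, annotations, decoys), so e.g. enlarging the gene universe does not
perturb stage labels.

**Calibrated defaults.** Two generator defaults are calibrated effect sizes,
fixed before the test suite was finalized and not tuned afterwards:

- `signature_hit_prob = 0.6`: with the weaker 0.4 the planted structure is
  genuinely ambiguous (consensus ARI ≈ 0.7); 0.6 gives a strong-signal
  cohort (scan ARI ≥ 0.95, silhouette ≈ 0.95) appropriate for validation
  fixtures whose point is recovery, not difficulty.
- early:late odds `5.0 → 0.4` (log-spaced): chosen so the exact test detects
  the planted stage gradient with power ≥ 0.95 at the default cohort size
  (measured 0.99 over 100 seeds); the weaker 4.0 → 0.5 gradient had power
  0.90.

**Known limits of realism.** Gene-level hit probabilities are independent
given cluster membership (no mutual exclusivity, no gene length effects);
scores are i.i.d. Gamma rather than CADD-like; per-patient mutation burden
has no hypermutator tail. These simplifications are intentional: the
generator validates the machinery, it does not simulate tumor biology.

## 7. Reproducibility

One master seed drives everything. The pipeline derives stage seeds by
SHA-256 of `"{seed}:{stage}"` (mod 2³¹); the model scan derives cell seeds
from `SeedSequence([seed, n_top, k, run])`; classification derives fold and
permutation streams from dedicated `SeedSequence` keys. All intermediates are
plain TSV/JSON, and `manifest.json` records the config, stage seeds, the
score offset and SHA-256 checksums of every artifact; two runs with the same
config produce identical manifests, and running the subcommands one by one
reproduces `run-all` bit for bit.

## 8. Problem sizes and runtimes (single CPU)

- Unit + property test suite: ~35 s (143 tests).
- Acceptance suite (`tests/test_acceptance.py`): ~40 s, dominated by the
  planted-cohort model scan (200 × 90, 20 runs/cell, k ∈ 2..5, ~4 s) and the
  N = 200 permutation test (~35 s).
- README worked example (full pipeline incl. 200 permutations): ~2 min.

## 9. Non-goals

Hyperparameter tuning, alternative classifiers beyond the pluggable factory,
figure generation, workflow-engine integration, and reproduction of results
that require a specific private cohort.
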