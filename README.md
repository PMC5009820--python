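# mutclust

Somatic-mutation burden subgrouping for tumor cohorts: build a gene × patient
deleteriousness-score matrix from filtered somatic variants, discover patient
subgroups with consensus non-negative matrix factorization (NMF), test the
subgroups for clinical-stage enrichment and differentially mutated genes, and
quantify how predictable the subgroups are with cross-validated
classification against a permutation null.

## Method in brief

1. **Scoring** (`mutclust.scoring`) — variant calls are filtered to somatic,
   single-nucleotide, nonsynonymous, coding-region variants with dbSNP minor
   allele frequency below 0.05 (or absent from dbSNP). Each surviving variant
   carries a precomputed CADD raw deleteriousness score; scores are shifted by
   a constant so the minimum is zero, then summed per gene per patient into
   the **mutation score matrix**.
2. **Gene selection** (`mutclust.features`) — genes are ranked by variance of
   their score across patients; the top-N most variable genes feed clustering.
3. **Clustering** (`mutclust.nmf`, `mutclust.consensus`) — KL-divergence NMF
   with multiplicative updates, run to connectivity-matrix convergence from
   many random initializations. Runs are averaged into a **consensus matrix**;
   the silhouette width on the dissimilarity `1 − consensus` selects the rank
   k and gene-count N, and average-linkage clustering of the consensus matrix
   yields the final patient assignments.
4. **Characterization** (`mutclust.characterize`) — tumor stages are
   dichotomized (I–II early, III–IV late; unknown excluded) and tested for
   association with cluster membership by an exact r×2 contingency test
   (Freeman–Halton). Genes differing between the most early- and most
   late-enriched clusters are found by per-gene Wilcoxon rank-sum tests with
   Benjamini–Hochberg FDR control.
5. **Classification** (`mutclust.classify`) — a random-forest classifier over
   genes selected by information gain (Fayyad–Irani MDL discretization,
   selection inside each training fold only) is evaluated with stratified
   k-fold cross-validation; significance is assessed by re-running the whole
   procedure on label-shuffled data.

A synthetic-cohort generator (`mutclust.synthetic`) plants known clusters,
gene signatures, and stage-enrichment effects so the full pipeline can be
validated end to end without patient data.

## Worked example

Run the full pipeline on a simulated 200-gene × 90-patient cohort with three
planted clusters:

```bash
cat > example.yaml <<'EOF'
outdir: example_out
seed: 11
synthetic:
  n_genes: 200
  n_patients: 90
  n_clusters: 3
gene_grid: [50]
k_grid: [2, 3, 4, 5]
runs_per_cell: 20
folds: 5
k_top_features: 25
n_estimators: 50
permutations: 200
EOF
mutclust run-all --config example.yaml
```

This takes about two minutes on one CPU and writes plain-text artifacts plus
a `manifest.json` with SHA-256 checksums (two runs with the same config
produce identical manifests). Key results from this exact run:

```
$ cat example_out/silhouette.json
{
  "selected_n_top": 50,
  "selected_k": 3,
  "silhouette": 0.9530500901359946,
  "runs_per_cell": 20
}

$ cat example_out/enrichment.json
{
  "enrichment_p_value": 0.0011133218976895566,
  "excluded_unknown": 1,
  "early_enriched_cluster": 1,
  "late_enriched_cluster": 3,
  "n_significant_genes": 20,
  "fdr_threshold": 0.1
}

$ cat example_out/stage_by_cluster.tsv
cluster	n_patients	n_early	n_late	ratio
1	29	23	6	3.8333333333333335
2	29	15	14	1.0714285714285714
3	32	10	21	0.47619047619047616

$ cat example_out/permutation.json
{
  "observed_accuracy": 0.9555555555555556,
  "count_better": 0,
  "n_permutations": 200,
  "p_value": 0.0,
  "p_reported": "< 0.005"
}
```

The scan selects k = 3 (the planted number of clusters), the exact test
detects the planted early/late stage gradient across clusters, and the
classifier predicts cluster membership far better than any of 200
label-shuffled runs.

The same analysis from Python:

```python
from mutclust import (SyntheticConfig, generate_cohort, scan_models,
                      stage_by_cluster, stage_enrichment_exact)

cohort = generate_cohort(SyntheticConfig(seed=11))
matrix = cohort.score_matrix.drop_empty_genes()
scan = scan_models(matrix, gene_grid=[50], k_grid=[2, 3, 4, 5],
                   runs_per_cell=20, seed=11)
labels = scan.assignments()                      # patient -> cluster (1-based)
table = stage_by_cluster(labels, cohort.stage_table)
print(scan.selected_k, stage_enrichment_exact(table))
```

Real cohorts enter through the same pipeline with `vcf_dir` (one VCF per
patient), `annotation` (TSV: chrom, pos, ref, alt, cadd_raw, dbsnp_maf) and
`clinical` (TSV: patient_id, stage) instead of the `synthetic` section; the
run then starts at the `score` stage.

## Subcommands

`mutclust simulate | score | cluster | characterize | classify | run-all`,
each taking `--config <yaml> [--seed N] [--outdir DIR]`. Stages communicate
through TSV/JSON files in the output directory, so running them one at a time
reproduces `run-all` bit for bit.

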