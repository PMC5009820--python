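"""End-to-end orchestration: simulate|score -> cluster -> characterize -> classify.

Each stage is a plain function that reads its inputs from files and
writes plain-text artifacts (TSV/JSON), so running the stages one by one
reproduces a monolithic run bit for bit. ``run_full`` sequences the
stages and writes a manifest with input checksums, seeds and the applied
score offset; two runs with the same config produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mutclust import io as mio
from mutclust import __version__
from mutclust.characterize import differential_mutation, stage_by_cluster, stage_enrichment_exact
from mutclust.classify import (
    LabeledDataset,
    cross_validate,
    default_classifier_factory,
    permutation_test,
)
from mutclust.consensus import scan_models
from mutclust.features import rank_by_variance
from mutclust.scoring import score_pipeline
from mutclust.synthetic import SyntheticConfig, generate_cohort, generate_variant_records

logger = logging.getLogger(__name__)


def _derived_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Single configuration object for the whole analysis.

    Either ``synthetic`` (keyword arguments for
    :class:`~mutclust.synthetic.SyntheticConfig`, seed filled from the
    master seed when absent) or the three real-data inputs
    (``vcf_dir``, ``annotation``, ``clinical``) must be provided.
    """

    outdir: str = "mutclust_out"
    seed: int = 0
    synthetic: dict | None = None
    vcf_dir: str | None = None
    annotation: str | None = None
    clinical: str | None = None
    maf_threshold: float = 0.05
    include_stop: bool = False
    gene_grid: list[int] = field(default_factory=lambda: [10, 25, 50, 100, 250, 500, 1000])
    k_grid: list[int] = field(default_factory=lambda: list(range(2, 11)))
    runs_per_cell: int = 100
    fdr_threshold: float = 0.1
    folds: int = 10
    k_top_features: int = 500
    n_estimators: int = 100
    permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def synthetic_config(self) -> SyntheticConfig:
        if self.synthetic is None:
            raise ValueError("config has no synthetic section")
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", _derived_seed(self.seed, "simulate"))
        return SyntheticConfig(**kwargs)

    def out(self) -> Path:
        path = Path(self.outdir)
        path.mkdir(parents=True, exist_ok=True)
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Draw a synthetic cohort and write matrix, clinical, truth, VCFs, annotations."""
    syn = config.synthetic_config()
    out = config.out()
    cohort = generate_cohort(syn)
    paths = cohort.write(out)
    records, annotations = generate_variant_records(syn)
    vcf_paths = mio.write_cohort_vcfs(records, out / "vcf", patients=cohort.score_matrix.patients)
    mio.write_annotation_tsv(annotations, out / "annotations.tsv")
    paths.update({"vcf_dir": out / "vcf", "annotation": out / "annotations.tsv"})
    logger.info("simulated cohort: %d VCFs, %.1f%% zeros", len(vcf_paths),
                100 * cohort.score_matrix.zero_fraction)
    return paths


def stage_score(config: PipelineConfig) -> dict[str, Path]:
    """Filter variant records and build the mutation score matrix."""
    out = config.out()
    if config.synthetic is not None:
        vcf_dir = out / "vcf"
        annotation_path = out / "annotations.tsv"
        clinical_path = out / "clinical.tsv"
    else:
        if not (config.vcf_dir and config.annotation and config.clinical):
            raise ValueError("real-data run needs vcf_dir, annotation and clinical paths")
        vcf_dir, annotation_path, clinical_path = (
            Path(config.vcf_dir), Path(config.annotation), Path(config.clinical)
        )
    records = mio.read_cohort_vcfs(vcf_dir.glob("*.vcf"))
    annotations = mio.read_annotation_tsv(annotation_path)
    patients = sorted(p.stem for p in vcf_dir.glob("*.vcf"))
    result = score_pipeline(
        records, annotations,
        maf_threshold=config.maf_threshold, include_stop=config.include_stop,
        patients=patients,
    )
    matrix = result.matrix.drop_empty_genes()
    mio.write_matrix_tsv(matrix, out / "matrix.tsv")
    if clinical_path != out / "clinical.tsv":
        mio.write_clinical_tsv(mio.read_clinical_tsv(clinical_path), out / "clinical.tsv")
    mio.write_json(
        {
            "score_offset": result.offset,
            "zero_fraction": matrix.zero_fraction,
            "filter_audit": result.audit.as_dict(),
        },
        out / "score_meta.json",
    )
    return {"matrix": out / "matrix.tsv", "score_meta": out / "score_meta.json"}


def stage_cluster(config: PipelineConfig) -> dict[str, Path]:
    """Variance ranking, model scan, consensus clustering, final assignments."""
    out = config.out()
    matrix = mio.read_matrix_tsv(out / "matrix.tsv").drop_empty_genes()
    ranking = rank_by_variance(matrix)
    ranking.to_csv(out / "variance_ranking.tsv", sep="\t", index=False)

    m = matrix.shape[0]
    gene_grid = sorted({g for g in config.gene_grid if g <= m}) or [m]
    k_grid = [k for k in config.k_grid if k < matrix.shape[1]]
    scan = scan_models(
        matrix, gene_grid, k_grid,
        runs_per_cell=config.runs_per_cell, seed=_derived_seed(config.seed, "cluster"),
    )
    scan.grid.to_csv(out / "scan_grid.tsv", sep="\t", index=False)
    pd.DataFrame(
        scan.selected_consensus.matrix, index=matrix.patients, columns=matrix.patients
    ).to_csv(out / "consensus.tsv", sep="\t", index_label="patient_id")
    mio.write_json(
        {
            "selected_n_top": scan.selected_n_top,
            "selected_k": scan.selected_k,
            "silhouette": scan.selected_silhouette,
            "runs_per_cell": config.runs_per_cell,
        },
        out / "silhouette.json",
    )
    mio.write_assignments_tsv(scan.assignments(), out / "assignments.tsv")
    return {
        "assignments": out / "assignments.tsv",
        "scan_grid": out / "scan_grid.tsv",
        "consensus": out / "consensus.tsv",
        "silhouette": out / "silhouette.json",
    }


def stage_characterize(config: PipelineConfig) -> dict[str, Path]:
    """Stage-by-cluster table, exact enrichment test, differential genes."""
    out = config.out()
    assignments = mio.read_assignments_tsv(out / "assignments.tsv")
    stages = mio.read_clinical_tsv(out / "clinical.tsv")
    matrix = mio.read_matrix_tsv(out / "matrix.tsv")

    table = stage_by_cluster(assignments, stages)
    table.table.to_csv(out / "stage_by_cluster.tsv", sep="\t")
    p_value = stage_enrichment_exact(table)

    # Differentially mutated genes between the most early- and most
    # late-enriched clusters (largest vs smallest early:late ratio).
    ratios = table.table["ratio"].dropna()
    if len(ratios) >= 2:
        early_cluster = ratios.idxmax()
        late_cluster = ratios.idxmin()
    else:  # fall back to the first two clusters when ratios degenerate
        early_cluster, late_cluster = table.table.index[:2]
    group_early = assignments.index[assignments == early_cluster].tolist()
    group_late = assignments.index[assignments == late_cluster].tolist()
    diff = differential_mutation(
        matrix, group_late, group_early, fdr_threshold=config.fdr_threshold
    ).rename(columns={"mean_a": "mean_late_cluster", "mean_b": "mean_early_cluster"})
    diff.to_csv(out / "differential_genes.tsv", sep="\t", index=False)

    mio.write_json(
        {
            "enrichment_p_value": p_value,
            "excluded_unknown": table.excluded_unknown,
            "early_enriched_cluster": int(early_cluster),
            "late_enriched_cluster": int(late_cluster),
            "n_significant_genes": int(diff["significant"].sum()),
            "fdr_threshold": config.fdr_threshold,
        },
        out / "enrichment.json",
    )
    return {
        "stage_table": out / "stage_by_cluster.tsv",
        "enrichment": out / "enrichment.json",
        "differential": out / "differential_genes.tsv",
    }


def stage_classify(config: PipelineConfig) -> dict[str, Path]:
    """Cross-validated cluster prediction plus the permutation null."""
    out = config.out()
    matrix = mio.read_matrix_tsv(out / "matrix.tsv")
    assignments = mio.read_assignments_tsv(out / "assignments.tsv")
    dataset = LabeledDataset(X=matrix.data.T, y=assignments)
    factory = default_classifier_factory(config.n_estimators)
    seed = _derived_seed(config.seed, "classify")

    report = cross_validate(
        dataset, factory, folds=config.folds, k_top=config.k_top_features, seed=seed
    )
    mio.write_json(report.to_dict(), out / "classification_report.json")
    roc_rows = []
    for cls, (fpr, tpr) in report.roc_curves.items():
        for f, t in zip(fpr, tpr):
            roc_rows.append({"class": cls, "fpr": f, "tpr": t})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.tsv", sep="\t", index=False)

    paths = {"report": out / "classification_report.json", "roc": out / "roc_points.tsv"}
    if config.permutations > 0:
        perm = permutation_test(
            dataset, factory, n_permutations=config.permutations, seed=seed,
            folds=config.folds, k_top=config.k_top_features,
        )
        pd.DataFrame({"accuracy": perm.permutation_accuracies}).to_csv(
            out / "permutation_trace.tsv", sep="\t", index=False
        )
        mio.write_json(
            {
                "observed_accuracy": perm.observed_accuracy,
                "count_better": perm.count_better,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value,
                "p_reported": perm.p_label,
            },
            out / "permutation.json",
        )
        paths.update({
            "permutation": out / "permutation.json",
            "permutation_trace": out / "permutation_trace.tsv",
        })
    return paths


_STAGES = ("simulate", "score", "cluster", "characterize", "classify")


def run_full(config: PipelineConfig) -> dict:
    """Run every stage in order and write the run manifest.

    Synthetic configs start at ``simulate``; real-data configs at
    ``score``. A stage failure aborts with the stage name; artifacts of
    completed stages are left in place.
    """
    out = config.out()
    artifacts: dict[str, Path] = {}
    stages = _STAGES if config.synthetic is not None else _STAGES[1:]
    for stage in stages:
        try:
            artifacts.update(globals()[f"stage_{stage}"](config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "mutclust_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _derived_seed(config.seed, s) for s in ("simulate", "cluster", "classify")},
        "config": dataclasses.asdict(config),
        "artifacts": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
            if p.is_file()
        },
    }
    score_meta = out / "score_meta.json"
    if score_meta.exists():
        import json

        manifest["score_offset"] = json.loads(score_meta.read_text())["score_offset"]
    mio.write_json(manifest, out / "manifest.json")
    return manifest
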