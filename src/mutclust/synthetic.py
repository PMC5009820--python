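"""Synthetic sparse mutation-score cohorts with planted cluster structure.

The generator emulates the data regime of a whole-exome somatic-mutation
cohort: a ~96%-zero non-negative gene x patient score matrix with
heavy-tailed per-event C-scores, k planted patient clusters marked by
disjoint sets of cluster-specific signature genes, and clinical stage
labels whose early:late odds differ by cluster. It can also emit the
underlying variant-level records (plus filter-bait decoys) so the
scoring cascade can be exercised end to end: running the scoring
pipeline on the records reproduces the cohort's matrix exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mutclust.scoring import (
    Consequence,
    MutationScoreMatrix,
    Region,
    VariantAnnotation,
    VariantRecord,
    build_matrix,
    shift_scores,
)


class ConfigurationError(ValueError):
    """Raised for invalid synthetic-cohort configurations."""


_STAGES = ("I", "II", "III", "IV")
# Composition within the early/late dichotomy (stage II and III dominate
# their halves in typical breast-cancer cohorts).
_P_STAGE_I_GIVEN_EARLY = 0.35
_P_STAGE_III_GIVEN_LATE = 0.7
_BASES = "ACGT"
# Synthetic genome layout: each gene owns a disjoint coordinate block so
# (chrom, pos, ref, alt) keys are unique across all emitted variants.
_GENE_SPAN = 100_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which a synthetic cohort is drawn.

    Defaults describe a desk-scale analogue of an exome cohort: 200
    genes x 90 patients, 3 planted clusters, a 96% zero-fraction target,
    and gamma-distributed per-event scores whose sums are heavy-tailed.
    ``background_hit_prob=None`` derives the background mutation rate
    from ``background_sparsity`` so the overall expected zero fraction
    hits the target given the signature settings.
    """

    n_genes: int = 200
    n_patients: int = 90
    n_clusters: int = 3
    background_sparsity: float = 0.96
    signature_genes_per_cluster: int = 10
    signature_hit_prob: float = 0.6
    background_hit_prob: float | None = None
    extra_variants_lambda: float = 0.2
    score_shape: float = 1.5
    score_scale: float = 8.0
    min_raw_score: float = -2.0
    early_late_odds: tuple[float, ...] | float | None = None
    unknown_stage_prob: float = 0.015
    maf_present_prob: float = 0.3
    decoy_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_patients < 1:
            raise ConfigurationError("n_genes and n_patients must be positive")
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if self.n_clusters > self.n_patients:
            raise ConfigurationError("n_clusters cannot exceed n_patients")
        if self.signature_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ConfigurationError("signature gene sets (disjoint across clusters) exceed n_genes")
        for name in ("background_sparsity", "signature_hit_prob", "unknown_stage_prob", "maf_present_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.background_hit_prob is not None and not (0.0 <= self.background_hit_prob <= 1.0):
            raise ConfigurationError(f"background_hit_prob must be in [0, 1], got {self.background_hit_prob}")
        if self.score_shape <= 0 or self.score_scale <= 0:
            raise ConfigurationError("gamma score parameters must be positive")
        if self.extra_variants_lambda < 0 or self.decoy_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        odds = self.resolved_odds()
        if len(odds) != self.n_clusters or any(o <= 0 for o in odds):
            raise ConfigurationError("early_late_odds must be positive, one value per cluster")

    def resolved_odds(self) -> tuple[float, ...]:
        """Per-cluster early:late odds; default log-spaced 5.0 down to 0.4
        (an early-enriched cluster, a late-enriched one, mixed between)."""
        if self.early_late_odds is None:
            return tuple(np.exp(np.linspace(math.log(5.0), math.log(0.4), self.n_clusters)))
        if np.isscalar(self.early_late_odds):
            return (float(self.early_late_odds),) * self.n_clusters
        return tuple(float(o) for o in self.early_late_odds)

    def resolved_background_hit_prob(self) -> float:
        """Background per-cell hit probability meeting the sparsity target.

        Expected zero fraction is (1-p_bg)*(1 - f*p_sig) with f the
        fraction of cells that are own-cluster signature cells; solve for
        p_bg so it equals ``background_sparsity``.
        """
        if self.background_hit_prob is not None:
            return self.background_hit_prob
        f = self.signature_genes_per_cluster / self.n_genes
        denom = 1.0 - f * self.signature_hit_prob
        p = 1.0 - self.background_sparsity / denom
        if -1e-9 < p < 0.0:  # float round-off when signatures alone meet the target
            p = 0.0
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(
                "background_sparsity target unattainable with the given signature settings"
            )
        return p


@dataclass
class SyntheticCohort:
    """A drawn cohort: score matrix, planted truth, and stage labels."""

    score_matrix: MutationScoreMatrix
    true_cluster: pd.Series  # patient -> cluster id (1-based)
    stage_table: pd.Series  # patient -> stage in {I, II, III, IV, unknown}
    signature_genes: dict[int, list[str]]
    score_offset: float = 0.0

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write matrix TSV, clinical TSV and truth JSON; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "score_matrix.tsv",
            "clinical": outdir / "clinical.tsv",
            "truth": outdir / "truth.json",
        }
        self.score_matrix.data.to_csv(paths["matrix"], sep="\t", index_label="gene")
        pd.DataFrame(
            {"patient_id": self.stage_table.index, "stage": self.stage_table.values}
        ).to_csv(paths["clinical"], sep="\t", index=False)
        truth = {
            "true_cluster": {p: int(c) for p, c in self.true_cluster.items()},
            "signature_genes": {str(k): v for k, v in self.signature_genes.items()},
            "score_offset": self.score_offset,
        }
        paths["truth"].write_text(json.dumps(truth, indent=2))
        return paths


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _patient_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def _gene_locus(gene_index: int) -> tuple[str, int]:
    """Deterministic synthetic locus for a gene: chromosome and base position."""
    chrom = f"chr{gene_index % 22 + 1}"
    base = (gene_index // 22) * _GENE_SPAN + 1
    return chrom, base


@dataclass
class _Truth:
    """Internal draw shared by generate_cohort and generate_variant_records."""

    records: list[VariantRecord]
    raw_scores: list[float]
    mafs: list[float | None]
    clusters: np.ndarray  # 1-based, per patient
    stages: list[str]
    signature: dict[int, list[str]]
    genes: list[str]
    patients: list[str]


def _draw_truth(config: SyntheticConfig) -> _Truth:
    # Independent substreams per stage of the draw, so e.g. adding genes
    # (events stream) does not perturb the stage labels.
    ss = np.random.SeedSequence(config.seed)
    rng_events, rng_scores, rng_stages, rng_annot = (np.random.default_rng(s) for s in ss.spawn(4))

    genes = _gene_names(config.n_genes)
    patients = _patient_names(config.n_patients)
    k = config.n_clusters

    # Balanced planted clusters, contiguous patient blocks.
    clusters = (np.arange(config.n_patients) * k // config.n_patients) + 1

    signature: dict[int, list[str]] = {}
    for c in range(1, k + 1):
        start = (c - 1) * config.signature_genes_per_cluster
        signature[c] = genes[start : start + config.signature_genes_per_cluster]

    # Per-cell hit probabilities: background everywhere, boosted for a
    # patient's own-cluster signature genes.
    p_bg = config.resolved_background_hit_prob()
    prob = np.full((config.n_genes, config.n_patients), p_bg)
    for c in range(1, k + 1):
        rows = [genes.index(g) for g in signature[c]]
        cols = np.where(clusters == c)[0]
        block = prob[np.ix_(rows, cols)]
        prob[np.ix_(rows, cols)] = 1.0 - (1.0 - block) * (1.0 - config.signature_hit_prob)

    hits = rng_events.random(prob.shape) < prob
    gi, pi = np.nonzero(hits)  # row-major: gene-by-gene, patients within gene
    n_cells = gi.size
    multiplicity = 1 + rng_events.poisson(config.extra_variants_lambda, size=n_cells)

    records: list[VariantRecord] = []
    raw_scores: list[float] = []
    mafs: list[float | None] = []
    pos_counter = np.zeros(config.n_genes, dtype=int)
    for cell in range(n_cells):
        g, p = int(gi[cell]), int(pi[cell])
        chrom, base = _gene_locus(g)
        for _ in range(int(multiplicity[cell])):
            pos = base + int(pos_counter[g])
            pos_counter[g] += 1
            ref, alt = rng_scores.choice(list(_BASES), size=2, replace=False)
            raw = config.min_raw_score + rng_scores.gamma(config.score_shape, config.score_scale)
            maf = float(rng_annot.uniform(0.0, 0.049)) if rng_annot.random() < config.maf_present_prob else None
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=str(ref),
                    alt=str(alt),
                    patient_id=patients[p],
                    somatic=True,
                    consequence=Consequence.NONSYNONYMOUS,
                    region=Region.CODING,
                    gene=genes[g],
                )
            )
            raw_scores.append(float(raw))
            mafs.append(maf)

    # Stage labels conditioned on cluster: Bernoulli(early) with odds per
    # cluster, then a realistic split within the early/late halves.
    odds = config.resolved_odds()
    stages: list[str] = []
    for p in range(config.n_patients):
        if rng_stages.random() < config.unknown_stage_prob:
            stages.append("unknown")
            continue
        o = odds[clusters[p] - 1]
        early = rng_stages.random() < o / (1.0 + o)
        if early:
            stages.append("I" if rng_stages.random() < _P_STAGE_I_GIVEN_EARLY else "II")
        else:
            stages.append("III" if rng_stages.random() < _P_STAGE_III_GIVEN_LATE else "IV")

    return _Truth(records, raw_scores, mafs, clusters, stages, signature, genes, patients)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort under ``config``; identical seeds give identical cohorts.

    The score matrix spans the full configured gene universe (genes with
    no mutation appear as all-zero rows; the pipeline drops those before
    clustering, mirroring the "at least one mutation per row" convention
    of real cohorts). Matrix entries are sums of shifted per-event raw
    scores, using exactly the shift the scoring module applies, so
    :func:`generate_variant_records` round-trips exactly.
    """
    truth = _draw_truth(config)
    if truth.records:
        shifted, offset = shift_scores(truth.raw_scores)
    else:
        shifted, offset = np.array([]), 0.0
    matrix = build_matrix(truth.records, shifted, patients=truth.patients, genes=truth.genes)
    return SyntheticCohort(
        score_matrix=matrix,
        true_cluster=pd.Series(truth.clusters, index=truth.patients, name="cluster"),
        stage_table=pd.Series(truth.stages, index=truth.patients, name="stage"),
        signature_genes=truth.signature,
        score_offset=offset,
    )


def generate_variant_records(
    config: SyntheticConfig,
) -> tuple[list[VariantRecord], dict[tuple, VariantAnnotation]]:
    """Emit the cohort's variant-level records plus an annotation lookup.

    Returns the true somatic nonsynonymous coding SNVs underlying
    :func:`generate_cohort` (same seed, same events) followed by decoy
    records that the filter cascade must remove: germline calls,
    synonymous changes, non-coding variants, and common polymorphisms
    (dbSNP MAF >= 0.05). Feeding the output through
    :func:`mutclust.scoring.score_pipeline` with the cohort's gene and
    patient universe reproduces the cohort's score matrix exactly.
    """
    truth = _draw_truth(config)
    rng_decoys = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])

    records = list(truth.records)
    annotations: dict[tuple, VariantAnnotation] = {}
    for rec, raw, maf in zip(truth.records, truth.raw_scores, truth.mafs):
        annotations[rec.key] = VariantAnnotation(cadd_raw=raw, dbsnp_maf=maf)

    pos_counter = {g: _GENE_SPAN // 2 for g in range(config.n_genes)}  # decoy block within each locus
    n_decoys = int(round(config.decoy_rate * len(truth.records)))
    decoy_kinds = ("germline", "synonymous", "noncoding", "common")
    noncoding_regions = (Region.INTRON, Region.UTR, Region.INTERGENIC)
    for d in range(n_decoys):
        kind = decoy_kinds[d % len(decoy_kinds)]
        g = int(rng_decoys.integers(config.n_genes))
        patient = truth.patients[int(rng_decoys.integers(config.n_patients))]
        chrom, base = _gene_locus(g)
        pos = base + pos_counter[g]
        pos_counter[g] += 1
        ref, alt = rng_decoys.choice(list(_BASES), size=2, replace=False)
        somatic, consequence, region, maf = True, Consequence.NONSYNONYMOUS, Region.CODING, None
        if kind == "germline":
            somatic = False
        elif kind == "synonymous":
            consequence = Consequence.SYNONYMOUS
        elif kind == "noncoding":
            region = noncoding_regions[d % len(noncoding_regions)]
        else:  # common polymorphism
            maf = float(rng_decoys.uniform(0.05, 0.5))
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=str(ref),
            alt=str(alt),
            patient_id=patient,
            somatic=somatic,
            consequence=consequence,
            region=region,
            gene=truth.genes[g],
        )
        records.append(rec)
        raw = config.min_raw_score + rng_decoys.gamma(config.score_shape, config.score_scale)
        annotations[rec.key] = VariantAnnotation(cadd_raw=float(raw), dbsnp_maf=maf)

    return records, annotations
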