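"""Variant filtering and construction of the mutation score matrix.

Somatic single-nucleotide variants are pushed through a fixed filter
cascade (somatic -> nonsynonymous -> coding region -> rare in dbSNP),
their CADD raw C-scores are shifted to be non-negative, and the shifted
scores are summed per (gene, patient) into a sparse non-negative matrix
that all downstream clustering and testing consumes.
"""

from __future__ import annotations

import enum
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Consequence(str, enum.Enum):
    """Predicted coding consequence of a variant."""

    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    OTHER = "other"


class Region(str, enum.Enum):
    """Genomic region class of a variant."""

    CODING = "coding"
    INTRON = "intron"
    UTR = "utr"
    INTERGENIC = "intergenic"
    OTHER = "other"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one patient.

    Positions are 1-based as in VCF. ``gene`` is taken from upstream
    annotation, never recomputed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    somatic: bool
    consequence: Consequence
    region: Region
    gene: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in _BASES and self.alt in _BASES


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant annotation: CADD raw C-score and dbSNP minor allele frequency.

    ``cadd_raw`` may be negative (CADD raw scores are unbounded below);
    ``dbsnp_maf`` is ``None`` for variants absent from dbSNP.
    """

    cadd_raw: float
    dbsnp_maf: float | None = None

    def __post_init__(self) -> None:
        if self.dbsnp_maf is not None and not (0.0 <= self.dbsnp_maf <= 0.5):
            raise ValueError(f"dbsnp_maf must be in [0, 0.5], got {self.dbsnp_maf}")


AnnotationLookup = Mapping[tuple[str, int, str, str], VariantAnnotation]


@dataclass
class FilterAudit:
    """Counts of records removed at each stage of the filter cascade."""

    n_input: int = 0
    removed_not_snv: int = 0
    removed_germline: int = 0
    removed_consequence: int = 0
    removed_noncoding: int = 0
    removed_unannotated: int = 0
    removed_common: int = 0
    n_passing: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class FilterResult:
    records: list[VariantRecord]
    audit: FilterAudit

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def filter_variants(
    records: Iterable[VariantRecord],
    annotations: AnnotationLookup,
    maf_threshold: float = 0.05,
    include_stop: bool = False,
    on_missing_annotation: str = "drop",
) -> FilterResult:
    """Apply the somatic/nonsynonymous/coding/rare filter cascade.

    A record is retained iff it is a somatic single-nucleotide variant,
    its consequence is nonsynonymous (or stop-gain/stop-loss when
    ``include_stop``), it lies in a coding region, and its dbSNP minor
    allele frequency is either absent or strictly below ``maf_threshold``
    (common polymorphisms are treated as non-causal). Input order is
    preserved; removal counts per stage are returned in the audit.

    Parameters
    ----------
    on_missing_annotation
        ``"drop"`` (default) removes records with no annotation entry and
        logs a warning; ``"error"`` raises ``KeyError``.
    """
    if on_missing_annotation not in ("drop", "error"):
        raise ValueError(f"unknown missing-annotation policy: {on_missing_annotation!r}")
    allowed = {Consequence.NONSYNONYMOUS}
    if include_stop:
        allowed |= {Consequence.STOP_GAIN, Consequence.STOP_LOSS}

    audit = FilterAudit()
    passing: list[VariantRecord] = []
    for rec in records:
        audit.n_input += 1
        if not rec.is_snv:
            audit.removed_not_snv += 1
            continue
        if not rec.somatic:
            audit.removed_germline += 1
            continue
        if rec.consequence not in allowed:
            audit.removed_consequence += 1
            continue
        if rec.region is not Region.CODING:
            audit.removed_noncoding += 1
            continue
        ann = annotations.get(rec.key)
        if ann is None:
            if on_missing_annotation == "error":
                raise KeyError(f"no annotation for variant {rec.key} (patient {rec.patient_id})")
            logger.warning("dropping unannotated variant %s (patient %s)", rec.key, rec.patient_id)
            audit.removed_unannotated += 1
            continue
        if ann.dbsnp_maf is not None and ann.dbsnp_maf >= maf_threshold:
            audit.removed_common += 1
            continue
        passing.append(rec)
    audit.n_passing = len(passing)
    if audit.removed_not_snv:
        logger.info("dropped %d non-SNV records (only point mutations are scored)", audit.removed_not_snv)
    return FilterResult(passing, audit)


def shift_scores(scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """Shift raw C-scores so the smallest observed value maps to zero.

    NMF requires non-negative input, so each score is translated by the
    magnitude of the dataset minimum. Already non-negative data is left
    untouched (the offset is ``max(0, -min(scores))``). Returns the
    shifted array and the applied offset; the offset is dataset-dependent
    and must be recorded in run metadata for reproducibility.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot shift an empty score list")
    offset = max(0.0, -float(arr.min()))
    return arr + offset, offset


@dataclass
class MutationScoreMatrix:
    """Non-negative gene x patient matrix of summed shifted C-scores.

    Wraps a DataFrame with genes on the index and patient ids as columns;
    entry (i, j) is the sum of shifted C-scores of passing variants of
    gene i in patient j.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if (self.data.values < 0).any():
            raise ValueError("mutation score matrix must be non-negative")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate gene or patient labels")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def patients(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def zero_fraction(self) -> float:
        return float((self.data.values == 0).mean())

    def drop_empty_genes(self) -> "MutationScoreMatrix":
        """Remove genes with no mutation in any patient (all-zero rows)."""
        keep = (self.data.values != 0).any(axis=1)
        return MutationScoreMatrix(self.data.loc[keep])

    def subset_genes(self, genes: Sequence[str]) -> "MutationScoreMatrix":
        return MutationScoreMatrix(self.data.loc[list(genes)])

    def equals(self, other: "MutationScoreMatrix") -> bool:
        return self.data.equals(other.data)


def build_matrix(
    passing: Sequence[VariantRecord],
    shifted_scores: Sequence[float],
    patients: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> MutationScoreMatrix:
    """Sum per-record shifted scores into the gene x patient matrix.

    ``passing`` and ``shifted_scores`` must be aligned one-to-one. By
    default the gene set is exactly the genes with at least one passing
    record (so every row carries a mutation) and the patient set is the
    patients seen in the records; pass ``patients``/``genes`` explicitly
    to force a known cohort universe (patients with no passing variants
    then appear as all-zero columns).
    """
    if len(passing) != len(shifted_scores):
        raise ValueError("records and scores are not aligned one-to-one")
    for rec in passing:
        if not rec.gene:
            raise ValueError(f"record at {rec.key} has no gene symbol")
    scores = np.asarray(shifted_scores, dtype=float)
    if scores.size and scores.min() < 0:
        raise ValueError("shifted scores must be non-negative")

    if genes is None:
        gene_list = sorted({rec.gene for rec in passing})
    else:
        gene_list = list(genes)
    if patients is None:
        patient_list = sorted({rec.patient_id for rec in passing})
    else:
        patient_list = list(patients)

    gidx = {g: i for i, g in enumerate(gene_list)}
    pidx = {p: i for i, p in enumerate(patient_list)}
    values = np.zeros((len(gene_list), len(patient_list)))
    for rec, s in zip(passing, scores):
        try:
            values[gidx[rec.gene], pidx[rec.patient_id]] += s
        except KeyError as exc:
            raise KeyError(f"record {rec.key} references unknown gene or patient: {exc}") from exc
    return MutationScoreMatrix(pd.DataFrame(values, index=gene_list, columns=patient_list))


@dataclass
class ScoreResult:
    """Matrix plus the run metadata the scoring stage must preserve."""

    matrix: MutationScoreMatrix
    offset: float
    audit: FilterAudit
    zero_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.zero_fraction = self.matrix.zero_fraction


def score_pipeline(
    records: Iterable[VariantRecord],
    annotations: AnnotationLookup,
    maf_threshold: float = 0.05,
    include_stop: bool = False,
    on_missing_annotation: str = "drop",
    patients: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> ScoreResult:
    """Filter -> shift -> sum, end to end.

    Convenience wrapper chaining :func:`filter_variants`,
    :func:`shift_scores` on the passing records' raw C-scores, and
    :func:`build_matrix`. When no record passes, the shift offset is 0
    and the matrix is all-zero over the requested universe.
    """
    result = filter_variants(
        records,
        annotations,
        maf_threshold=maf_threshold,
        include_stop=include_stop,
        on_missing_annotation=on_missing_annotation,
    )
    raw = [annotations[rec.key].cadd_raw for rec in result.records]
    if raw:
        shifted, offset = shift_scores(raw)
    else:
        shifted, offset = np.array([]), 0.0
    matrix = build_matrix(result.records, shifted, patients=patients, genes=genes)
    logger.info(
        "scored %d passing variants into %dx%d matrix (offset %.4f, %.1f%% zeros)",
        len(result.records), *matrix.shape, offset, 100 * matrix.zero_fraction,
    )
    return ScoreResult(matrix=matrix, offset=offset, audit=result.audit)


def annotation_lookup_from_frame(frame: pd.DataFrame) -> "OrderedDict[tuple, VariantAnnotation]":
    """Build an annotation lookup from a table with columns
    chrom, pos, ref, alt, cadd_raw, dbsnp_maf (NaN for absent)."""
    lookup: OrderedDict[tuple, VariantAnnotation] = OrderedDict()
    for row in frame.itertuples(index=False):
        maf = None if pd.isna(row.dbsnp_maf) else float(row.dbsnp_maf)
        lookup[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = VariantAnnotation(
            cadd_raw=float(row.cadd_raw), dbsnp_maf=maf
        )
    return lookup
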