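"""Plain-text readers and writers for every pipeline artifact.

All inter-stage artifacts are TSV or JSON so intermediates stay diffable;
variant records travel as minimal per-patient VCFs (via pysam) with the
somatic status, consequence class, region class and gene carried in INFO,
plus a TSV annotation table keyed by (chrom, pos, ref, alt) holding the
CADD raw score and dbSNP minor allele frequency.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from mutclust.scoring import (
    Consequence,
    MutationScoreMatrix,
    Region,
    VariantAnnotation,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# matrix / clinical / generic tables
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix: MutationScoreMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path: str | Path) -> MutationScoreMatrix:
    return MutationScoreMatrix(pd.read_csv(path, sep="\t", index_col="gene"))


def write_clinical_tsv(stages: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"patient_id": stages.index, "stage": stages.values}).to_csv(
        path, sep="\t", index=False
    )


def read_clinical_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(frame["stage"].values, index=frame["patient_id"].values, name="stage")


def write_assignments_tsv(assignments: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"patient_id": assignments.index, "cluster": assignments.values}).to_csv(
        path, sep="\t", index=False
    )


def read_assignments_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return pd.Series(
        frame["cluster"].astype(int).values, index=frame["patient_id"].astype(str).values,
        name="cluster",
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------


def write_annotation_tsv(
    annotations: Mapping[tuple, VariantAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "chrom": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "cadd_raw": ann.cadd_raw,
            "dbsnp_maf": ann.dbsnp_maf if ann.dbsnp_maf is not None else np.nan,
        }
        for key, ann in annotations.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "cadd_raw", "dbsnp_maf"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path: str | Path) -> dict[tuple, VariantAnnotation]:
    frame = pd.read_csv(path, sep="\t")
    lookup: dict[tuple, VariantAnnotation] = {}
    for row in frame.itertuples(index=False):
        maf = None if pd.isna(row.dbsnp_maf) else float(row.dbsnp_maf)
        lookup[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = VariantAnnotation(
            cadd_raw=float(row.cadd_raw), dbsnp_maf=maf
        )
    return lookup


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(contigs: Sequence[str], patient_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("SOMATIC", 0, "Flag", "Variant is somatic (absent: germline)")
    header.info.add("CSQ_CLASS", 1, "String", "Consequence class")
    header.info.add("REGION", 1, "String", "Genomic region class")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.add_meta("patient_id", patient_id)
    return header


def _contig_sort_key(chrom: str):
    body = chrom.removeprefix("chr")
    return (0, int(body)) if body.isdigit() else (1, body)


def write_patient_vcf(records: Sequence[VariantRecord], patient_id: str, path: str | Path) -> None:
    """Write one patient's records as a minimal uncompressed VCF."""
    recs = [r for r in records if r.patient_id == patient_id]
    contigs = sorted({r.chrom for r in recs}, key=_contig_sort_key)
    header = _vcf_header(contigs, patient_id)
    recs.sort(key=lambda r: (_contig_sort_key(r.chrom), r.pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in recs:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            if r.somatic:
                rec.info["SOMATIC"] = True
            rec.info["CSQ_CLASS"] = r.consequence.value
            rec.info["REGION"] = r.region.value
            rec.info["GENE"] = r.gene
            vcf.write(rec)


def write_cohort_vcfs(
    records: Sequence[VariantRecord], outdir: str | Path, patients: Sequence[str] | None = None
) -> list[Path]:
    """One VCF per patient under ``outdir``; patients with no records get an
    empty (header-only) file so the cohort universe is preserved."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if patients is None:
        patients = sorted({r.patient_id for r in records})
    paths = []
    for patient in patients:
        path = outdir / f"{patient}.vcf"
        write_patient_vcf(records, patient, path)
        paths.append(path)
    return paths


def read_patient_vcf(path: str | Path, patient_id: str | None = None) -> list[VariantRecord]:
    """Read one patient's VCF back into variant records.

    The patient id defaults to the ``##patient_id`` header line (falling
    back to the file stem). Multi-allelic lines are split into one record
    per alternate allele before any filtering.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        if patient_id is None:
            for hrec in vcf.header.records:
                if hrec.key == "patient_id":
                    patient_id = hrec.value
                    break
            else:
                patient_id = path.stem
        for rec in vcf:
            info = dict(rec.info)
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        patient_id=patient_id,
                        somatic=bool(info.get("SOMATIC", False)),
                        consequence=Consequence(info.get("CSQ_CLASS", "other")),
                        region=Region(info.get("REGION", "other")),
                        gene=info.get("GENE", ""),
                    )
                )
    return records


def read_cohort_vcfs(paths: Iterable[str | Path]) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    for path in sorted(Path(p) for p in paths):
        records.extend(read_patient_vcf(path))
    return records
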