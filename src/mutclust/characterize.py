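"""Clinical characterization of patient clusters.

Relates discovered clusters to AJCC stage (early = I/II, late = III/IV,
unknown excluded) with per-cluster early:late ratios and an exact
conditional test of association on the cluster x stage table, and finds
genes whose mutation burden differs between two clusters with the
Wilcoxon rank-sum test under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from mutclust.scoring import MutationScoreMatrix

EARLY_STAGES = frozenset({"I", "II"})
LATE_STAGES = frozenset({"III", "IV"})
VALID_STAGES = EARLY_STAGES | LATE_STAGES | {"unknown"}


def dichotomize_stage(stage: str) -> str | None:
    """Map an AJCC stage to 'early' (I, II), 'late' (III, IV) or None (unknown)."""
    if stage in EARLY_STAGES:
        return "early"
    if stage in LATE_STAGES:
        return "late"
    if stage == "unknown":
        return None
    raise ValueError(f"unknown stage label: {stage!r}")


@dataclass
class StageByClusterTable:
    """Per-cluster early/late counts, ratios, and the unknown-stage exclusions."""

    table: pd.DataFrame  # index cluster; columns n_patients, n_early, n_late, ratio
    excluded_unknown: int

    def counts(self) -> np.ndarray:
        """The r x 2 (early, late) count matrix in cluster order."""
        return self.table[["n_early", "n_late"]].to_numpy(dtype=int)


def stage_by_cluster(assignments: pd.Series, stages: pd.Series) -> StageByClusterTable:
    """Cross-tabulate cluster assignments against dichotomized stage.

    Every assigned patient must appear in the stage table (stage may be
    'unknown'); unknown-stage patients are counted and excluded from all
    statistics. The per-cluster ratio n_early/n_late is NaN when a
    cluster has no late-stage patient.
    """
    missing = [p for p in assignments.index if p not in stages.index]
    if missing:
        raise KeyError(f"patients missing from stage table: {missing}")
    rows = []
    excluded = 0
    for cluster in sorted(assignments.unique()):
        patients = assignments.index[assignments == cluster]
        dich = [dichotomize_stage(stages[p]) for p in patients]
        n_early = sum(d == "early" for d in dich)
        n_late = sum(d == "late" for d in dich)
        excluded += sum(d is None for d in dich)
        rows.append(
            {
                "cluster": cluster,
                "n_patients": len(patients),
                "n_early": n_early,
                "n_late": n_late,
                "ratio": n_early / n_late if n_late > 0 else float("nan"),
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")
    return StageByClusterTable(table=table, excluded_unknown=excluded)


def _rx2_exact_pvalue(counts: np.ndarray, rel_tol: float = 1e-7) -> float:
    """Two-sided exact conditional p-value for an r x 2 contingency table.

    Conditions on both margins and sums the multivariate hypergeometric
    probabilities of all tables no more probable than the observed one
    (the Freeman-Halton generalization of Fisher's exact test; for 2 x 2
    this is the classic two-sided Fisher test). Probabilities are
    compared in log space with a relative tolerance on equality.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("counts must be an r x 2 table with r >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    n = int(counts.sum())
    e = int(col_tot[0])  # first-column (early) total

    lgamma = math.lgamma

    def log_choose(a: int, b: int) -> float:
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    log_denom = log_choose(n, e)

    def log_prob(cells: Sequence[int]) -> float:
        return sum(log_choose(int(r), int(c)) for r, c in zip(row_tot, cells)) - log_denom

    log_p_obs = log_prob(counts[:, 0])
    log_cut = log_p_obs + math.log1p(rel_tol)

    total = 0.0
    cells = [0] * len(row_tot)

    def recurse(i: int, remaining: int, log_acc: float) -> None:
        nonlocal total
        if i == len(row_tot) - 1:
            if 0 <= remaining <= row_tot[i]:
                lp = log_acc + log_choose(int(row_tot[i]), remaining) - log_denom
                if lp <= log_cut:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(row_tot[i + 1 :].sum()))
        hi = min(int(row_tot[i]), remaining)
        for c in range(lo, hi + 1):
            recurse(i + 1, remaining - c, log_acc + log_choose(int(row_tot[i]), c))

    recurse(0, e, 0.0)
    return min(1.0, total)


def stage_enrichment_exact(
    table: StageByClusterTable | np.ndarray, clusters: Sequence | None = None
) -> float:
    """Exact two-sided test of stage-by-cluster association.

    By default all clusters enter an r x 2 table of early/late counts;
    pass ``clusters`` to restrict to a subset (e.g. a 2 x 2 comparison of
    the most early- and late-enriched clusters).
    """
    if isinstance(table, StageByClusterTable):
        frame = table.table if clusters is None else table.table.loc[list(clusters)]
        counts = frame[["n_early", "n_late"]].to_numpy(dtype=int)
    else:
        counts = np.asarray(table, dtype=int)
        if clusters is not None:
            counts = counts[list(clusters)]
    if counts.shape[0] < 2:
        raise ValueError("at least 2 clusters are required")
    return _rx2_exact_pvalue(counts)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    _, fdr, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return fdr


def differential_mutation(
    matrix: MutationScoreMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum comparison of mutation scores between two groups.

    For each gene the two-sided rank-sum test compares the score vectors
    of ``group_a`` and ``group_b`` patients (exact null when the smaller
    group has <= 25 patients and the pooled data is tie-free, otherwise
    the normal approximation with midranks, tie correction and
    continuity correction). P-values are adjusted across all tested
    genes by Benjamini-Hochberg step-up. Returns a DataFrame sorted by
    p-value with columns gene, p_value, fdr, mean_a, mean_b, direction
    ('a' or 'b' for the group with the higher mean, 'none' for ties) and
    significant (fdr < ``fdr_threshold``).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 patients")
    Xa = matrix.data[group_a].to_numpy()
    Xb = matrix.data[group_b].to_numpy()

    n_min = min(len(group_a), len(group_b))
    p_values = np.ones(matrix.shape[0])
    for i in range(matrix.shape[0]):
        x, y = Xa[i], Xb[i]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            continue  # identical constant vectors: no evidence, p = 1
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (n_min <= 25 and not has_ties) else "asymptotic"
        p_values[i] = mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue

    fdr = benjamini_hochberg(p_values)
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    direction = np.where(mean_a > mean_b, "a", np.where(mean_b > mean_a, "b", "none"))
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "p_value": p_values,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": direction,
            "significant": fdr < fdr_threshold,
        }
    )
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
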