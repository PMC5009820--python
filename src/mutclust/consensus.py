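"""Consensus clustering over repeated NMF runs and silhouette model selection.

A single NMF run depends on its random initialization; stability across
runs is what justifies a clustering. Each run's sample partition is
encoded as a binary connectivity matrix, connectivity matrices are
averaged into a consensus matrix whose entries estimate co-clustering
probabilities, and the average silhouette width of the consensus
(dissimilarity 1 - consensus) scores how block-like, i.e. how stable,
the clustering is. Scanning a grid of (top-gene count, rank k) and
picking the silhouette maximum selects the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mutclust.features import rank_by_variance, select_top
from mutclust.nmf import NMFRunResult, run_nmf
from mutclust.scoring import MutationScoreMatrix

logger = logging.getLogger(__name__)


def connectivity(assignments: np.ndarray) -> np.ndarray:
    """Binary symmetric matrix with c_ij = 1 iff samples i and j share a cluster."""
    labels = np.asarray(assignments)
    return (labels[:, None] == labels[None, :]).astype(float)


@dataclass
class ConsensusMatrix:
    """Mean of connectivity matrices over repeated runs."""

    matrix: np.ndarray
    run_count: int

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.allclose(C, C.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        self.matrix = np.clip(C, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def dissimilarity(self) -> np.ndarray:
        """1 - consensus, symmetrized with a zero diagonal."""
        d = 1.0 - self.matrix
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        return d


def consensus(runs: Sequence[NMFRunResult] | Sequence[np.ndarray]) -> ConsensusMatrix:
    """Average the connectivity matrices of repeated runs.

    Accepts NMF run results or raw per-sample label arrays; all runs
    must cover the same sample set (same length and order).
    """
    if len(runs) == 0:
        raise ValueError("consensus requires at least one run")
    label_sets = [r.assignments if isinstance(r, NMFRunResult) else np.asarray(r) for r in runs]
    n = len(label_sets[0])
    if any(len(ls) != n for ls in label_sets):
        raise ValueError("runs cover inconsistent sample sets")
    acc = np.zeros((n, n))
    for labels in label_sets:
        acc += connectivity(labels)
    return ConsensusMatrix(matrix=acc / len(label_sets), run_count=len(label_sets))


@dataclass
class SilhouetteResult:
    s: np.ndarray  # per-sample silhouette in [-1, 1]
    a: np.ndarray  # mean dissimilarity to own-cluster co-members (nan for singletons)
    b: np.ndarray  # min over other clusters of mean dissimilarity
    labels: np.ndarray
    average_width: float


def silhouette_of_consensus(cons: ConsensusMatrix, labels: Sequence[int]) -> SilhouetteResult:
    """Average silhouette width of the consensus matrix under ``labels``.

    Dissimilarity is d = 1 - consensus. For each sample, a(i) is the mean
    d to the other members of its cluster and b(i) the smallest mean d to
    any other cluster; s(i) = (b - a) / max(a, b), with s(i) = 0 when
    a(i) = b(i) and for singleton clusters. Requires >= 2 clusters.
    """
    labels = np.asarray(labels)
    if len(labels) != cons.n:
        raise ValueError("labels do not match consensus size")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    d = cons.dissimilarity()
    n = cons.n
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    s = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i]) & (np.arange(n) != i)
        others = [np.mean(d[i, labels == c]) for c in uniq if c != labels[i]]
        b[i] = min(others)
        if not own.any():  # singleton cluster: s stays 0 by convention
            continue
        a[i] = np.mean(d[i, own])
        if a[i] < b[i]:
            s[i] = 1.0 - a[i] / b[i] if b[i] > 0 else 0.0
        elif a[i] > b[i]:
            s[i] = b[i] / a[i] - 1.0
        # a == b -> 0
    return SilhouetteResult(s=s, a=a, b=b, labels=labels, average_width=float(s.mean()))


def consensus_labels(cons: ConsensusMatrix, k: int) -> np.ndarray:
    """Cut an average-linkage tree of the consensus dissimilarity at k clusters.

    This makes the silhouette a pure function of the consensus matrix
    rather than of any single arbitrary run. Returns 1-based labels.
    """
    condensed = squareform(cons.dissimilarity(), checks=False)
    tree = linkage(condensed, method="average")
    return fcluster(tree, t=k, criterion="maxclust")


@dataclass
class ModelScanResult:
    """Silhouette grid over (n_top_genes, k) and the selected cell."""

    grid: pd.DataFrame  # columns: n_top, k, silhouette
    selected_n_top: int
    selected_k: int
    selected_silhouette: float
    selected_labels: np.ndarray  # consensus-derived labels at the selected cell
    selected_consensus: ConsensusMatrix
    patients: list[str]

    def assignments(self) -> pd.Series:
        return pd.Series(self.selected_labels, index=self.patients, name="cluster")


def _cell_seed(seed: int, n_top: int, k: int, run: int) -> int:
    """Deterministic per-run seed independent of grid traversal order."""
    return int(np.random.SeedSequence([seed, n_top, k, run]).generate_state(1)[0])


def scan_models(
    matrix: MutationScoreMatrix,
    gene_grid: Sequence[int],
    k_grid: Sequence[int],
    runs_per_cell: int = 100,
    seed: int = 0,
    **nmf_kwargs,
) -> ModelScanResult:
    """Scan (top-gene count, rank) and select the most stable clustering.

    For each grid cell the top genes by variance are selected, NMF is run
    ``runs_per_cell`` times with distinct derived seeds, the consensus
    matrix is built, and the average silhouette width is computed with
    consensus-derived (average-linkage) labels. The cell with the largest
    silhouette is selected (ties: smaller k, then fewer genes). Cells
    with k >= n_patients are skipped with a warning; cells whose
    consensus tree degenerates to a single cluster score NaN.
    """
    if len(gene_grid) == 0 or len(k_grid) == 0:
        raise ValueError("gene_grid and k_grid must be non-empty")
    if runs_per_cell < 2:
        raise ValueError("runs_per_cell must be >= 2")
    ranking = rank_by_variance(matrix)
    n_patients = matrix.shape[1]

    rows = []
    cache: dict[tuple[int, int], tuple[ConsensusMatrix, np.ndarray]] = {}
    for n_top in gene_grid:
        sub = select_top(matrix, ranking, n_top).drop_empty_genes()
        for k in k_grid:
            if k >= n_patients:
                logger.warning("skipping cell (n_top=%d, k=%d): k >= n_patients", n_top, k)
                continue
            if k >= sub.shape[0]:
                logger.warning("skipping cell (n_top=%d, k=%d): k >= usable genes", n_top, k)
                continue
            runs = [
                run_nmf(sub.values, k, seed=_cell_seed(seed, n_top, k, r), **nmf_kwargs)
                for r in range(runs_per_cell)
            ]
            cons = consensus(runs)
            labels = consensus_labels(cons, k)
            try:
                width = silhouette_of_consensus(cons, labels).average_width
            except ValueError:
                width = float("nan")
            cache[(n_top, k)] = (cons, labels)
            rows.append({"n_top": n_top, "k": k, "silhouette": width})

    grid = pd.DataFrame(rows, columns=["n_top", "k", "silhouette"])
    if grid.empty or grid["silhouette"].isna().all():
        raise ValueError("no valid grid cell; check gene_grid and k_grid against the matrix size")
    valid = grid.dropna(subset=["silhouette"]).sort_values(
        ["silhouette", "k", "n_top"], ascending=[False, True, True], kind="mergesort"
    )
    best = valid.iloc[0]
    n_top, k = int(best["n_top"]), int(best["k"])
    cons, labels = cache[(n_top, k)]
    return ModelScanResult(
        grid=grid.sort_values(["n_top", "k"], kind="mergesort").reset_index(drop=True),
        selected_n_top=n_top,
        selected_k=k,
        selected_silhouette=float(best["silhouette"]),
        selected_labels=labels,
        selected_consensus=cons,
        patients=matrix.patients,
    )
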