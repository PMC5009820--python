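"""Variance-based gene ranking and top-n selection for clustering.

With tens of thousands of genes against a few hundred patients, the
sample-to-feature ratio makes clustering on the full matrix hopeless;
genes are ranked by the sample variance of their scores across patients
and only the top n enter the factorization.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from mutclust.scoring import MutationScoreMatrix


def rank_by_variance(matrix: MutationScoreMatrix) -> pd.DataFrame:
    """Rank genes by decreasing sample variance across patients.

    Variance uses the n-1 denominator. Ties are broken by lexicographic
    gene symbol so rankings are reproducible. Returns a DataFrame with
    columns ``gene``, ``variance``, ``rank`` (1-based), sorted by rank.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variance ranking needs at least 2 patients")
    var = matrix.data.var(axis=1, ddof=1)
    out = (
        pd.DataFrame({"gene": var.index, "variance": var.values})
        .sort_values(["variance", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out["rank"] = out.index + 1
    return out


def select_top(
    matrix: MutationScoreMatrix, ranking: pd.DataFrame, n_top: int
) -> MutationScoreMatrix:
    """Restrict the matrix to the ``n_top`` highest-variance genes, in rank order."""
    m = matrix.shape[0]
    if not (1 <= n_top <= m):
        raise ValueError(f"n_top must be in [1, {m}], got {n_top}")
    genes: Sequence[str] = ranking["gene"].head(n_top).tolist()
    return matrix.subset_genes(genes)
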