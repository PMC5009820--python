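"""KL-divergence non-negative matrix factorization with multiplicative updates.

Factors a non-negative matrix A (genes x samples) as A ~ W H with
W (m x k) a basis of metagenes and H (k x n) per-sample metagene loads,
by the classic multiplicative update rules that monotonically decrease
the generalized Kullback-Leibler divergence D(A || WH). Each sample is
assigned to the metagene with the largest coefficient in its column of
H. Repeated seeded runs feed the consensus machinery in
:mod:`mutclust.consensus`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class FactorPair:
    """Basis W (m x k) and coefficient H (k x n) matrices."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise ValueError(f"incompatible factor shapes {self.W.shape} x {self.H.shape}")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factors must be non-negative")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def product(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class NMFRunResult:
    """Outcome of one seeded NMF run."""

    factors: FactorPair
    assignments: np.ndarray  # per-sample cluster id, 1-based
    divergence_trace: list[float]
    iterations: int
    seed: int
    converged: bool


def kl_divergence(A: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float = EPS) -> float:
    """Generalized KL divergence D(A || WH).

    D = sum_ij [ A_ij * log(A_ij / (WH)_ij) - A_ij + (WH)_ij ], with the
    0*log(0) = 0 convention and an epsilon floor on (WH)_ij.
    """
    A = np.asarray(A, dtype=float)
    WH = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    if WH.shape != A.shape:
        raise ValueError(f"shape mismatch: A is {A.shape}, WH is {WH.shape}")
    WH = np.maximum(WH, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(A > 0, A * np.log(np.maximum(A, eps) / WH), 0.0)
    return float(np.sum(log_term - A + WH))


def update_step(A: np.ndarray, factors: FactorPair, eps: float = EPS) -> FactorPair:
    """One coupled multiplicative update of W then H.

    W_ia <- W_ia * [sum_u H_au A_iu/(WH)_iu] / sum_v H_av, followed by
    the symmetric H update using the already-updated W. Non-negativity
    is preserved by construction and the divergence does not increase.
    """
    A = np.asarray(A, dtype=float)
    W = factors.W.copy()
    H = factors.H.copy()

    WH = np.maximum(W @ H, eps)
    W *= (A / WH) @ H.T / np.maximum(H.sum(axis=1), eps)
    WH = np.maximum(W @ H, eps)
    H *= W.T @ (A / WH) / np.maximum(W.sum(axis=0), eps)[:, None]

    if not (np.isfinite(W).all() and np.isfinite(H).all()):
        raise FloatingPointError("non-finite values produced by multiplicative update")
    return FactorPair(W, H)


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Assign sample j to the metagene with the largest H entry in column j.

    Ties (including all-zero columns, e.g. patients with no scored
    mutation) go to the smallest metagene index; 1-based cluster ids.
    """
    return np.argmax(H, axis=0) + 1


def run_nmf(
    A: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    stop_window: int = 40,
    check_interval: int = 10,
    eps: float = EPS,
) -> NMFRunResult:
    """Run seeded multiplicative-update NMF to a stable sample clustering.

    W and H are initialized i.i.d. uniform on (0, max(A)]. Every
    ``check_interval`` iterations the sample connectivity (column argmax
    of H) is compared with the previous check; the run stops once it has
    been unchanged for ``stop_window`` consecutive checks, or at
    ``max_iter``. The divergence is recorded at each check.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    if (A < 0).any():
        raise ValueError("A must be non-negative")
    m, n = A.shape
    if not (1 <= k < min(m, n)):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min(m, n) = {min(m, n)}")
    if (A.sum(axis=1) == 0).any():
        raise ValueError("A contains all-zero gene rows; drop them before factorization")
    zero_cols = np.where(A.sum(axis=0) == 0)[0]
    if zero_cols.size:
        logger.warning(
            "%d all-zero sample columns; their assignment falls to the argmax tie rule",
            zero_cols.size,
        )

    rng = np.random.default_rng(seed)
    high = float(A.max())
    factors = FactorPair(
        W=rng.uniform(eps, high, size=(m, k)),
        H=rng.uniform(eps, high, size=(k, n)),
    )

    def _connectivity(labels: np.ndarray) -> np.ndarray:
        return labels[:, None] == labels[None, :]

    trace: list[float] = [kl_divergence(A, factors.W, factors.H, eps)]
    prev_conn = _connectivity(assign_clusters(factors.H))
    stable_checks = 0
    iteration = 0
    converged = False
    while iteration < max_iter:
        try:
            factors = update_step(A, factors, eps)
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} at iteration {iteration + 1}") from exc
        iteration += 1
        if iteration % check_interval == 0 or iteration == max_iter:
            trace.append(kl_divergence(A, factors.W, factors.H, eps))
            conn = _connectivity(assign_clusters(factors.H))
            if np.array_equal(conn, prev_conn):
                stable_checks += 1
            else:
                stable_checks = 0
            prev_conn = conn
            if stable_checks >= stop_window:
                converged = True
                break

    return NMFRunResult(
        factors=factors,
        assignments=assign_clusters(factors.H),
        divergence_trace=trace,
        iterations=iteration,
        seed=seed,
        converged=converged,
    )
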