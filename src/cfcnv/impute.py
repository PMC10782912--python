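"""Dropout imputation by regularized low-rank matrix factorization.

Entries flagged as missing (dropout) are replaced by the reconstruction of a
rank-``r`` factor model fit by gradient descent on the observed entries;
observed entries are never altered (completion, not smoothing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .covmatrix import CoverageMatrix

logger = logging.getLogger(__name__)

__all__ = ["MissingMask", "FactorModel", "flag_missing", "impute_lowrank"]


@dataclass
class MissingMask:
    """Boolean samples x windows mask; True marks entries treated as missing."""

    mask: np.ndarray
    n_missing: int
    n_total: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction(self) -> float:
        return self.n_missing / self.n_total if self.n_total else 0.0


@dataclass
class FactorModel:
    rank: int
    row_factors: np.ndarray     # samples x rank
    col_factors: np.ndarray     # windows x rank
    regularization: float
    seed: int
    loss_history: np.ndarray    # recorded once per epoch

    def reconstruction(self) -> np.ndarray:
        return self.row_factors @ self.col_factors.T


def flag_missing(m: CoverageMatrix, epsilon: float = 0.01) -> MissingMask:
    """Flag entries with value strictly below ``epsilon`` as dropout.

    With ``epsilon = 0`` only exact zeros are flagged (value < 0 cannot occur
    for coverage, so the strict comparison is widened to ``<=`` at zero).
    A row or column that would be entirely missing is an error.
    """
    if m.stage != "normalized":
        raise ValueError(f"flag_missing expects a normalized matrix, got {m.stage!r}")
    if epsilon == 0:
        mask = m.values == 0
    else:
        mask = m.values < epsilon
    all_missing_rows = np.flatnonzero(mask.all(axis=1))
    if all_missing_rows.size:
        raise ValueError(
            f"row(s) entirely missing: {[m.sample_ids[i] for i in all_missing_rows]}"
        )
    all_missing_cols = np.flatnonzero(mask.all(axis=0))
    if all_missing_cols.size:
        raise ValueError(
            "column(s) entirely missing: "
            f"{[int(m.window_indices[j]) for j in all_missing_cols]}"
        )
    n_missing = int(mask.sum())
    logger.info("flagged %d / %d entries as missing", n_missing, mask.size)
    return MissingMask(mask=mask, n_missing=n_missing, n_total=mask.size)


def impute_lowrank(
    m: CoverageMatrix,
    mask: MissingMask,
    rank: int = 10,
    regularization: float = 0.1,
    learning_rate: float = 0.05,
    epochs: int = 2000,
    seed: int = 0,
) -> tuple[CoverageMatrix, FactorModel]:
    """Replace masked entries with a regularized rank-``rank`` reconstruction.

    Minimizes sum of squared error over observed entries plus
    ``regularization * (||U||^2 + ||V||^2)`` with Adam from a seeded random
    init.  Observed entries are copied through unchanged.  A loss that fails
    to decrease over the final 20% of epochs triggers a warning.
    """
    X = m.values
    B = np.asarray(mask.mask, dtype=bool)
    if B.shape != X.shape:
        raise ValueError("mask shape does not match matrix")
    n, p = X.shape
    out_values = X.copy()
    if mask.n_missing == 0:
        model = FactorModel(rank, np.zeros((n, rank)), np.zeros((p, rank)),
                            regularization, seed, np.zeros(0))
        return m.advance(out_values, "imputed"), model
    if not 0 < rank < min(n, p):
        raise ValueError(f"rank must be in (0, {min(n, p)}), got {rank}")

    rng = np.random.default_rng(seed)
    obs = ~B
    # positive random init: coverage is non-negative, and sign-mixed factors
    # can strand gradient descent in a sign-mismatch local minimum
    scale = np.sqrt(max(abs(X[obs].mean()), 1e-6) / rank)
    U = np.abs(rng.normal(scale=scale, size=(n, rank)))
    V = np.abs(rng.normal(scale=scale, size=(p, rank)))

    # Adam state
    mU = np.zeros_like(U); vU = np.zeros_like(U)
    mV = np.zeros_like(V); vV = np.zeros_like(V)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lam = regularization
    history = np.empty(epochs)
    for t in range(1, epochs + 1):
        R = np.where(obs, X - U @ V.T, 0.0)
        loss = float((R ** 2).sum() + lam * ((U ** 2).sum() + (V ** 2).sum()))
        history[t - 1] = loss
        gU = -2.0 * (R @ V) + 2.0 * lam * U
        gV = -2.0 * (R.T @ U) + 2.0 * lam * V
        mU = b1 * mU + (1 - b1) * gU; vU = b2 * vU + (1 - b2) * gU ** 2
        mV = b1 * mV + (1 - b1) * gV; vV = b2 * vV + (1 - b2) * gV ** 2
        c1 = 1 - b1 ** t; c2 = 1 - b2 ** t
        U -= learning_rate * (mU / c1) / (np.sqrt(vU / c2) + eps)
        V -= learning_rate * (mV / c1) / (np.sqrt(vV / c2) + eps)

    tail = max(1, int(0.2 * epochs))
    if history[-1] > history[-tail] * 1.01:  # allow small Adam oscillation
        warnings.warn(
            f"imputation may not have converged: loss {history[-tail]:.6g} -> "
            f"{history[-1]:.6g} over final {tail} epochs"
        )
    recon = U @ V.T
    out_values[B] = recon[B]
    model = FactorModel(rank, U, V, regularization, seed, history)
    return m.advance(out_values, "imputed"), model
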