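"""Applicability-domain and influence diagnostics for the selected model.

Leverage (hat values) measures how far a case sits in descriptor space:
h_ii is the i-th diagonal of the projection matrix X(XᵀX)⁻¹Xᵀ of the
model's design (selected features plus intercept).  Cases with
h > 3m/n — m model parameters, n observations — fall outside the
applicability domain.  Cook's distance combines residual and leverage to
flag cases that materially shift the fitted coefficients; the default
cutoff is 4/n.

For non-linear winners (RF, SVRM, NN) the diagnostics are computed on the
linear design of the selected features: leverage is a property of the
descriptor-space geometry, not of the fitted predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DomainError(ValueError):
    pass


@dataclass
class ADReport:
    case_ids: np.ndarray
    hat_values: np.ndarray
    mean_hat: float
    leverage_threshold: float
    high_leverage_ids: list[int]
    cooks_distances: np.ndarray
    cooks_cutoff: float
    influential_ids: list[int]
    m: int  # model parameters incl. intercept


def _design(X_model: np.ndarray, add_intercept: bool) -> np.ndarray:
    X_model = np.asarray(X_model, dtype=float)
    if X_model.ndim == 1:
        X_model = X_model[:, None]
    if add_intercept:
        X_model = np.column_stack([np.ones(X_model.shape[0]), X_model])
    return X_model


def _drop_aliased_cols(A: np.ndarray) -> np.ndarray:
    """Keep a maximal full-rank prefix-greedy subset of columns."""
    kept: list[int] = []
    for j in range(A.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(A[:, trial]) == len(trial):
            kept.append(j)
    if len(kept) < A.shape[1]:
        warnings.warn("rank-deficient design: aliased columns dropped for leverage")
    return A[:, kept]


def hat_values(X_model, add_intercept: bool = True) -> np.ndarray:
    """Diagonal of the hat matrix X(XᵀX)⁻¹Xᵀ of the (intercept-augmented) design.

    Rank-deficient designs have aliased columns dropped with a warning.
    The returned values always satisfy the trace identity sum(h) = m.
    """
    A = _design(X_model, add_intercept)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        A = _drop_aliased_cols(A)
    # QR is numerically stabler than forming (XᵀX)⁻¹ explicitly
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q * Q, axis=1)
    return h


def leverage_threshold(m: int, n: int) -> float:
    """The applicability-domain leverage cutoff 3·m/n."""
    if n <= 0:
        raise DomainError("n must be positive")
    return 3.0 * m / n


def cooks_distances(X_model, y, add_intercept: bool = True) -> np.ndarray:
    """Cook's distance D_i = e_i²·h_i / (m·s²·(1−h_i)²) from an OLS fit.

    s² = RSS/(n−m).  Cases with h_i = 1 (exactly self-determined) get
    D_i = inf as an explicit flag.
    """
    A = _design(X_model, add_intercept)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        A = _drop_aliased_cols(A)
    y = np.asarray(y, dtype=float)
    n, m = A.shape
    if n <= m:
        raise DomainError(f"need n > m for Cook's distances (n={n}, m={m})")
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    e = y - A @ coef
    h = hat_values(A, add_intercept=False)
    rss = float(e @ e)
    if rss <= 1e-24 * max(1.0, float(y @ y)):
        rss = 0.0  # numerically perfect fit: all distances are zero
    s2 = rss / (n - m)
    D = np.empty(n)
    for i in range(n):
        if h[i] >= 1.0 - 1e-12:
            D[i] = np.inf
        elif s2 == 0:
            D[i] = 0.0
        else:
            D[i] = e[i] ** 2 * h[i] / (m * s2 * (1.0 - h[i]) ** 2)
    return D


def assess_domain(
    X_model,
    y,
    case_ids=None,
    add_intercept: bool = True,
    cooks_cutoff: float | None = None,
) -> ADReport:
    """Full leverage + influence report for the model's design matrix.

    high-leverage: h > 3m/n; influential: D > cutoff (default 4/n).
    """
    A = _design(X_model, add_intercept)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        A = _drop_aliased_cols(A)
    n, m = A.shape
    if case_ids is None:
        case_ids = np.arange(n)
    case_ids = np.asarray(case_ids, dtype=int)
    h = hat_values(A, add_intercept=False)
    thr = leverage_threshold(m, n)
    D = cooks_distances(A, y, add_intercept=False)
    cutoff = 4.0 / n if cooks_cutoff is None else cooks_cutoff
    high = sorted(int(c) for c in case_ids[h > thr])
    infl = sorted(int(c) for c in case_ids[D > cutoff])
    return ADReport(
        case_ids=case_ids,
        hat_values=h,
        mean_hat=float(h.mean()),
        leverage_threshold=thr,
        high_leverage_ids=high,
        cooks_distances=D,
        cooks_cutoff=cutoff,
        influential_ids=infl,
        m=m,
    )
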