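"""PLS1 regression engine with cross-validation schemes and fit metrics.

The model is single-response partial least squares, Y = XB + E, fit by
NIPALS.  For PLS1 the NIPALS inner loop is non-iterative, so the fit is
deterministic.  The engine exposes the full coefficient *path* over
1..max_lv latent variables from a single deflation pass, which makes
latent-variable selection by cross-validation cheap: each CV fold is fit
once and scored at every component count.

Predictors are autoscaled (train statistics, sample SD) inside the model;
the response is centered but never scaled, so predictions and errors stay
on the response's natural scale (um for granule sizes, % for LOD).

Cross-validation plans:

``loo``           leave-one-out, one fold per row.
``sequential_k``  row i goes to fold i mod k (interleaved; optimistic on
                  autocorrelated series because every test row has near
                  neighbours in training).
``block_k``       k contiguous blocks (respects serial correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.linalg.blas import dger

from .preprocess import ScalingParams, apply_scaling, fit_scaling

__all__ = [
    "PLSModel",
    "CVPlan",
    "MetricBundle",
    "loo_plan",
    "sequential_plan",
    "block_plan",
    "fit_pls",
    "predict",
    "cross_validate",
    "cross_validate_path",
    "select_n_lv",
    "metrics",
]

_TOL = 1e-14


# ---------------------------------------------------------------------------
# Core NIPALS


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_lv: int) -> np.ndarray:
    """Coefficient path for centered data.

    Returns ``B`` of shape ``(p, m)`` where column k-1 is the coefficient
    vector using k latent variables.  Extraction stops early if the
    residual X or y carries no more covariance; remaining columns repeat
    the last extracted solution.
    """
    X = np.asfortranarray(Xc)           # rank-1 deflation updates in place
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    scale0 = max(np.abs(Xc).max(initial=0.0), 1.0)
    a = 0
    for a in range(max_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _TOL * scale0:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= _TOL:
            break
        P[:, a] = X.T @ t / tt
        q[a] = (y @ t) / tt
        W[:, a] = w
        X = dger(-1.0, t, P[:, a], a=X, overwrite_a=1)
        y = y - q[a] * t
        a += 1
    k = a
    B = np.zeros((p, max_lv))
    if k == 0:
        return B
    # R = W (P'W)^{-1}; P'W is unit upper triangular, so leading blocks of
    # its inverse give every sub-path consistently.
    PtW = P[:, :k].T @ W[:, :k]
    # R = W (P'W)^{-1}  <=>  R' = (P'W)^{-T} W', a lower-triangular solve.
    R = solve_triangular(PtW.T, W[:, :k].T, lower=True).T
    Rq = R * q[:k]
    B[:, :k] = np.cumsum(Rq, axis=1)
    if k < max_lv:
        B[:, k:] = B[:, [k - 1]]
    return B


@dataclass
class PLSModel:
    """A fitted PLS1 model on the original predictor scale."""

    n_lv: int
    B: np.ndarray                 # (p,) coefficients, original X scale
    intercept: float
    scaling: ScalingParams
    y_mean: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_predictors(self) -> int:
        return self.B.size


def _check_bounds(n: int, p: int, n_lv: int) -> None:
    hi = min(n - 1, p)
    if not (1 <= n_lv <= hi):
        raise ValueError(f"n_lv must be in [1, {hi}] for a {n}x{p} problem, got {n_lv}")


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: bool = True,
    provenance: dict | None = None,
) -> PLSModel:
    """Fit PLS1 with ``n_lv`` latent variables.

    ``scale=True`` autoscales predictors on the training rows; the
    response is centered only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y are not row-aligned")
    n, p = X.shape
    _check_bounds(n, p, n_lv)
    if scale:
        sp = fit_scaling(X)
    else:
        sp = ScalingParams(X.mean(axis=0), np.ones(p), np.ones(p, dtype=bool),
                           targets_excluded=True)
    Xc = apply_scaling(sp, X)
    y_mean = float(y.mean())
    Bpath = _nipals_path(Xc, y - y_mean, n_lv)
    Bs = Bpath[:, n_lv - 1]
    B = Bs / sp.sd
    intercept = y_mean - float(sp.mean @ B)
    return PLSModel(n_lv=n_lv, B=B, intercept=intercept, scaling=sp,
                    y_mean=y_mean, provenance=provenance or {})


def predict(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Apply a fitted model: stored scaling folded into B, no refitting."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.n_predictors:
        raise ValueError(
            f"model expects {m.n_predictors} predictor columns, got {X_new.shape[1]}"
        )
    return X_new @ m.B + m.intercept


# ---------------------------------------------------------------------------
# Cross-validation plans


@dataclass(frozen=True)
class CVPlan:
    """Fold assignment per row; folds partition the rows."""

    scheme: str
    k: int
    folds: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.folds, dtype=int)
        object.__setattr__(self, "folds", f)
        present = np.unique(f)
        if f.size and (present.min() < 0 or present.max() >= self.k):
            raise ValueError("fold labels must lie in [0, k)")

    @property
    def n_rows(self) -> int:
        return self.folds.size


def loo_plan(n: int) -> CVPlan:
    return CVPlan("loo", n, np.arange(n))


def sequential_plan(n: int, k: int) -> CVPlan:
    """Interleaved folds: row i -> fold i mod k."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    return CVPlan("sequential_k", k, np.arange(n) % k)


def block_plan(n: int, k: int) -> CVPlan:
    """k contiguous blocks; the remainder is spread over the leading blocks."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return CVPlan("block_k", k, np.repeat(np.arange(k), sizes))


def cross_validate_path(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    max_lv: int,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """RMSECV for every component count 1..max_lv in one pass per fold.

    Returns ``(rmsecv, residuals)`` with ``rmsecv`` of shape ``(max_lv,)``
    and ``residuals`` of shape ``(n, max_lv)`` (observed - CV-predicted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if plan.n_rows != n:
        raise ValueError("plan does not cover all rows")
    max_lv = min(max_lv, p)
    resid = np.empty((n, max_lv))
    for fold in range(plan.k):
        test = plan.folds == fold
        train = ~test
        n_tr = int(train.sum())
        if n_tr < max_lv + 1:
            raise ValueError(
                f"fold {fold} leaves {n_tr} training rows, too few for "
                f"{max_lv} latent variables"
            )
        Xtr, ytr = X[train], y[train]
        if scale:
            sp = fit_scaling(Xtr)
            Xtr_s = apply_scaling(sp, Xtr)
            Xte_s = apply_scaling(sp, X[test])
        else:
            mu = Xtr.mean(axis=0)
            Xtr_s, Xte_s = Xtr - mu, X[test] - mu
        ym = ytr.mean()
        Bpath = _nipals_path(Xtr_s, ytr - ym, max_lv)
        pred = Xte_s @ Bpath + ym
        resid[test] = y[test, None] - pred
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    return rmsecv, resid


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    n_lv: int,
    scale: bool = True,
) -> tuple[float, np.ndarray]:
    """RMSECV and per-row CV residuals at a fixed latent-variable count."""
    _check_bounds(np.asarray(X).shape[0], np.asarray(X).shape[1], n_lv)
    rmsecv, resid = cross_validate_path(X, y, plan, n_lv, scale=scale)
    return float(rmsecv[n_lv - 1]), resid[:, n_lv - 1]


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    max_lv: int = 20,
    scale: bool = True,
) -> int:
    """Smallest component count attaining the global RMSECV minimum.

    The parsimony tie-break (within 1e-12) guards against over-fitted
    models whose extra components buy nothing.
    """
    n, p = np.asarray(X).shape
    smallest_fold_train = min(
        int((plan.folds != f).sum()) for f in range(plan.k)
    )
    max_lv = max(1, min(max_lv, p, smallest_fold_train - 1))
    rmsecv, _ = cross_validate_path(X, y, plan, max_lv, scale=scale)
    best = rmsecv.min()
    return int(np.flatnonzero(rmsecv <= best + 1e-12)[0]) + 1


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricBundle:
    """RMSE / R-squared family plus the standardized prediction ratios.

    rpd = SD_ref/RMSEP, rer = range_ref/RMSEP, prl = RMSEP/lab_error,
    rpiq = (Q3-Q1)_ref/RMSEP.  Ratios are only populated when reference
    statistics are supplied.
    """

    rmsep: float
    r2_test: float
    rmsec: float | None = None
    rmsecv: float | None = None
    r2_cal: float | None = None
    r2_cv: float | None = None
    rpd: float | None = None
    rer: float | None = None
    prl: float | None = None
    rpiq: float | None = None


def _rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    reference_stats=None,
    rmsec: float | None = None,
    rmsecv: float | None = None,
    r2_cal: float | None = None,
    r2_cv: float | None = None,
) -> MetricBundle:
    """Prediction metrics for a test set.

    ``reference_stats`` is any object exposing ``sd``, ``range``,
    ``lab_error`` and ``iqr`` attributes for the reference population of
    the target (see :class:`granupls.evaluate.ReferenceStats`).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted are not aligned")
    rmsep = _rmse(obs, pred)
    bundle = MetricBundle(rmsep=rmsep, r2_test=_r2(obs, pred), rmsec=rmsec,
                          rmsecv=rmsecv, r2_cal=r2_cal, r2_cv=r2_cv)
    if reference_stats is not None:
        if rmsep == 0:
            raise ZeroDivisionError(
                "RMSEP is exactly 0; ratio metrics (RPD/RER/RPIQ) are undefined"
            )
        bundle.rpd = float(reference_stats.sd) / rmsep
        bundle.rer = float(reference_stats.range) / rmsep
        lab = float(reference_stats.lab_error)
        bundle.prl = rmsep / lab if lab > 0 else float("nan")
        bundle.rpiq = float(reference_stats.iqr) / rmsep
    return bundle
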