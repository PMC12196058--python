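"""Uninformative variable elimination for PLS (UVE-PLS).

Artificial noise variables (uniform, vanishing amplitude, fixed seed) are
appended to the predictor block; jackknifing the PLS coefficients over
the cross-validation submodels yields a stability value per variable,

    stability_j = mean(b_j) / SD(b_j)  over CV submodels.

The stability ratio is scale-free, so the tiny amplitude of the noise
columns does not matter — after autoscaling they compete with the real
predictors on equal footing and calibrate how large |stability| can get
by chance.  The retention cutoff is then searched on a grid: 20 linearly
spaced candidates from the smallest |stability| up to an interpreted
maximum (default: the (n_lv + 2)-th largest |stability| value), with
cutoff 0 prepended so the no-elimination model is always a candidate.
The cutoff with minimal refit RMSECV wins; ties go to the smaller cutoff
(retain more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import CVPlan, PLSModel, cross_validate_path, fit_pls, select_n_lv

__all__ = ["UVEResult", "uve_stabilities", "uve_select", "uve_pls_fit"]

_NOISE_AMPLITUDE = 1e-10


@dataclass
class UVEResult:
    """Stability spectrum and the outcome of the cutoff search."""

    stability: np.ndarray          # (p_real + n_noise,)
    n_real: int
    cutoffs_tried: np.ndarray
    rmsecv_at_cutoff: np.ndarray   # NaN where a cutoff retained no variables
    chosen_cutoff: float
    retained: np.ndarray           # bool over the real variables
    n_lv: int
    skipped_cutoffs: list[float]

    @property
    def real_stability(self) -> np.ndarray:
        return self.stability[: self.n_real]

    @property
    def noise_stability(self) -> np.ndarray:
        return self.stability[self.n_real:]


def _with_noise(X: np.ndarray, n_noise: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, _NOISE_AMPLITUDE, size=(X.shape[0], n_noise))
    return np.hstack([X, noise])


def uve_stabilities(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    n_lv: int,
    n_noise: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-variable jackknife stability over the CV submodels.

    Returns stabilities for the real variables followed by the appended
    noise variables (``n_noise`` defaults to the real predictor count).
    A variable with zero coefficient SD across submodels gets signed
    infinity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_noise is None:
        n_noise = X.shape[1]
    Xa = _with_noise(X, n_noise, seed)
    coefs = []
    for fold in range(plan.k):
        train = plan.folds != fold
        m = fit_pls(Xa[train], y[train], n_lv)
        coefs.append(m.B)
    C = np.asarray(coefs)
    mean = C.mean(axis=0)
    sd = C.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = mean / sd
    stab[np.isnan(stab)] = 0.0           # 0/0: never-moving zero coefficient
    return stab


def _max_cutoff(abs_stab: np.ndarray, n_lv: int, strategy: str) -> float:
    finite = abs_stab[np.isfinite(abs_stab)]
    if finite.size == 0:
        return 1.0
    if strategy == "top":
        return float(finite.max())
    if strategy == "rank":
        k = n_lv + 2
        srt = np.sort(finite)[::-1]
        return float(srt[min(k, srt.size) - 1])
    raise ValueError(f"unknown cutoff strategy {strategy!r}")


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    n_lv: int,
    n_noise: int | None = None,
    seed: int = 0,
    n_cutoffs: int = 20,
    cutoff_strategy: str = "rank",
) -> UVEResult:
    """Search the retention cutoff by refit RMSECV.

    ``cutoff_strategy='rank'`` caps the grid at the (n_lv + 2)-th largest
    |stability|; ``'top'`` uses the overall maximum instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    stab = uve_stabilities(X, y, plan, n_lv, n_noise=n_noise, seed=seed)
    abs_real = np.abs(stab[: X.shape[1]])
    abs_all = np.abs(stab)
    lo = float(abs_all[np.isfinite(abs_all)].min(initial=0.0))
    hi = _max_cutoff(abs_all, n_lv, cutoff_strategy)
    grid = np.unique(np.concatenate([[0.0], np.linspace(lo, hi, n_cutoffs)]))
    rmsecv = np.full(grid.size, np.nan)
    skipped: list[float] = []
    for i, cut in enumerate(grid):
        keep = abs_real >= cut
        if not keep.any():
            skipped.append(float(cut))
            continue
        lv = max(1, min(n_lv, int(keep.sum())))
        path, _ = cross_validate_path(X[:, keep], y, plan, lv)
        rmsecv[i] = float(path[lv - 1])
    if np.all(np.isnan(rmsecv)):
        raise ValueError("every cutoff retained zero variables")
    best = np.nanmin(rmsecv)
    # tie-break: smallest cutoff within tolerance of the minimum
    ties = np.flatnonzero(np.nan_to_num(rmsecv, nan=np.inf) <= best + 1e-12)
    chosen = float(grid[ties[0]])
    return UVEResult(
        stability=stab,
        n_real=X.shape[1],
        cutoffs_tried=grid,
        rmsecv_at_cutoff=rmsecv,
        chosen_cutoff=chosen,
        retained=abs_real >= chosen,
        n_lv=n_lv,
        skipped_cutoffs=skipped,
    )


def uve_pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    n_lv: int | None = None,
    max_lv: int = 15,
    seed: int = 0,
    cutoff_strategy: str = "rank",
) -> tuple[PLSModel, UVEResult]:
    """Full UVE-PLS: select variables, then fit only on the retained ones.

    The artificial noise columns never enter the returned model; the
    model's provenance records which real columns were retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_lv is None:
        n_lv = select_n_lv(X, y, plan, max_lv)
    result = uve_select(X, y, plan, n_lv, seed=seed, cutoff_strategy=cutoff_strategy)
    keep = np.flatnonzero(result.retained)
    lv = max(1, min(n_lv, keep.size))
    model = fit_pls(X[:, keep], y, lv, provenance={"retained_columns": keep})
    return model, result
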