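"""Batch outlier screening.

Two complementary routes identify aberrant batches before calibration:

* **PCA diagnostics** on the SNV spectra of the LOD-bearing rows: a
  modified Kaiser rule picks the PC count, Mahalanobis distances in PC
  score space flag individual spectra (default threshold 3), and SIMCA-
  style one-tailed t tests on squared distances give per-row membership
  p-values for the non-outlier class.
* **BBE-PLS** (backward batch elimination): an NIR-to-LOD PLS model is
  cross-validated; in each cycle the batch whose removal most lowers
  RMSECV is eliminated if a one-tailed equal-variance t-test on the
  squared CV residuals (full-model sample vs reduced-model sample) is
  significant at alpha (default 0.1).  Elimination stops at the first
  non-significant cycle.

The Kaiser score of a PC is ``n_variables x (fraction of variance
explained)`` — the eigenvalue of the correlation matrix when all columns
are autoscaled — so the classic "eigenvalue > 1" rule reads "score >= 1".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Campaign
from .preprocess import apply_scaling, fit_scaling, snv
from .pls import cross_validate_path, loo_plan, select_n_lv

__all__ = ["PCAModel", "OutlierReport", "fit_pca", "choose_n_pc",
           "mahalanobis_pc", "simca_p", "bbe_pls", "screen"]


@dataclass
class PCAModel:
    """PCA of a (scaled) data matrix with all components retained."""

    loadings: np.ndarray            # (p, k) columns = components
    explained_fraction: np.ndarray  # (k,) sums to 1
    scores: np.ndarray              # (n, k) for the fitted rows
    kaiser_scores: np.ndarray       # (k,) = n_variables * fraction
    mean: np.ndarray
    sd: np.ndarray                  # ones when scale_all=False

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    def transform(self, rows: np.ndarray, n_pc: int | None = None) -> np.ndarray:
        z = (np.atleast_2d(np.asarray(rows, dtype=float)) - self.mean) / self.sd
        t = z @ self.loadings
        return t if n_pc is None else t[:, :n_pc]


def fit_pca(rows: np.ndarray, scale_all: bool = True) -> PCAModel:
    """PCA by SVD; deterministic up to sign, fixed by making each loading's
    largest-magnitude entry positive."""
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    mean = X.mean(axis=0)
    if scale_all:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dead = np.where(sd == 0)[0].tolist()
            raise ValueError(f"zero-variance column(s) cannot be scaled: {dead}")
    else:
        sd = np.ones(X.shape[1])
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # Sign convention
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.full_like(var, 1.0 / var.size)
    return PCAModel(
        loadings=Vt.T,
        explained_fraction=frac,
        scores=U * s,
        kaiser_scores=X.shape[1] * frac,
        mean=mean,
        sd=sd,
    )


def choose_n_pc(
    m: PCAModel,
    kaiser_threshold: float = 1.0,
    use_scree: bool = True,
) -> int:
    """Modified Kaiser rule for the significant PC count.

    Returns the largest k whose Kaiser score meets ``kaiser_threshold``
    and (when ``use_scree``) whose log-eigenvalue drop to the next
    component exceeds the median of the later drops — i.e. the last
    component that both passes Kaiser and sits above a genuine scree
    elbow.  The strict Kaiser rule alone tends to overestimate; the scree
    condition trims trailing components whose scores hover just above the
    threshold.  Floor at 1.
    """
    scores = m.kaiser_scores
    k_max = scores.size
    passing = np.flatnonzero(scores >= kaiser_threshold)
    if passing.size == 0:
        return 1
    if not use_scree:
        return int(passing[-1]) + 1
    with np.errstate(divide="ignore"):
        log_ev = np.log(np.maximum(scores, 1e-300))
    drops = -np.diff(log_ev)          # drop from component k to k+1 (0-based k)
    best = 1
    for idx in passing:               # idx is 0-based component index
        if idx >= k_max - 1:
            continue                  # no later drops to compare against
        later = drops[idx + 1:]
        if later.size == 0:
            continue
        if drops[idx] > np.median(later):
            best = idx + 1
    return max(best, 1)


def mahalanobis_pc(
    m: PCAModel,
    n_pc: int,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Mahalanobis distance in the space of the first ``n_pc`` PC scores.

    The covariance is that of the fitted scores; ``rows`` defaults to the
    fitted rows themselves.
    """
    if n_pc > m.loadings.shape[1]:
        raise ValueError(f"model holds {m.loadings.shape[1]} components, asked {n_pc}")
    ref = m.scores[:, :n_pc]
    cov = np.cov(ref, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < n_pc:
        raise ValueError("singular score covariance; reduce n_pc")
    inv = np.linalg.inv(cov)
    t = ref if rows is None else m.transform(rows, n_pc)
    centered = t - ref.mean(axis=0)
    return np.sqrt(np.einsum("ij,jk,ik->i", centered, inv, centered))


def simca_p(
    distances_sq: np.ndarray,
    candidate: np.ndarray | None = None,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """One-tailed t-based membership p-values for the non-outlier class.

    ``reference`` holds the squared distances of the assumed non-outlier
    rows; each candidate squared distance d gets
    ``p = P(T_{n-1} >= (d - mean_ref) / (sd_ref * sqrt(1 + 1/n)))``,
    the predictive-interval tail probability for one new observation.
    A candidate at the reference mean gets p = 0.5; p decreases
    monotonically in d.
    """
    if reference is None:
        reference = np.asarray(distances_sq, dtype=float)
    else:
        reference = np.asarray(reference, dtype=float)
    if candidate is None:
        candidate = np.asarray(distances_sq, dtype=float)
    else:
        candidate = np.asarray(candidate, dtype=float)
    n = reference.size
    if n < 3:
        raise ValueError("reference set must have at least 3 rows")
    sd = reference.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance reference distances")
    t = (candidate - reference.mean()) / (sd * np.sqrt(1.0 + 1.0 / n))
    return stats.t.sf(t, df=n - 1)


# ---------------------------------------------------------------------------
# BBE-PLS


@dataclass
class OutlierReport:
    """Outcome of a screening run."""

    cycles: list[dict] = field(default_factory=list)
    surviving_ids: list[str] = field(default_factory=list)
    eliminated_ids: list[str] = field(default_factory=list)
    row_distances: dict[str, np.ndarray] = field(default_factory=dict)
    batch_simca_p: dict[str, float] = field(default_factory=dict)
    n_pc: int | None = None


def _lod_pool(c: Campaign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SNV spectra, LOD values and batch labels for all LOD-bearing rows."""
    spectra, values, labels = [], [], []
    for b in c.batches:
        rows = b.lod_rows
        if rows.size:
            spectra.append(b.spectra[rows])
            values.append(b.lod_values)
            labels.extend([b.batch_id] * rows.size)
    if not spectra:
        raise ValueError("campaign has no LOD measurements")
    return snv(np.vstack(spectra)), np.concatenate(values), np.asarray(labels)


def _squared_cv_residuals(X: np.ndarray, y: np.ndarray, max_lv: int) -> tuple[float, np.ndarray]:
    """LOO RMSECV at the CV-optimal component count, plus squared residuals."""
    plan = loo_plan(X.shape[0])
    cap = max(1, min(max_lv, X.shape[1], X.shape[0] - 2))
    rmsecv_path, resid = cross_validate_path(X, y, plan, cap)
    best = int(np.argmin(rmsecv_path))
    return float(rmsecv_path[best]), resid[:, best] ** 2


def bbe_pls(
    c: Campaign,
    alpha: float = 0.1,
    max_lv: int = 6,
) -> OutlierReport:
    """Backward batch elimination on the NIR-to-LOD PLS model.

    Each cycle: (i) LOO-CV RMSECV on all remaining rows; (ii) RMSECV with
    each batch left out in turn; (iii) the batch whose removal gives the
    lowest RMSECV is eliminated if the one-tailed equal-variance t-test
    comparing the full model's squared CV residuals against the reduced
    model's is significant (p < alpha); (iv) repeat until the first
    non-significant cycle.  The latent-variable count is re-selected by
    RMSECV minimum in every evaluation.
    """
    if len(c.batches) < 3:
        raise ValueError("BBE-PLS needs at least 3 batches")
    X_all, y_all, labels = _lod_pool(c)
    remaining = [b.batch_id for b in c.batches if b.batch_id in set(labels)]
    report = OutlierReport()
    while True:
        if len(remaining) <= 1:
            break  # hard stop: nothing left to compare
        keep = np.isin(labels, remaining)
        X, y, lab = X_all[keep], y_all[keep], labels[keep]
        rmsecv_full, sq_full = _squared_cv_residuals(X, y, max_lv)
        best = None
        for bid in remaining:
            sub = lab != bid
            if np.unique(lab[sub]).size < 2 or sub.sum() < 6:
                continue
            rmsecv_red, sq_red = _squared_cv_residuals(X[sub], y[sub], max_lv)
            if best is None or rmsecv_red < best[1]:
                best = (bid, rmsecv_red, sq_red)
        if best is None:
            break
        bid, rmsecv_red, sq_red = best
        p = float(stats.ttest_ind(sq_full, sq_red, equal_var=True,
                                  alternative="greater").pvalue)
        cycle = {
            "eliminated": bid,
            "rmsecv_before": rmsecv_full,
            "rmsecv_after": rmsecv_red,
            "p_value": p,
        }
        if p < alpha:
            report.cycles.append(cycle)
            report.eliminated_ids.append(bid)
            remaining = [r for r in remaining if r != bid]
        else:
            cycle["eliminated"] = None
            report.cycles.append(cycle)
            break
    report.surviving_ids = remaining
    return report


def screen(
    c: Campaign,
    alpha: float = 0.1,
    mahalanobis_threshold: float = 3.0,
    kaiser_threshold: float = 1.0,
    max_lv: int = 6,
) -> OutlierReport:
    """Full screening pass: PCA/Mahalanobis/SIMCA diagnostics plus BBE-PLS.

    Per-batch SIMCA p-values are the median of the batch rows' membership
    p-values, with the sub-threshold rows as the reference population.
    """
    X, _, labels = _lod_pool(c)
    pca = fit_pca(X, scale_all=True)
    n_pc = choose_n_pc(pca, kaiser_threshold=kaiser_threshold)
    n_pc = min(max(n_pc, 2), pca.scores.shape[1])
    dist = mahalanobis_pc(pca, n_pc)
    inside = dist <= mahalanobis_threshold
    if inside.sum() >= 3 and np.ptp(dist[inside]) > 0:
        pvals = simca_p(dist**2, candidate=dist**2, reference=dist[inside] ** 2)
    else:
        pvals = np.full(dist.size, np.nan)
    report = bbe_pls(c, alpha=alpha, max_lv=max_lv)
    report.n_pc = n_pc
    for bid in dict.fromkeys(labels):
        sel = labels == bid
        report.row_distances[bid] = dist[sel]
        report.batch_simca_p[bid] = float(np.median(pvals[sel]))
    return report
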