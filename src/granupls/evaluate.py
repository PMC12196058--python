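"""Modeling approaches, split plans and model comparison.

Two families of granule-size prediction schemes are implemented:

* **MA 1** — within-batch endpoint prediction.  For each batch, the last
  10% of rows in time order form the external test set; within the first
  90%, every 10th row is an internal (easy) test row and the rest train
  the model.  **MA 1-add** instead holds out the last half of the final
  zero-spray (drying) run.
* **MA 2** — across-batch prediction.  The campaign's batches are split
  into folds of whole test batches: 3 per fold (MA 2a), 1 per fold, i.e.
  leave-one-batch-out (MA 2b), or 4 per fold (MA 2c); the remaining
  batches train the model.

Three predictor sets are compared on each scheme: the 256 SNV spectral
channels (``nir``), the 17 process parameters (``pars``), and their
union (``merged``, 273 predictors; optionally 274 with the seven-point
moving-average spray rate).  Latent-variable counts are selected by
sequential cross-validation on the training rows only; scaling always
uses train statistics, so no test row leaks into any model that predicts
it.  Ratio metrics (RPD/RER/PRL/RPIQ) are computed against the reference
population statistics of the non-outlier campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import PARAMETER_NAMES, SIZE_NAMES, BatchRecord, Campaign
from .preprocess import moving_average, snv
from .pls import (
    CVPlan,
    MetricBundle,
    PLSModel,
    block_plan,
    cross_validate_path,
    fit_pls,
    metrics,
    predict,
    sequential_plan,
)

__all__ = [
    "SplitPlan",
    "ReferenceStats",
    "EvalReport",
    "ma1_split",
    "ma1add_split",
    "block_cv_plan",
    "ma2_folds",
    "predictor_matrix",
    "run_comparison",
    "paired_test",
    "coefficient_importance",
    "lod_holdout",
]

APPROACH_TEST_SIZE = {"ma2a": 3, "ma2b": 1, "ma2c": 4}
PREDICTOR_SETS = ("nir", "pars", "merged")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train / internal-test / external-test indices."""

    train: np.ndarray
    internal_test: np.ndarray
    external_test: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        parts = [np.asarray(s, dtype=int) for s in
                 (self.train, self.internal_test, self.external_test)]
        object.__setattr__(self, "train", parts[0])
        object.__setattr__(self, "internal_test", parts[1])
        object.__setattr__(self, "external_test", parts[2])
        allidx = np.concatenate(parts)
        if np.unique(allidx).size != allidx.size:
            raise ValueError("split sets overlap")

    @property
    def n_rows(self) -> int:
        return self.train.size + self.internal_test.size + self.external_test.size


@dataclass(frozen=True)
class ReferenceStats:
    """Population statistics of a size target used for the ratio metrics.

    ``lab_error`` is the SD of the per-batch endpoint values — the
    batch-to-batch spread of the final granule size, playing the role of
    the laboratory reference uncertainty.
    """

    sd: float
    min: float
    max: float
    iqr: float
    lab_error: float

    @property
    def range(self) -> float:
        return self.max - self.min

    @classmethod
    def from_campaign(cls, c: Campaign, target: str = "dv50") -> "ReferenceStats":
        j = SIZE_NAMES.index(target)
        vals = np.concatenate([b.sizes[:, j] for b in c.batches])
        endpoints = np.array([b.sizes[-1, j] for b in c.batches])
        q1, q3 = np.percentile(vals, [25, 75])
        return cls(
            sd=float(vals.std(ddof=1)),
            min=float(vals.min()),
            max=float(vals.max()),
            iqr=float(q3 - q1),
            lab_error=float(endpoints.std(ddof=1)) if endpoints.size > 1 else 0.0,
        )


# ---------------------------------------------------------------------------
# Split plans


def _internal_split(head: int, scheme: str, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Within the first ``head`` rows: every 10th (1-based) is internal test."""
    idx = np.arange(head)
    internal = idx[9::10]
    train = np.setdiff1d(idx, internal)
    return train + offset, internal + offset


def ma1_split(b: BatchRecord) -> SplitPlan:
    """Endpoint scheme: external = last floor(n/10) rows of the batch."""
    n = b.n_rows
    if n < 20:
        raise ValueError(f"batch {b.batch_id!r} has {n} rows; need >= 20")
    n_ext = n // 10
    head = n - n_ext
    train, internal = _internal_split(head, "ma1")
    return SplitPlan(train, internal, np.arange(head, n), "ma1")


def ma1add_split(b: BatchRecord) -> SplitPlan:
    """External = last half of the terminal zero-spray (drying) run."""
    n = b.n_rows
    drying = b.phase == "drying"
    if not drying[-1]:
        raise ValueError(f"batch {b.batch_id!r} does not end in a drying run")
    start = n
    while start > 0 and drying[start - 1]:
        start -= 1
    run = n - start
    n_ext = run // 2
    if n_ext < 1:
        raise ValueError(f"batch {b.batch_id!r}: terminal drying run too short")
    head = n - n_ext
    train, internal = _internal_split(head, "ma1add")
    return SplitPlan(train, internal, np.arange(head, n), "ma1add")


def block_cv_plan(n_train_rows: int, k: int) -> CVPlan:
    """Contiguous-block CV over the training rows (see pls.block_plan)."""
    return block_plan(n_train_rows, k)


def ma2_folds(
    c: Campaign,
    train_size: int,
    test_size: int,
) -> list[tuple[list[str], list[str]]]:
    """Partition batch ids into whole-batch test groups, campaign order kept."""
    ids = c.batch_ids
    n = len(ids)
    if train_size + test_size != n:
        raise ValueError(f"train_size + test_size must equal {n} batches")
    if n % test_size != 0:
        raise ValueError(
            f"{n} batches cannot be grouped into equal test sets of {test_size}; "
            "drop batches or pick a divisor (residue handling: choose test_size "
            f"in {[d for d in range(1, n + 1) if n % d == 0]})"
        )
    folds = []
    for start in range(0, n, test_size):
        test = ids[start:start + test_size]
        train = [i for i in ids if i not in test]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# Predictor assembly


def predictor_matrix(
    b: BatchRecord,
    which: str,
    use_spray_rate: bool = False,
) -> np.ndarray:
    """Assemble a batch's predictor matrix for one predictor set.

    ``nir`` = 256 SNV channels; ``pars`` = 17 process parameters;
    ``merged`` = both (273).  With ``use_spray_rate`` the seven-point
    moving average of the spray rate is appended to ``pars``/``merged``.
    """
    n_base = len(PARAMETER_NAMES)
    if which == "nir":
        return snv(b.spectra)
    pars = b.params[:, :n_base]
    if use_spray_rate:
        if not b.has_spray_rate:
            raise ValueError(f"batch {b.batch_id!r} carries no spray-rate column")
        sr = moving_average(b.params[:, n_base], 7)
        pars = np.column_stack([pars, sr])
    if which == "pars":
        return pars
    if which == "merged":
        return np.hstack([snv(b.spectra), pars])
    raise ValueError(f"unknown predictor set {which!r}")


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    """Per-unit (batch or fold), per-target, per-predictor-set results."""

    approach: str
    targets: tuple[str, ...]
    predictor_sets: tuple[str, ...]
    #: results[target][pset][unit] -> dict with 'external' MetricBundle,
    #: optional 'internal' MetricBundle, 'n_lv', and for MA 2 'per_batch'
    #: RMSEPs of individual test batches.
    results: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)
    merged_models: list[PLSModel] = field(default_factory=list)
    paired_p: dict = field(default_factory=dict)

    def rmsep_by_unit(self, target: str, pset: str) -> dict[str, float]:
        return {u: r["external"].rmsep for u, r in self.results[target][pset].items()}

    def per_batch_rmsep(self, target: str, pset: str) -> dict[str, float]:
        """External RMSEP per individual batch (MA 2 folds are expanded)."""
        out: dict[str, float] = {}
        for unit, r in self.results[target][pset].items():
            if "per_batch" in r:
                out.update(r["per_batch"])
            else:
                out[unit] = r["external"].rmsep
        return out

    def mean_rmsep(self, target: str, pset: str) -> float:
        return float(np.mean(list(self.per_batch_rmsep(target, pset).values())))


def _fit_and_score(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    cv_k: int,
    max_lv: int,
    cv_scheme: str = "sequential",
) -> tuple[PLSModel, int, float]:
    n = X_tr.shape[0]
    k = min(cv_k, n)
    plan = sequential_plan(n, k) if cv_scheme == "sequential" else block_plan(n, k)
    smallest = min(int((plan.folds != f).sum()) for f in range(plan.k))
    cap = max(1, min(max_lv, X_tr.shape[1], smallest - 1))
    path, _ = cross_validate_path(X_tr, y_tr, plan, cap)
    n_lv = int(np.flatnonzero(path <= path.min() + 1e-12)[0]) + 1
    return fit_pls(X_tr, y_tr, n_lv), n_lv, float(path[n_lv - 1])


def run_comparison(
    c: Campaign,
    approach: str = "ma1",
    predictor_sets: tuple[str, ...] = ("nir", "merged"),
    targets: tuple[str, ...] = ("dv50",),
    cv_k: int = 10,
    max_lv: int = 15,
    cv_scheme: str = "sequential",
    use_spray_rate: bool = False,
) -> EvalReport:
    """Run one modeling approach over the campaign.

    The campaign passed in should already have outlier batches removed
    (or deliberately kept, when studying their effect).
    """
    for t in targets:
        if t not in SIZE_NAMES:
            raise ValueError(f"unknown target column {t!r}")
    report = EvalReport(approach=approach, targets=tuple(targets),
                        predictor_sets=tuple(predictor_sets))
    for t in targets:
        report.reference[t] = ReferenceStats.from_campaign(c, t)
        report.results[t] = {p: {} for p in predictor_sets}

    if approach in ("ma1", "ma1add"):
        splitter = ma1_split if approach == "ma1" else ma1add_split
        for b in c.batches:
            plan = splitter(b)
            for pset in predictor_sets:
                X = predictor_matrix(b, pset, use_spray_rate)
                for t in targets:
                    y = b.sizes[:, SIZE_NAMES.index(t)]
                    model, n_lv, rmsecv = _fit_and_score(
                        X[plan.train], y[plan.train], cv_k, max_lv, cv_scheme)
                    ext = metrics(y[plan.external_test],
                                  predict(model, X[plan.external_test]),
                                  report.reference[t], rmsecv=rmsecv)
                    inte = metrics(y[plan.internal_test],
                                   predict(model, X[plan.internal_test]))
                    report.results[t][pset][b.batch_id] = {
                        "external": ext, "internal": inte, "n_lv": n_lv,
                    }
                    if pset == "merged" and t == targets[0]:
                        report.merged_models.append(model)
    elif approach in APPROACH_TEST_SIZE:
        test_size = APPROACH_TEST_SIZE[approach]
        folds = ma2_folds(c, len(c.batches) - test_size, test_size)
        for train_ids, test_ids in folds:
            unit = "+".join(test_ids)
            for pset in predictor_sets:
                X_tr = np.vstack([predictor_matrix(c.batch(i), pset, use_spray_rate)
                                  for i in train_ids])
                for t in targets:
                    j = SIZE_NAMES.index(t)
                    y_tr = np.concatenate([c.batch(i).sizes[:, j] for i in train_ids])
                    model, n_lv, rmsecv = _fit_and_score(X_tr, y_tr, cv_k, max_lv,
                                                         cv_scheme)
                    per_batch, obs_all, pred_all = {}, [], []
                    for i in test_ids:
                        Xi = predictor_matrix(c.batch(i), pset, use_spray_rate)
                        yi = c.batch(i).sizes[:, j]
                        pi = predict(model, Xi)
                        per_batch[i] = float(np.sqrt(np.mean((yi - pi) ** 2)))
                        obs_all.append(yi)
                        pred_all.append(pi)
                    ext = metrics(np.concatenate(obs_all), np.concatenate(pred_all),
                                  report.reference[t], rmsecv=rmsecv)
                    report.results[t][pset][unit] = {
                        "external": ext, "n_lv": n_lv, "per_batch": per_batch,
                    }
                    if pset == "merged" and t == targets[0]:
                        report.merged_models.append(model)
    else:
        raise ValueError(f"unknown approach {approach!r}")

    # Paired one-tailed comparisons between predictor sets, per target.
    for t in targets:
        for a in predictor_sets:
            for bset in predictor_sets:
                if a >= bset:
                    continue
                ra = report.per_batch_rmsep(t, a)
                rb = report.per_batch_rmsep(t, bset)
                common = sorted(set(ra) & set(rb))
                if len(common) >= 2:
                    va = np.array([ra[i] for i in common])
                    vb = np.array([rb[i] for i in common])
                    try:
                        report.paired_p[(t, a, bset)] = paired_test(va, vb)
                    except ValueError:
                        pass
    return report


def paired_test(rmsep_a: np.ndarray, rmsep_b: np.ndarray) -> float:
    """One-tailed paired t-test p-value for 'a predicts better than b'.

    All-zero differences (identical performance) return 0.5: the data
    carry no evidence in either direction.
    """
    a = np.asarray(rmsep_a, dtype=float)
    b = np.asarray(rmsep_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.5
    if d.std(ddof=1) == 0:
        raise ValueError("degenerate test: nonzero differences with zero variance")
    return float(stats.ttest_rel(a, b, alternative="less").pvalue)


def coefficient_importance(
    models: list[PLSModel],
    parameter_names: tuple[str, ...] = PARAMETER_NAMES,
    n_spectral: int = 256,
) -> dict:
    """Variable importance as mean |regression coefficient| across models.

    Coefficients are taken on the autoscaled predictor scale so spectral
    channels and process parameters are comparable.  Returns the spectral
    block's mean, SD and mean + 2 SD margin, the wavelengths/parameters
    exceeding it, and the parameters ranked by importance.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    rows = []
    for m in models:
        b_scaled = np.abs(m.B * m.scaling.sd)     # back to autoscaled-X scale
        rows.append(b_scaled)
    mean_abs = np.mean(rows, axis=0)
    spec = mean_abs[:n_spectral]
    pars = mean_abs[n_spectral:]
    margin = float(spec.mean() + 2 * spec.std(ddof=1))
    order = np.argsort(pars)[::-1]
    ranking = [(parameter_names[i], float(pars[i])) for i in order
               if i < len(parameter_names)]
    return {
        "mean_abs": mean_abs,
        "spectral_mean": float(spec.mean()),
        "spectral_sd": float(spec.std(ddof=1)),
        "margin": margin,
        "n_spectral_above_margin": int((spec > margin).sum()),
        "parameter_ranking": ranking,
    }


def lod_holdout(c: Campaign, cv_k: int = 10, max_lv: int = 10) -> dict:
    """NIR-to-LOD calibration with the sequential one-fifth hold-out.

    All LOD-bearing rows are pooled in campaign/time order; every 5th row
    (1-based) is a test sample, the rest calibrate the model.
    """
    spectra, values = [], []
    for b in c.batches:
        rows = b.lod_rows
        if rows.size:
            spectra.append(snv(b.spectra[rows]))
            values.append(b.lod_values)
    X = np.vstack(spectra)
    y = np.concatenate(values)
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 LOD rows, have {n}")
    test = np.arange(4, n, 5)
    train = np.setdiff1d(np.arange(n), test)
    model, n_lv, rmsecv = _fit_and_score(X[train], y[train], cv_k, max_lv)
    fitted = predict(model, X[train])
    pred = predict(model, X[test])
    test_m = metrics(y[test], pred)
    return {
        "n_train": int(train.size),
        "n_test": int(test.size),
        "n_lv": n_lv,
        "rmsec": float(np.sqrt(np.mean((y[train] - fitted) ** 2))),
        "rmsecv": rmsecv,
        "rmsep": test_m.rmsep,
        "r2_cal": 1.0 - float(np.sum((y[train] - fitted) ** 2)
                              / np.sum((y[train] - y[train].mean()) ** 2)),
        "r2_test": test_m.r2_test,
        "train_index": train,
        "test_index": test,
    }
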