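"""Spectral and predictor preprocessing.

Three operations used throughout the pipeline:

* SNV (standard normal variate): per-spectrum centering and scaling to
  unit sample SD, removing additive offset and multiplicative scatter.
* Column autoscaling with statistics learned on the training rows only,
  never on target columns (targets are predicted on their natural scale).
* A centered moving average (default 7 points) used to smooth the spray
  rate when it enters the model as an 18th predictor.

Sample (ddof=1) standard deviations are used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["DegenerateSpectrumError", "ScalingParams", "snv", "fit_scaling",
           "apply_scaling", "moving_average"]


class DegenerateSpectrumError(ValueError):
    """Raised for a constant spectrum, whose SNV is undefined."""


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate of one or many spectra.

    Accepts a single spectrum ``(p,)`` or a stack ``(n, p)``; each row is
    centered and divided by its sample SD (ddof=1).
    """
    x = np.asarray(spectrum, dtype=float)
    one = x.ndim == 1
    x = np.atleast_2d(x)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        raise DegenerateSpectrumError("constant spectrum has no SNV transform")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if one else out


@dataclass
class ScalingParams:
    """Train-set column means/SDs; target columns pass through untouched."""

    mean: np.ndarray
    sd: np.ndarray
    scaled_columns: np.ndarray          # bool mask, False for excluded targets
    targets_excluded: bool = True

    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.scaled_columns = np.asarray(self.scaled_columns, dtype=bool)
        self.n_columns = self.mean.size


def fit_scaling(rows: np.ndarray, exclude: Sequence[int] = ()) -> ScalingParams:
    """Learn per-column autoscaling statistics on training rows.

    ``exclude`` lists target-column indices that must pass through
    unscaled.  A zero-variance column that would be scaled is an error —
    silently epsilon-fixing it would hide a broken predictor.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    p = rows.shape[1]
    mask = np.ones(p, dtype=bool)
    mask[list(exclude)] = False
    mean = np.where(mask, rows.mean(axis=0), 0.0)
    sd = np.where(mask, rows.std(axis=0, ddof=1), 1.0)
    dead = np.where(mask & (sd == 0))[0]
    if dead.size:
        raise ValueError(f"zero-variance column(s) cannot be autoscaled: {dead.tolist()}")
    return ScalingParams(mean, sd, mask, targets_excluded=bool(len(list(exclude))))


def apply_scaling(params: ScalingParams, rows: np.ndarray) -> np.ndarray:
    """Apply train-set scaling to new rows (no refitting, hence no leakage)."""
    rows = np.asarray(rows, dtype=float)
    if rows.shape[-1] != params.n_columns:
        raise ValueError(
            f"expected {params.n_columns} columns, got {rows.shape[-1]}"
        )
    return (rows - params.mean) / params.sd


def moving_average(series: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered moving average; edge windows truncate to available points."""
    x = np.asarray(series, dtype=float)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd count")
    n = x.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
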