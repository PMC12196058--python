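"""Batch data model and CSV interchange for fluid-bed granulation campaigns.

A campaign is a set of granulation batches monitored inline: every
acquisition instant yields one row holding a 256-channel NIR absorbance
spectrum (1081-2122 nm), the fluid-bed process parameters, and the five
volumetric granule-size percentiles (Dv10..Dv90, um) from the imaging
probe.  Loss-on-drying (LOD) moisture measurements are sparse: only a
handful of rows per batch carry a gravimetric reference value.

On disk a campaign is a directory with one CSV table per batch plus a
JSON manifest; the CSV schema is the single interchange format used by
the rest of the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_WAVELENGTHS",
    "WAVELENGTH_MIN_NM",
    "WAVELENGTH_MAX_NM",
    "PARAMETER_NAMES",
    "SIZE_NAMES",
    "SpectralGrid",
    "ProcessParameterSet",
    "BatchRecord",
    "Campaign",
    "SchemaError",
    "ValidationError",
    "default_grid",
    "read_campaign",
    "write_campaign",
    "pool_rows",
]

N_WAVELENGTHS = 256
WAVELENGTH_MIN_NM = 1081.0
WAVELENGTH_MAX_NM = 2122.0

#: Canonical fluid-bed process parameters, in fixed column order.
#: PHT = combined pressure/humidity/temperature air probe (inlet/outlet).
PARAMETER_NAMES: tuple[str, ...] = (
    "airflow_rate",             # m3/h
    "runtime",                  # s since batch start
    "atomizing_pressure",       # bar
    "pht_out_temp",             # degC
    "inlet_air_temp",           # degC
    "plenum_pressure",
    "exhaust_pressure",
    "pht_in_abs_hum",
    "pht_in_rel_hum",           # %
    "pht_out_rel_hum",          # %
    "pht_out_abs_hum",
    "exhaust_temp",             # degC
    "pht_out_pressure",
    "product_temp",             # degC
    "pht_in_pressure",
    "prod_filt_diff_pressure",  # mbar
    "pht_in_temp",              # degC
)

SPRAY_RATE_NAME = "spray_rate"  # g/min, optional 18th predictor

SIZE_NAMES: tuple[str, ...] = ("dv10", "dv25", "dv50", "dv75", "dv90")

PHASES = ("spray", "drying")


class SchemaError(ValueError):
    """A table is missing a required column or has an incompatible layout."""


class ValidationError(ValueError):
    """Data violate a batch/campaign invariant (ordering, range, alignment)."""


@dataclass(frozen=True)
class SpectralGrid:
    """The 256-point NIR wavelength grid, strictly increasing in 1081-2122 nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size != N_WAVELENGTHS:
            raise ValidationError(
                f"spectral grid must have {N_WAVELENGTHS} wavelengths, got {w.size}"
            )
        if not np.all(np.diff(w) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if w[0] < WAVELENGTH_MIN_NM or w[-1] > WAVELENGTH_MAX_NM:
            raise ValidationError(
                f"wavelengths must lie in [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )

    def __len__(self) -> int:
        return N_WAVELENGTHS

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.wavelengths_nm, other.wavelengths_nm
        )


def default_grid() -> SpectralGrid:
    """Evenly spaced 256-point grid spanning the instrument range."""
    return SpectralGrid(np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_WAVELENGTHS))


@dataclass(frozen=True)
class ProcessParameterSet:
    """Ordered canonical process-parameter names, optionally with spray rate."""

    include_spray_rate: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        if self.include_spray_rate:
            return PARAMETER_NAMES + (SPRAY_RATE_NAME,)
        return PARAMETER_NAMES

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class BatchRecord:
    """One batch's aligned inline time series.

    All row-wise arrays share the same length; ``lod`` is a sparse list of
    ``(row_index, lod_percent)`` pairs because moisture reference values
    exist only where a sample was pulled for the moisture analyzer.
    """

    batch_id: str
    times: np.ndarray                      # s from batch start, non-decreasing
    spectra: np.ndarray                    # (n, 256) absorbance
    params: np.ndarray                     # (n, 17 or 18)
    sizes: np.ndarray                      # (n, 5) Dv10..Dv90 in um
    lod: list[tuple[int, float]] = field(default_factory=list)
    phase: np.ndarray = None               # (n,) str in {"spray","drying"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.params = np.asarray(self.params, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.phase is None:
            self.phase = np.full(self.n_rows, "spray", dtype=object)
        self.phase = np.asarray(self.phase, dtype=object)
        self.validate()

    @property
    def n_rows(self) -> int:
        return self.spectra.shape[0]

    @property
    def has_spray_rate(self) -> bool:
        return self.params.shape[1] == len(PARAMETER_NAMES) + 1

    @property
    def lod_rows(self) -> np.ndarray:
        return np.array([i for i, _ in self.lod], dtype=int)

    @property
    def lod_values(self) -> np.ndarray:
        return np.array([v for _, v in self.lod], dtype=float)

    def validate(self) -> None:
        n = self.n_rows
        if self.spectra.ndim != 2 or self.spectra.shape[1] != N_WAVELENGTHS:
            raise ValidationError(
                f"batch {self.batch_id!r}: spectra must be (n, {N_WAVELENGTHS})"
            )
        n_par = self.params.shape[1] if self.params.ndim == 2 else -1
        if n_par not in (len(PARAMETER_NAMES), len(PARAMETER_NAMES) + 1):
            raise ValidationError(
                f"batch {self.batch_id!r}: params must have 17 or 18 columns"
            )
        for name, arr, width in (
            ("times", self.times, None),
            ("sizes", self.sizes, len(SIZE_NAMES)),
            ("phase", self.phase, None),
        ):
            rows = arr.shape[0]
            if rows != n:
                raise ValidationError(
                    f"batch {self.batch_id!r}: {name} has {rows} rows, expected {n}"
                )
            if width is not None and arr.shape[1] != width:
                raise ValidationError(f"batch {self.batch_id!r}: {name} width mismatch")
        if self.params.shape[0] != n:
            raise ValidationError(f"batch {self.batch_id!r}: params row mismatch")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError(f"batch {self.batch_id!r}: times must be non-decreasing")
        if np.any(self.sizes <= 0):
            raise ValidationError(f"batch {self.batch_id!r}: granule sizes must be > 0")
        bad = np.where(np.any(np.diff(self.sizes, axis=1) < 0, axis=1))[0]
        if bad.size:
            raise ValidationError(
                f"batch {self.batch_id!r}, row {bad[0]}: Dv percentiles must satisfy "
                "Dv10 <= Dv25 <= Dv50 <= Dv75 <= Dv90"
            )
        for i, v in self.lod:
            if not (0 <= i < n):
                raise ValidationError(f"batch {self.batch_id!r}: LOD row {i} out of range")
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"batch {self.batch_id!r}: LOD {v} outside [0, 100]%")
        bad_phase = set(np.unique(self.phase)) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"batch {self.batch_id!r}: unknown phase labels {bad_phase}")
        if self.has_spray_rate:
            spray = self.params[:, -1]
            drying = self.phase == "drying"
            if np.any(drying & (spray != 0)) or np.any(~drying & (spray <= 0)):
                raise ValidationError(
                    f"batch {self.batch_id!r}: phase must be 'drying' exactly where "
                    "spray_rate is 0"
                )


@dataclass
class Campaign:
    """An ordered collection of batches sharing one grid and parameter set."""

    batches: list[BatchRecord]
    grid: SpectralGrid
    paramset: ProcessParameterSet

    def __post_init__(self) -> None:
        ids = [b.batch_id for b in self.batches]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate batch ids in campaign: {ids}")
        width = len(self.paramset)
        for b in self.batches:
            if b.params.shape[1] != width:
                raise ValidationError(
                    f"batch {b.batch_id!r} has {b.params.shape[1]} parameter columns, "
                    f"campaign declares {width}"
                )

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    def batch(self, batch_id: str) -> BatchRecord:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(f"unknown batch id {batch_id!r}")

    def subset(self, ids: Sequence[str]) -> "Campaign":
        keep = [self.batch(i) for i in ids]
        return Campaign(keep, self.grid, self.paramset)

    @property
    def n_rows(self) -> int:
        return sum(b.n_rows for b in self.batches)


# ---------------------------------------------------------------------------
# CSV interchange


def _wavelength_cols(grid: SpectralGrid) -> list[str]:
    return [format(w, ".6g") for w in grid.wavelengths_nm]


def _batch_frame(b: BatchRecord, grid: SpectralGrid, paramset: ProcessParameterSet) -> pd.DataFrame:
    lod = np.full(b.n_rows, np.nan)
    for i, v in b.lod:
        lod[i] = v
    cols: dict[str, np.ndarray] = {"time_s": b.times}
    cols.update({c: b.spectra[:, j] for j, c in enumerate(_wavelength_cols(grid))})
    cols.update({name: b.params[:, j] for j, name in enumerate(paramset.names)})
    cols.update({name: b.sizes[:, j] for j, name in enumerate(SIZE_NAMES)})
    cols["lod"] = lod
    cols["phase"] = b.phase
    return pd.DataFrame(cols)


def write_campaign(c: Campaign, path: str | Path) -> list[Path]:
    """Write one CSV per batch plus a JSON manifest; returns written paths.

    Floats are written in ``repr`` round-trip precision so a read-back
    reproduces every value bit-for-bit.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for b in c.batches:
        f = path / f"batch_{b.batch_id}.csv"
        _batch_frame(b, c.grid, c.paramset).to_csv(f, index=False, float_format="%.17g")
        written.append(f)
    manifest = {
        "batch_ids": c.batch_ids,
        "wavelengths_nm": [float(w) for w in c.grid.wavelengths_nm],
        "parameters": list(c.paramset.names),
        "include_spray_rate": c.paramset.include_spray_rate,
    }
    mf = path / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=1))
    written.append(mf)
    return written


def read_campaign(path: str | Path) -> Campaign:
    """Read a campaign directory written by :func:`write_campaign`."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise SchemaError(f"no manifest.json under {path}")
    manifest = json.loads(mf.read_text())
    grid = SpectralGrid(np.asarray(manifest["wavelengths_nm"], dtype=float))
    paramset = ProcessParameterSet(bool(manifest.get("include_spray_rate", False)))
    wl_cols = _wavelength_cols(grid)
    batches: list[BatchRecord] = []
    for bid in manifest["batch_ids"]:
        f = path / f"batch_{bid}.csv"
        if not f.exists():
            raise SchemaError(f"manifest lists batch {bid!r} but {f.name} is missing")
        df = pd.read_csv(f, float_precision="round_trip")
        required = ["time_s", *wl_cols, *paramset.names, *SIZE_NAMES, "lod", "phase"]
        missing = [col for col in required if col not in df.columns]
        if missing:
            raise SchemaError(f"{f.name}: missing column(s) {missing}")
        lod_col = df["lod"].to_numpy(dtype=float)
        lod = [(int(i), float(v)) for i, v in enumerate(lod_col) if np.isfinite(v)]
        batches.append(
            BatchRecord(
                batch_id=str(bid),
                times=df["time_s"].to_numpy(dtype=float),
                spectra=df[wl_cols].to_numpy(dtype=float),
                params=df[list(paramset.names)].to_numpy(dtype=float),
                sizes=df[list(SIZE_NAMES)].to_numpy(dtype=float),
                lod=lod,
                phase=df["phase"].to_numpy(dtype=object),
            )
        )
    return Campaign(batches, grid, paramset)


# ---------------------------------------------------------------------------
# Row pooling


def pool_rows(
    c: Campaign,
    which: Iterable[str] | None = None,
    columns: str = "all",
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Concatenate rows of selected batches into one matrix with provenance.

    Parameters
    ----------
    which
        Batch ids to pool (campaign order is preserved); ``None`` pools all.
    columns
        ``"spectra"``, ``"params"``, ``"sizes"`` or ``"all"`` (horizontal
        concatenation spectra | params | sizes).

    Returns
    -------
    matrix, provenance
        ``provenance[k] == (batch_id, row_index)`` for pooled row ``k``.
    """
    ids = c.batch_ids if which is None else list(which)
    order = {bid: k for k, bid in enumerate(c.batch_ids)}
    for bid in ids:
        if bid not in order:
            raise KeyError(f"unknown batch id {bid!r}")
    ids = sorted(ids, key=order.__getitem__)
    blocks, prov = [], []
    for bid in ids:
        b = c.batch(bid)
        if columns == "spectra":
            m = b.spectra
        elif columns == "params":
            m = b.params
        elif columns == "sizes":
            m = b.sizes
        elif columns == "all":
            m = np.hstack([b.spectra, b.params, b.sizes])
        else:
            raise ValueError(f"unknown column selector {columns!r}")
        blocks.append(m)
        prov.extend((bid, i) for i in range(b.n_rows))
    if not blocks:
        return np.empty((0, 0)), []
    return np.vstack(blocks), prov
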