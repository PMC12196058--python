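"""Synthetic fluid-bed granulation campaigns.

The generator is statistical, not mechanistic: it reproduces the data
*structure* the downstream chemometrics assume, so every stage of the
pipeline can be exercised and its recovery properties measured without
access to plant data.

Each batch runs a spray phase followed by a drying phase.  Two latent
trajectories drive everything:

* moisture (%): rises toward a wetting-dominated equilibrium during
  spraying, decays (faster at high airflow) during drying;
* median granule size Dv50 (um): grows during spraying toward a plateau
  set by the spray rate and modulated monotonically by airflow and
  atomizing pressure, then shrinks mildly (attrition) during drying.

The remaining size percentiles are fixed span multiples of Dv50.  Process
parameters are setpoints plus AR(1) noise; several (exhaust/product
temperatures, outlet humidities) are tied to the latents so the parameter
block genuinely carries process-state information.  Spectra are built on
the 256-point grid from a particle-size-dependent baseline (offset plus
wavelength slope, read with an autocorrelated relative error and a
dry-bed consolidation bias), fixed solid-component Gaussian bands, water
bands at 1450/1934 nm scaled by moisture, a per-row multiplicative
scatter factor, AR(1) baseline/slope drift and additive Gaussian noise.
Sparse LOD reference values are the moisture latent plus measurement
error.

Batch duration is fixed; a smaller row count therefore means coarser
sampling of the same process, so endpoint sizes do not depend on the row
budget.
"""

from __future__ import annotations

import zlib

from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    PARAMETER_NAMES,
    BatchRecord,
    Campaign,
    ProcessParameterSet,
    SpectralGrid,
    default_grid,
)

__all__ = ["SimConfig", "GroundTruth", "ConfigError", "simulate_batch",
           "simulate_campaign", "inject_outlier_batch", "spectral_model"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Setpoint ranges explored across batches (airflow span matches the pilot
# unit's operating window; the others are plausible fluid-bed values).
_AIRFLOW_RANGE = (18.7, 36.0)       # m3/h
_ATOMIZING_RANGE = (1.0, 3.0)       # bar
_INLET_TEMP_RANGE = (50.0, 75.0)    # degC
_SPRAY_RATE_RANGE = (18.0, 22.0)   # g/min

_BATCH_DURATION_S = 5000.0

#: Dv10/Dv25/Dv50/Dv75/Dv90 as multiples of Dv50.
SPAN_FACTORS = np.array([0.45, 0.7, 1.0, 1.4, 1.9])

#: Solid-component absorbance bands: (center nm, amplitude, sigma nm).
_COMPONENT_BANDS = ((1200.0, 0.30, 60.0), (1700.0, 0.45, 60.0), (2050.0, 0.35, 60.0))

#: Parameters shifted when a batch is corrupted into an extreme-settings outlier.
OUTLIER_SHIFT_PARAMS = (
    "airflow_rate",
    "atomizing_pressure",
    "exhaust_temp",
    "inlet_air_temp",
    "plenum_pressure",
    "product_temp",
)


@dataclass(frozen=True)
class SimConfig:
    """Campaign-generator settings; defaults emulate the 14-batch study layout."""

    n_batches: int = 14
    rows_per_batch: tuple[int, int] = (2000, 3000)
    seed: int = 0
    spray_fraction: float = 0.7
    growth_gain: float = 0.01           # um per (g/min * s) initial growth rate
    growth_jitter_sd: float = 0.0       # hidden log-sd of per-batch growth rate
    saturation_gain: float = 8.0        # um of plateau size per (g/min) * g()
    airflow_effect: float = 0.5         # signed sensitivity of growth to airflow
    atomization_effect: float = 0.5     # signed sensitivity to atomizing pressure
    baseline_gain: float = 4e-4         # absorbance offset per um of Dv50
    water_band_centers: tuple[float, float] = (1450.0, 1934.0)
    band_width_nm: float = 35.0
    moisture_gain: float = 0.03         # absorbance per % moisture at band center
    noise_sd: float = 0.003             # additive spectral noise (AU)
    scatter_sd: float = 0.05            # log-sd of multiplicative scatter; 0 = off
    drift_sd: float = 0.004             # AR(1) baseline/slope drift (AU); 0 = off
    size_read_sd: float = 0.04          # AR(1) relative error of the size baseline
    dry_shift: float = 0.08             # optical size bias of the consolidated dry bed
    ar1_rho: float = 0.97               # parameter-noise autocorrelation
    outlier_ids: tuple[str, ...] = ()
    outlier_magnitude: float = 8.0      # shift in campaign SDs
    lod_points_per_batch: int = 12
    lod_noise_sd: float = 0.3           # % moisture measurement error
    include_spray_rate: bool = False

    def validate(self) -> None:
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        lo, hi = self.rows_per_batch
        if lo < 10 or hi < lo:
            raise ConfigError("rows_per_batch must be a range with lo >= 10")
        if not (0.0 < self.spray_fraction < 1.0):
            raise ConfigError("spray_fraction must lie in (0, 1)")
        if min(self.noise_sd, self.scatter_sd, self.drift_sd, self.size_read_sd) < 0:
            raise ConfigError("noise levels must be >= 0")
        if not (abs(self.ar1_rho) < 1):
            raise ConfigError("|ar1_rho| must be < 1")
        if self.lod_points_per_batch < 1:
            raise ConfigError("lod_points_per_batch must be >= 1")


@dataclass
class GroundTruth:
    """Latent trajectories and the informative-predictor mask for one batch."""

    batch_id: str
    moisture: np.ndarray        # (n,) %
    dv50: np.ndarray            # (n,) um
    informative_mask: np.ndarray  # (273,) bool over [256 spectra | 17 params]
    is_outlier: bool = False


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    e = rng.normal(0.0, sd * np.sqrt(1 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + e[i]
    return x


def spectral_model(
    dv50: np.ndarray,
    moisture: np.ndarray,
    grid: SpectralGrid,
    cfg: SimConfig,
) -> np.ndarray:
    """Noise-free spectra for given latent trajectories, shape (n, 256)."""
    wl = grid.wavelengths_nm
    lam = (wl - 1600.0) / 520.0          # roughly [-1, 1] over the grid
    dv50 = np.asarray(dv50, dtype=float)[:, None]
    moisture = np.asarray(moisture, dtype=float)[:, None]
    # Consolidated dry granules (moisture under ~1.2%) scatter differently:
    # the optical size response shifts as the bed dries out, so the very
    # endpoint regime is read with a bias the wetter training data lack.
    consolidation = 1.0 / (1.0 + np.exp((moisture - 1.2) / 0.2))
    dv50_optical = dv50 * (1.0 + cfg.dry_shift * consolidation)
    baseline = cfg.baseline_gain * dv50_optical * (1.0 + 0.4 * lam)
    bands = np.zeros_like(wl)
    for c, a, s in _COMPONENT_BANDS:
        bands = bands + a * np.exp(-0.5 * ((wl - c) / s) ** 2)
    water = np.zeros_like(wl)
    for w_amp, c in zip((1.0, 0.8), cfg.water_band_centers):
        water = water + w_amp * np.exp(-0.5 * ((wl - c) / cfg.band_width_nm) ** 2)
    return baseline + bands + cfg.moisture_gain * moisture * water


def _g_growth(cfg: SimConfig, airflow: np.ndarray, atomizing: np.ndarray) -> np.ndarray:
    """Monotone modulation of the growth rate by airflow and atomization.

    Growth increases with airflow (better wetting/mixing at higher
    fluidization here) and decreases with atomizing pressure (finer
    droplets), each scaled to its setpoint half-span; clipped positive.
    """
    z_air = (airflow - np.mean(_AIRFLOW_RANGE)) / (np.ptp(_AIRFLOW_RANGE) / 2)
    z_atom = (atomizing - np.mean(_ATOMIZING_RANGE)) / (np.ptp(_ATOMIZING_RANGE) / 2)
    return np.clip(1.0 + cfg.airflow_effect * z_air - cfg.atomization_effect * z_atom, 0.1, None)


def simulate_batch(
    cfg: SimConfig,
    batch_id: str,
    seed: int | np.random.SeedSequence,
) -> tuple[BatchRecord, GroundTruth]:
    """Generate one clean batch and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.rows_per_batch[0], cfg.rows_per_batch[1] + 1))
    n_spray = int(round(cfg.spray_fraction * n))
    n_spray = min(max(n_spray, 1), n - 1)
    dt = _BATCH_DURATION_S / n
    times = np.arange(n) * dt
    phase = np.where(np.arange(n) < n_spray, "spray", "drying").astype(object)
    spraying = np.arange(n) < n_spray

    u = rng.uniform
    sp_airflow = u(*_AIRFLOW_RANGE)
    sp_atomizing = u(*_ATOMIZING_RANGE)
    sp_inlet = u(*_INLET_TEMP_RANGE)
    sp_spray = u(*_SPRAY_RATE_RANGE)

    ar = lambda sd: _ar1(rng, n, cfg.ar1_rho, sd)  # noqa: E731
    airflow = sp_airflow + ar(0.6)
    atomizing = np.clip(sp_atomizing + ar(0.05), 0.05, None)
    inlet_temp = sp_inlet + ar(0.8)
    spray_rate = np.where(spraying, np.clip(sp_spray + ar(1.0), 0.5, None), 0.0)

    # Latent trajectories (Euler in real time).
    # Latent trajectories (Euler in real time).  Growth slows as the granule
    # bed approaches its operating-point plateau: the plateau size is
    # saturation_gain * spray * g(airflow, atomization) above the seed size,
    # so endpoint size is (nearly) linear in the observed setpoints.
    moisture = np.empty(n)
    dv50 = np.empty(n)
    m, d = 2.0, 140.0
    d0 = 140.0
    # hidden batch-to-batch kinetics: the approach to the plateau varies,
    # the plateau itself does not
    rate_jitter = float(np.exp(rng.normal(0.0, cfg.growth_jitter_sd)))
    for i in range(n):
        moisture[i], dv50[i] = m, d
        if spraying[i]:
            # wetting-dominated equilibrium: near-saturation bed moisture is
            # set by evaporative balance, only weakly by the spray rate
            m += (8e-3 + 1e-4 * spray_rate[i] - 1.2e-3 * m) * dt
            g = _g_growth(cfg, airflow[i], atomizing[i])
            span = max(cfg.saturation_gain * spray_rate[i] * g, 1e-9)
            headroom = max(0.0, 1.0 - (d - d0) / span)
            d += cfg.growth_gain * rate_jitter * spray_rate[i] * g * headroom * dt
        else:
            m += -2e-3 * (airflow[i] / 27.0) * max(m - 0.5, 0.0) * dt
            d += -1e-4 * (d - 120.0) * dt
        m = max(m, 0.05)

    # Derived process parameters, several tied to the latents.
    exhaust_temp = inlet_temp - 15.0 - 0.8 * moisture + ar(0.5)
    product_temp = inlet_temp - 20.0 - 1.2 * moisture + ar(0.5)
    pht_out_temp = exhaust_temp - 2.0 + ar(0.3)
    pht_in_temp = 25.0 + ar(0.4)
    plenum_pressure = 10.0 + 0.2 * airflow + ar(0.2)
    exhaust_pressure = plenum_pressure - 3.0 + ar(0.15)
    pht_out_pressure = exhaust_pressure - 1.0 + ar(0.1)
    pht_in_pressure = 101.3 + ar(0.2)
    in_abs_hum = u(6.0, 10.0) + ar(0.3)
    in_rel_hum = u(30.0, 50.0) + ar(1.0)
    out_abs_hum = in_abs_hum + 0.4 * moisture + ar(0.2)
    out_rel_hum = 25.0 + 2.0 * moisture + ar(1.0)
    filt_dp = 2.0 + 0.05 * airflow + ar(0.05)

    cols = {
        "airflow_rate": airflow,
        "runtime": times,
        "atomizing_pressure": atomizing,
        "pht_out_temp": pht_out_temp,
        "inlet_air_temp": inlet_temp,
        "plenum_pressure": plenum_pressure,
        "exhaust_pressure": exhaust_pressure,
        "pht_in_abs_hum": in_abs_hum,
        "pht_in_rel_hum": in_rel_hum,
        "pht_out_rel_hum": out_rel_hum,
        "pht_out_abs_hum": out_abs_hum,
        "exhaust_temp": exhaust_temp,
        "pht_out_pressure": pht_out_pressure,
        "product_temp": product_temp,
        "pht_in_pressure": pht_in_pressure,
        "prod_filt_diff_pressure": filt_dp,
        "pht_in_temp": pht_in_temp,
    }
    params = np.column_stack([cols[name] for name in PARAMETER_NAMES])
    if cfg.include_spray_rate:
        params = np.column_stack([params, spray_rate])

    grid = default_grid()
    # The size-dependent baseline is read with a relative AR(1) error: the
    # optical size response depends on packing/flow state, not size alone.
    dv50_optical = dv50 * (1.0 + _ar1(rng, n, cfg.ar1_rho, cfg.size_read_sd)) \
        if cfg.size_read_sd > 0 else dv50
    spectra = spectral_model(dv50_optical, moisture, grid, cfg)
    if cfg.scatter_sd > 0:
        spectra = spectra * np.exp(rng.normal(0.0, cfg.scatter_sd, n))[:, None]
    if cfg.drift_sd > 0:
        # Instrument/bed baseline drift: autocorrelated offset and slope
        # components confound the size-driven baseline within a batch.
        lam = (grid.wavelengths_nm - 1600.0) / 520.0
        offset_drift = _ar1(rng, n, cfg.ar1_rho, cfg.drift_sd)
        slope_drift = _ar1(rng, n, cfg.ar1_rho, 0.5 * cfg.drift_sd)
        spectra = spectra + offset_drift[:, None] + slope_drift[:, None] * lam[None, :]
    if cfg.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, cfg.noise_sd, spectra.shape)

    sizes = dv50[:, None] * SPAN_FACTORS[None, :]

    k = min(cfg.lod_points_per_batch, n)
    lod_rows = np.sort(rng.choice(n, size=k, replace=False))
    lod = [
        (int(i), float(np.clip(moisture[i] + rng.normal(0.0, cfg.lod_noise_sd), 0.0, 100.0)))
        for i in lod_rows
    ]

    record = BatchRecord(
        batch_id=batch_id, times=times, spectra=spectra, params=params,
        sizes=sizes, lod=lod, phase=phase,
    )
    truth = GroundTruth(
        batch_id=batch_id, moisture=moisture, dv50=dv50,
        informative_mask=_informative_mask(grid, cfg),
    )
    return record, truth


def _informative_mask(grid: SpectralGrid, cfg: SimConfig) -> np.ndarray:
    """Mask over [256 spectral | 17 parameter] predictors that carry signal."""
    wl = grid.wavelengths_nm
    spec = np.zeros(len(wl), dtype=bool)
    for c, _, s in _COMPONENT_BANDS:
        spec |= np.abs(wl - c) <= 2.5 * s
    for c in cfg.water_band_centers:
        spec |= np.abs(wl - c) <= 2.5 * cfg.band_width_nm
    par = np.zeros(len(PARAMETER_NAMES), dtype=bool)
    for name in ("airflow_rate", "runtime", "atomizing_pressure"):
        par[PARAMETER_NAMES.index(name)] = True
    return np.concatenate([spec, par])


def inject_outlier_batch(
    b: BatchRecord,
    mode: str,
    magnitude: float,
    param_sds: dict[str, float] | None = None,
) -> BatchRecord:
    """Corrupt a batch into an extreme-settings outlier.

    A stated subset of process parameters is shifted by
    ``sign * magnitude * campaign SD`` (sign +1 for ``high_extreme``, -1
    for ``low_extreme``).  The spectra receive three distortions: a
    baseline tilt/curvature with the mode's sign (separates the batch in
    PC score space), a mode-independent attenuation of the water-band
    channels (a fouled window weakens the moisture signal for either
    extreme), and a wavelength-registration failure — a systematic
    channel shift in the mode's direction plus per-row jitter — so the
    batch's NIR-to-moisture relationship is broken in a way no global
    linear model can absorb, which is what makes it a genuine
    calibration outlier rather than merely an offset one.
    """
    if mode not in ("high_extreme", "low_extreme"):
        raise ConfigError(f"unknown outlier mode {mode!r}")
    if magnitude < 0:
        raise ConfigError("magnitude must be >= 0")
    sign = 1.0 if mode == "high_extreme" else -1.0
    params = b.params.copy()
    n_base = len(PARAMETER_NAMES)
    sds = param_sds or {}
    for name in OUTLIER_SHIFT_PARAMS:
        j = PARAMETER_NAMES.index(name)
        sd = float(sds.get(name, np.std(b.params[:, j], ddof=1) or 1.0))
        params[:, j] += sign * magnitude * sd
    if b.has_spray_rate:
        spray = params[:, n_base]
        on = b.phase == "spray"
        sd = float(sds.get("spray_rate", np.std(spray[on], ddof=1) or 1.0))
        shifted = spray[on] + sign * magnitude * sd
        params[on, n_base] = np.clip(shifted, 0.5, None)

    wl = default_grid().wavelengths_nm
    lam = (wl - 1600.0) / 520.0
    distortion = sign * magnitude * (0.03 + 0.04 * lam + 0.05 * (lam**2 - 1.0 / 3.0))
    spectra = b.spectra + distortion[None, :]
    # Batch-specific spectral corruption (seeded by the batch id, so the
    # injection stays deterministic): a systematic water-band rescaling
    # that separates the batch and breaks its NIR-moisture slope, plus
    # erratic per-row tilt/curvature shape noise that SNV cannot remove
    # and that makes the batch's spectra uninformative for any global
    # linear model, even with the batch's own rows in training.
    water = np.zeros(wl.size, dtype=bool)
    for c in SimConfig().water_band_centers:
        water |= np.abs(wl - c) <= 2.0 * SimConfig().band_width_nm
    spectra[:, water] *= float(np.exp(-0.08 * magnitude))
    rng = np.random.default_rng(zlib.crc32(b.batch_id.encode()))
    # Erratic per-row wavelength registration: each spectrum is shifted by
    # up to ~half a band-width on the channel grid, so band positions no
    # longer line up with the clean batches' and no global linear model
    # can read this batch's spectra, even with its own rows in training.
    # Wavelength-registration failure: a systematic channel shift in the
    # mode's direction (biases the global model while the batch is kept)
    # plus per-row jitter (defeats batch-local absorption by extra
    # latent directions).
    sys_shift = int(np.copysign(round(magnitude / 2), sign))
    jitter = max(1, int(round(magnitude / 4)))
    if magnitude > 0:
        shifts = sys_shift + rng.integers(-jitter, jitter + 1, b.n_rows)
        for i, sh in enumerate(shifts):
            if sh:
                spectra[i] = np.roll(spectra[i], sh)

    return BatchRecord(
        batch_id=b.batch_id, times=b.times.copy(), spectra=spectra,
        params=params, sizes=b.sizes.copy(), lod=list(b.lod),
        phase=b.phase.copy(),
    )


def simulate_campaign(cfg: SimConfig) -> tuple[Campaign, list[GroundTruth]]:
    """Generate a full campaign; batches in ``outlier_ids`` are corrupted.

    Outlier batches alternate high/low extreme modes, emulating a pair of
    batches run at mutually opposite parameter extremes.
    """
    cfg.validate()
    ids = [str(1001 + i) for i in range(cfg.n_batches)]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate batch ids")
    unknown = set(cfg.outlier_ids) - set(ids)
    if unknown:
        raise ConfigError(f"outlier_ids not in campaign: {sorted(unknown)}")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_batches)
    batches, truths = [], []
    for bid, ss in zip(ids, seeds):
        rec, truth = simulate_batch(cfg, bid, ss)
        batches.append(rec)
        truths.append(truth)
    # Campaign-level parameter SDs from the clean batches only.
    clean_rows = np.vstack([b.params for b in batches if b.batch_id not in cfg.outlier_ids])
    names = list(PARAMETER_NAMES) + ([
        "spray_rate"] if cfg.include_spray_rate else [])
    sds = {name: float(np.std(clean_rows[:, j], ddof=1)) for j, name in enumerate(names)}
    for k, bid in enumerate(cfg.outlier_ids):
        mode = "high_extreme" if k % 2 == 0 else "low_extreme"
        i = ids.index(bid)
        batches[i] = inject_outlier_batch(batches[i], mode, cfg.outlier_magnitude, sds)
        truths[i].is_outlier = True
    campaign = Campaign(batches, default_grid(), ProcessParameterSet(cfg.include_spray_rate))
    return campaign, truths


def clean_config(**overrides) -> SimConfig:
    """Convenience: a SimConfig with keyword overrides applied."""
    return replace(SimConfig(), **overrides)
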