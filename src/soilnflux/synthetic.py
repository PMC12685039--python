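"""Seeded synthetic soil-climate, chamber-closure and incubation generator.

Emulates a temperate-forest soil-warming experiment with the statistical
structure the downstream analysis assumes: a continental-monsoon climate
(~811 mm yr⁻¹, >80 % falling May–September), mineral soil temperatures
spanning −5 to 25 °C, a moisture bucket with warming-enhanced drying
(defaults −16 % in the O horizon, −5 % in 0–10 cm mineral soil), spring
thaw advanced 8–11 days under +2 °C warming, freeze–thaw N2O pulses, and
flux surfaces combining an exponential temperature term (Q10 3.5 for NO,
2.1 for N2O) with a quadratic (NO) or increasing (N2O) moisture term.

Warming suppression of fluxes is carried by a substrate-supply factor
(θ_O relative to the ambient seasonal climatology, raised to a species
exponent) emulating moisture-limited N mineralization/nitrification; the
factor is ≈1 in control plots so ambient temperature sensitivity is
unbiased, and shrinks under warming-induced O-horizon drying.

Randomness contract: one root seed; every plot, chamber and purpose
derives an independent substream, so adding chambers or species never
perturbs existing series.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import ChamberGeometry, ClosureSeries, compute_flux_batch
from .constants import mole_fraction_to_mass
from .soil import compute_wfps

# substream purpose tags
_S_TEMP, _S_PRECIP, _S_MOIST, _S_THAW, _S_CHAMBER, _S_CLOSURE, _S_INC = range(1, 8)

TREATMENTS = ("control", "warmed")


def _plot_key(plot_id) -> int:
    """Stable integer substream key for a plot id."""
    return zlib.crc32(str(plot_id).encode()) & 0x7FFFFFFF

DEFAULT_PLOTS = (("P1", "control"), ("P2", "control"), ("P3", "control"),
                 ("P4", "warmed"), ("P5", "warmed"), ("P6", "warmed"))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic experiment; the seed fixes every output."""

    seed: int = 0
    n_years: int = 2
    plots: tuple = DEFAULT_PLOTS
    chambers_per_plot: int = 5
    closures_per_day: int = 4
    base_year: int = 2019

    # warming treatment
    warming_delta_t: float = 2.0            # °C
    rel_moisture_change_o: float = -0.16    # growing-season relative change
    rel_moisture_change_mineral: float = -0.05
    thaw_advance_days: tuple = (8.0, 11.0)  # uniform draw, scaled by ΔT/2

    # flux response surface
    temp_k_no: float = math.log(3.5) / 10.0   # per °C, implies Q10 = 3.5
    temp_k_n2o: float = math.log(2.1) / 10.0  # implies Q10 = 2.1
    moisture_optimum_wfps: float = 35.0
    moisture_curvature: float = -0.001        # per (%WFPS)²; negative
    amplitude_no: float = 1.2                 # µg N m⁻² h⁻¹ at 0 °C, optimum moisture
    amplitude_n2o: float = 1.5
    substrate_exponent_no: float = 2.4        # sensitivity to O-horizon drying
    substrate_exponent_n2o: float = 1.8
    pulse_peak: float = 640.0                 # freeze-thaw N2O pulse, µg N m⁻² h⁻¹
    pulse_onset_days: float = 2.0             # soil rewetted to field capacity
    pulse_decay_days: float = 5.0
    pulse_window_days: float = 14.0
    pulse_moisture_exponent: float = 1.0
    pulse_ref_wfps: float = 60.0

    # climate
    mean_temp: float = 10.0                   # mineral soil annual mean, °C
    temp_amplitude: float = 15.0              # seasonal amplitude (range −5..25)
    o_temp_amplitude: float = 17.0
    peak_doy: int = 196
    temp_noise_sd: float = 1.2
    temp_noise_rho: float = 0.8
    heavy_precip_threshold: float = 30.0      # mm
    precip_prob_wet: float = 0.35             # May–Sep daily rain probability
    precip_mean_wet: float = 12.0             # mm per wet day
    precip_prob_dry: float = 0.15
    precip_mean_dry: float = 5.0
    precip_gamma_shape: float = 0.7

    # moisture buckets
    bulk_density: float = 0.70
    bucket_depth_mm: float = 100.0
    infiltration_frac: float = 0.7
    et_coef: float = 0.13                    # mm d⁻¹ per °C at reference wetness
    vwc_init: float = 0.30
    vwc_max: float = 0.70
    field_capacity_vwc: float = 0.42   # gravity water drains within a day
    vwc_ref: float = 0.35
    melt_rate_mm: float = 10.0
    theta_o_baseline: float = 0.81            # ambient O horizon, g H2O g⁻¹
    o_gain_per_mm: float = 0.02
    o_et_coef: float = 0.0026
    theta_o_max: float = 1.30
    moisture_noise_sd: float = 0.03           # multiplicative lognormal

    # measurement
    ambient_no: float = 1.0                   # nmol mol⁻¹ (conventional choice)
    ambient_n2o: float = 330.0
    analyzer_noise_sd_no: float = 0.2         # nmol mol⁻¹
    analyzer_noise_sd_n2o: float = 0.5
    chamber_lognormal_sd: float = 0.15        # persistent spatial heterogeneity
    pressure_hpa: float = 1013.0

    # laboratory incubation
    inc_temps: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    inc_days: float = 7.0
    inc_b: float = math.log(2.0) / 10.0       # Arrhenius-type exponent
    inc_a_rm_o: float = 0.28                  # mg N kg⁻¹ d⁻¹ at 0 °C, O horizon
    inc_a_rm_mineral: float = 0.11
    inc_nitrif_frac: float = 0.6              # R_N / R_M
    inc_warm_mult_rm_o: float = 0.79          # warming multipliers, O horizon
    inc_warm_mult_rn_o: float = 0.86
    inc_noise_sd: float = 0.15                # mg N kg⁻¹ on after-pools
    inc_replicates: int = 6

    def __post_init__(self):
        if self.n_years <= 0:
            raise ValueError("n_years must be positive")
        if self.warming_delta_t < 0:
            raise ValueError("warming_delta_t must be non-negative")
        if self.moisture_curvature >= 0:
            raise ValueError("moisture_curvature must be negative")
        for v in (self.rel_moisture_change_o, self.rel_moisture_change_mineral):
            if not -1.0 < v < 1.0:
                raise ValueError("relative moisture changes must lie in (-1, 1)")
        for _, trt in self.plots:
            if trt not in TREATMENTS:
                raise ValueError(f"unknown treatment label {trt!r}")

    def rng(self, *key) -> np.random.Generator:
        """Independent substream for a (purpose, plot, ...) key."""
        return np.random.default_rng(np.random.SeedSequence((self.seed,) + key))

    def ambient(self, species: str) -> float:
        return self.ambient_no if species == "NO" else self.ambient_n2o

    def analyzer_noise_sd(self, species: str) -> float:
        return (self.analyzer_noise_sd_no if species == "NO"
                else self.analyzer_noise_sd_n2o)

    def temp_k(self, species: str) -> float:
        return self.temp_k_no if species == "NO" else self.temp_k_n2o

    def substrate_exponent(self, species: str) -> float:
        return (self.substrate_exponent_no if species == "NO"
                else self.substrate_exponent_n2o)


def _calendar(config: SimConfig) -> pd.DataFrame:
    """Day-of-year 1–365 calendar with leap days dropped."""
    days = pd.date_range(f"{config.base_year}-01-01",
                         f"{config.base_year + config.n_years - 1}-12-31",
                         freq="D")
    days = days[~((days.month == 2) & (days.day == 29))]
    df = pd.DataFrame({"date": days})
    df["year"] = df["date"].dt.year
    df["doy"] = df.groupby("year").cumcount() + 1
    return df


def _seasonal_temp(doy, mean, amplitude, peak_doy):
    return mean + amplitude * np.cos(2.0 * np.pi * (np.asarray(doy, float)
                                                    - peak_doy) / 365.0)


def _ar1(rng, n, sd, rho):
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - rho ** 2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def _simulate_precip(config: SimConfig, cal: pd.DataFrame) -> np.ndarray:
    """Site-level daily precipitation (mm): seasonally inhomogeneous events."""
    rng = config.rng(_S_PRECIP)
    months = cal["date"].dt.month.to_numpy()
    wet_season = (months >= 5) & (months <= 9)
    p = np.where(wet_season, config.precip_prob_wet, config.precip_prob_dry)
    mean = np.where(wet_season, config.precip_mean_wet, config.precip_mean_dry)
    occurs = rng.random(len(cal)) < p
    shape = config.precip_gamma_shape
    amounts = rng.gamma(shape, mean / shape)
    return np.where(occurs, amounts, 0.0)


def _thaw_doys(config: SimConfig) -> dict:
    """Per (year, treatment) snowmelt/thaw onset day-of-year.

    Control: first spring day the seasonal mineral-soil temperature
    crosses 0 °C.  Warmed: the control date minus a drawn 8–11 d advance
    scaled by ΔT/2, so a null treatment (ΔT = 0) has no advance.
    """
    doys = np.arange(1, 183)
    seas = _seasonal_temp(doys, config.mean_temp, config.temp_amplitude,
                          config.peak_doy)
    above = np.nonzero(seas > 0.0)[0]
    control_thaw = float(doys[above[0]]) if len(above) else 1.0
    out = {}
    for y in range(config.n_years):
        rng = config.rng(_S_THAW, y)
        lo, hi = config.thaw_advance_days
        # whole days: thaw is a daily-resolution event, and a fractional
        # offset would misalign the two treatments' pulse-decay grids
        advance = float(np.round(rng.uniform(lo, hi)
                                 * (config.warming_delta_t / 2.0)))
        year = config.base_year + y
        out[(year, "control")] = control_thaw
        out[(year, "warmed")] = control_thaw - advance
    return out


def _run_buckets(config: SimConfig, temps_mineral, temps_o, precip,
                 doy, year, thaw_by_year, et_mult_mineral, et_mult_o):
    """Daily mineral VWC, O-horizon gravimetric moisture and snowpack.

    Water balance per layer: infiltration from rain (and snowmelt after
    the thaw date), loss from evapotranspiration proportional to
    temperature and relative wetness; snow accumulates while the mineral
    soil is at or below 0 °C.  Gains never exceed precipitation, so the
    bucket conserves water.
    """
    n = len(precip)
    vwc = np.empty(n)
    theta = np.empty(n)
    snow_out = np.empty(n)
    v = config.vwc_init
    th = config.theta_o_baseline
    snow = 0.0
    for i in range(n):
        t = temps_mineral[i]
        t_o = temps_o[i]
        thaw = thaw_by_year[year[i]]
        melt = 0.0
        if t <= 0.0:
            snow += precip[i]
            rain = 0.0
        else:
            rain = precip[i]
        if doy[i] >= thaw and snow > 0.0 and doy[i] < 250:
            melt = min(snow, config.melt_rate_mm)
            snow -= melt
        # mineral bucket (mm water over bucket_depth)
        gain = config.infiltration_frac * (rain + melt)
        et = (et_mult_mineral * config.et_coef * max(t, 0.0)
              * (v / config.vwc_ref)) if t > 0.0 else 0.0
        v = min(max(v + (gain - et) / config.bucket_depth_mm, 0.02),
                config.vwc_max)
        v = min(v, config.field_capacity_vwc)  # fast drainage of gravity water
        # O-horizon bucket (gravimetric)
        gain_o = config.o_gain_per_mm * (rain + 0.4 * melt)
        et_o = (et_mult_o * config.o_et_coef * max(t_o, 0.0)
                * (th / config.theta_o_baseline)) if t_o > 0.0 else 0.0
        th = min(max(th + gain_o - et_o, 0.15), config.theta_o_max)
        vwc[i] = v
        theta[i] = th
        snow_out[i] = snow
    return vwc, theta, snow_out


def _calibrate_et_multiplier(config: SimConfig, cal, precip, layer: str,
                             thaw_control: dict, thaw_warmed: dict) -> float:
    """ET multiplier for warmed plots matching the target moisture change.

    Bisects the warmed-layer evapotranspiration multiplier so the
    noise-free warmed bucket's growing-season mean moisture equals
    (1 + relative change) × the control's.  Null treatment short-circuits
    to 1.
    """
    target = (config.rel_moisture_change_o if layer == "O"
              else config.rel_moisture_change_mineral)
    if target == 0.0 and config.warming_delta_t == 0.0:
        return 1.0
    doy = cal["doy"].to_numpy()
    year = cal["year"].to_numpy()
    months = cal["date"].dt.month.to_numpy()
    growing = (months >= 5) & (months <= 10)
    t_min_c = _seasonal_temp(doy, config.mean_temp, config.temp_amplitude,
                             config.peak_doy)
    t_o_c = _seasonal_temp(doy, config.mean_temp, config.o_temp_amplitude,
                           config.peak_doy)
    dt = config.warming_delta_t

    def growing_mean(mult, t_min, t_o, thaw):
        vwc, theta, _ = _run_buckets(config, t_min, t_o, precip, doy, year,
                                     thaw,
                                     mult if layer == "mineral" else 1.0,
                                     mult if layer == "O" else 1.0)
        series = theta if layer == "O" else vwc
        return float(series[growing].mean())

    ctrl = growing_mean(1.0, t_min_c, t_o_c, thaw_control)
    goal = ctrl * (1.0 + target)
    lo, hi = 0.2, 6.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        val = growing_mean(mid, t_min_c + dt, t_o_c + dt, thaw_warmed)
        if val > goal:
            lo = mid   # too wet -> raise ET
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_climate(config: SimConfig) -> pd.DataFrame:
    """Daily soil climate for every plot.

    Returns one row per (date, plot): mineral and O-horizon temperature,
    precipitation and snowpack, mineral VWC and WFPS, O-horizon
    gravimetric moisture with its ambient climatology, frozen flag,
    days-since-thaw and a season label.
    """
    cal = _calendar(config)
    n = len(cal)
    doy = cal["doy"].to_numpy()
    year = cal["year"].to_numpy()
    months = cal["date"].dt.month.to_numpy()
    precip = _simulate_precip(config, cal)
    thaws = _thaw_doys(config)
    thaw_c = {config.base_year + y: thaws[(config.base_year + y, "control")]
              for y in range(config.n_years)}
    thaw_w = {config.base_year + y: thaws[(config.base_year + y, "warmed")]
              for y in range(config.n_years)}
    mult_min = _calibrate_et_multiplier(config, cal, precip, "mineral",
                                        thaw_c, thaw_w)
    mult_o = _calibrate_et_multiplier(config, cal, precip, "O",
                                      thaw_c, thaw_w)

    seas_min = _seasonal_temp(doy, config.mean_temp, config.temp_amplitude,
                              config.peak_doy)
    seas_o = _seasonal_temp(doy, config.mean_temp, config.o_temp_amplitude,
                            config.peak_doy)
    # ambient climatology of O-horizon moisture: noise-free control bucket
    _, theta_clim, _ = _run_buckets(config, seas_min, seas_o, precip, doy,
                                    year, thaw_c, 1.0, 1.0)

    frames = []
    for plot_id, treatment in config.plots:
        p_key = _plot_key(plot_id)
        warmed = treatment == "warmed"
        dt = config.warming_delta_t if warmed else 0.0
        rng_t = config.rng(_S_TEMP, p_key)
        noise = _ar1(rng_t, n, config.temp_noise_sd, config.temp_noise_rho)
        t_min = seas_min + noise + dt
        t_o = seas_o + 1.1 * noise + dt
        thaw = thaw_w if warmed else thaw_c
        vwc, theta, snow = _run_buckets(
            config, t_min, t_o, precip, doy, year, thaw,
            mult_min if warmed else 1.0, mult_o if warmed else 1.0)
        rng_m = config.rng(_S_MOIST, p_key)
        sd = config.moisture_noise_sd
        if sd > 0:
            vwc = np.clip(vwc * np.exp(rng_m.normal(-sd * sd / 2, sd, n)),
                          0.02, config.vwc_max)
            theta = np.clip(theta * np.exp(rng_m.normal(-sd * sd / 2, sd, n)),
                            0.15, config.theta_o_max)
        frozen = t_min <= 0.0
        thaw_doy = np.array([thaw[y] for y in year])
        # freeze-thaw-stage temperature: ambient seasonal course at the same
        # days-since-thaw plus the treatment's warming offset; referencing
        # the pulse to thaw stage (not calendar) keeps the warming factor on
        # the pulse equal to e^(k·ΔT) instead of being cancelled by the
        # advanced thaw date landing on colder calendar days
        thaw_c_doy = np.array([thaw_c[y] for y in year])
        pulse_temp = _seasonal_temp(thaw_c_doy + (doy - thaw_doy),
                                    config.mean_temp, config.temp_amplitude,
                                    config.peak_doy) + dt
        frames.append(pd.DataFrame({
            "date": cal["date"], "year": year, "doy": doy,
            "plot_id": plot_id, "treatment": treatment,
            "temp_mineral": t_min, "temp_o": t_o,
            "precip_mm": precip, "snow_mm": snow,
            "vwc_mineral": vwc,
            "wfps": compute_wfps(vwc, config.bulk_density),
            "theta_o": theta, "theta_o_clim": theta_clim,
            "frozen": frozen,
            "days_since_thaw": doy - thaw_doy,
            "pulse_temp": pulse_temp,
            "season": np.where((months >= 5) & (months <= 10),
                               "growing", "dormant"),
        }))
    return pd.concat(frames, ignore_index=True)


def true_flux_surface(temp, wfps, species: str, config: SimConfig,
                      days_since_thaw=None, substrate=1.0,
                      pulse_substrate=None, pulse_temp=None):
    """Noise-free flux surface, µg N m⁻² h⁻¹; never NaN, never negative.

    NO: A·e^(kT) times a downward parabola in WFPS peaking at the
    optimum, clipped at zero.  N2O: A·e^(kT) times a moisture-increasing
    factor, plus — within ``pulse_window_days`` after thaw — an
    exponentially decaying freeze–thaw pulse scaled by the same
    temperature factor and by post-thaw wetness.  ``substrate`` is the
    N-supply factor (≈1 ambient, <1 under warming-induced drying);
    ``pulse_substrate`` (default: same as ``substrate``) is the supply
    factor for the freeze–thaw pulse, which feeds on N mineralized over
    the preceding growing season rather than on same-day supply.
    ``pulse_temp`` (default: same as ``temp``) is the freeze-thaw-stage
    temperature that scales the pulse.
    """
    temp = np.asarray(temp, dtype=float)
    wfps = np.asarray(wfps, dtype=float)
    if np.any(wfps < 0) or np.any(wfps > 100):
        raise ValueError("WFPS must lie in [0, 100]")
    substrate = np.asarray(substrate, dtype=float)
    if species == "NO":
        g = np.maximum(0.0, 1.0 + config.moisture_curvature
                       * (wfps - config.moisture_optimum_wfps) ** 2)
        out = config.amplitude_no * np.exp(config.temp_k_no * temp) * g \
            * substrate
    elif species == "N2O":
        h = np.maximum(0.0, wfps / config.moisture_optimum_wfps)
        tfac = np.exp(config.temp_k_n2o * temp)
        out = config.amplitude_n2o * tfac * h * substrate
        if days_since_thaw is not None:
            dst = np.asarray(days_since_thaw, dtype=float)
            psub = substrate if pulse_substrate is None \
                else np.asarray(pulse_substrate, dtype=float)
            ptfac = tfac if pulse_temp is None \
                else np.exp(config.temp_k_n2o * np.asarray(pulse_temp, float))
            on = config.pulse_onset_days
            in_window = (dst >= on) & (dst < on + config.pulse_window_days)
            pulse = np.where(
                in_window,
                config.pulse_peak
                * np.exp(-(dst - on) / config.pulse_decay_days)
                * ptfac * (wfps / config.pulse_ref_wfps)
                ** config.pulse_moisture_exponent * psub,
                0.0)
            out = out + pulse
    else:
        raise ValueError(f"unknown species {species!r}")
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def daily_true_fluxes(config: SimConfig, climate: pd.DataFrame,
                      species=("NO", "N2O")) -> pd.DataFrame:
    """Plot-day true fluxes from the climate state, one row per species.

    The day's substrate-supply factor is the O-horizon moisture relative
    to its ambient climatology, raised to the species exponent.  The
    freeze–thaw N2O pulse instead carries the preceding growing season's
    mean moisture status (per plot and year): the N pool it draws on was
    mineralized before winter, so a drier previous season thins the
    spring pulse.
    """
    ratio_day = np.clip(climate["theta_o"].to_numpy()
                        / climate["theta_o_clim"].to_numpy(), 0.3, 2.0)
    grow = climate[climate["season"] == "growing"]
    grow_ratio = (grow.assign(
        ratio=np.clip(grow["theta_o"] / grow["theta_o_clim"], 0.3, 2.0))
        .groupby(["plot_id", "year"])["ratio"].mean())
    prev_ratio = np.array([
        grow_ratio.get((p, y - 1), grow_ratio.get((p, y), 1.0))
        for p, y in zip(climate["plot_id"], climate["year"])])
    frames = []
    for sp in species:
        substrate = ratio_day ** config.substrate_exponent(sp)
        pulse_sub = prev_ratio ** config.substrate_exponent(sp) \
            if sp == "N2O" else None
        pulse_temp = climate["pulse_temp"].to_numpy() \
            if "pulse_temp" in climate.columns else None
        flux = true_flux_surface(
            climate["temp_mineral"].to_numpy(), climate["wfps"].to_numpy(),
            sp, config, days_since_thaw=climate["days_since_thaw"].to_numpy(),
            substrate=substrate, pulse_substrate=pulse_sub,
            pulse_temp=pulse_temp)
        df = climate[["date", "plot_id", "treatment", "temp_mineral",
                      "wfps", "season"]].copy()
        df["species"] = sp
        df["true_flux"] = flux
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# chamber forward model

def _closure_time_grid(geometry: ChamberGeometry, dt_s: float = 10.0):
    closed = np.arange(0.0, geometry.closure_minutes * 60.0 + dt_s / 2, dt_s)
    post = geometry.closure_minutes * 60.0 + np.arange(
        dt_s, geometry.ambient_window_s + dt_s / 2, dt_s)
    return closed, post


def closure_concentration(t_s, true_flux, species, geometry, ambient,
                          temp_k, pressure_hpa, flush_end_s):
    """Closed-form well-mixed vented-chamber solution, nmol mol⁻¹.

    The chamber accumulates from the end of the lid-flush period:
    C(t) = C_in + S·(1 − e^(−(t−t0)·Q/V)) with steady amplitude
    S = F·A / (Q·conv).  Before t0 the analyzer reads ambient line air.
    """
    conv = mole_fraction_to_mass(species, np.asarray(temp_k, dtype=float),
                                 pressure_hpa)
    s_amp = np.asarray(true_flux, dtype=float) * geometry.area_m2 \
        / (geometry.flow_m3_h * conv)
    tau_s = geometry.turnover_h * 3600.0
    t = np.asarray(t_s, dtype=float)
    rise = 1.0 - np.exp(-np.maximum(t - flush_end_s, 0.0) / tau_s)
    if s_amp.ndim == 0:
        return ambient + float(s_amp) * rise
    return ambient + s_amp[:, None] * rise


def simulate_closure(true_flux: float, geometry: ChamberGeometry | None = None,
                     ambient_conc: float | None = None,
                     config: SimConfig | None = None, species: str = "NO",
                     temp_k: float = 288.15, pressure_hpa: float = 1013.0,
                     noise_sd: float | None = None,
                     rng: np.random.Generator | None = None,
                     dt_s: float = 10.0, **meta) -> ClosureSeries:
    """Forward-model one chamber closure for a known true flux.

    Integrates the well-mixed vented-chamber mass balance
    V·dC/dt = F·A + Q·(C_in − C) at ``dt_s`` resolution over the closure,
    marks the flush period (analyzer reads ambient line air), appends a
    30-s post-opening ambient segment, adds white analyzer noise, and
    stores the true flux on the series for recovery testing.
    """
    if not np.isfinite(true_flux):
        raise ValueError("true flux must be finite")
    config = config or SimConfig()
    geometry = geometry or ChamberGeometry()
    ambient = config.ambient(species) if ambient_conc is None else ambient_conc
    noise_sd = config.analyzer_noise_sd(species) if noise_sd is None else noise_sd
    rng = rng or config.rng(_S_CLOSURE, 0)
    closed, post = _closure_time_grid(geometry, dt_s)
    flush_end = geometry.flush_minutes * 60.0
    c_closed = closure_concentration(closed, true_flux, species, geometry,
                                     ambient, temp_k, pressure_hpa, flush_end)
    c_closed = np.where(closed < flush_end, ambient, c_closed)
    c_post = np.full(post.shape, float(ambient))
    t_all = np.concatenate([closed, post])
    c_all = np.concatenate([c_closed, c_post])
    if noise_sd > 0:
        c_all = c_all + rng.normal(0.0, noise_sd, size=c_all.shape)
    return ClosureSeries(species=species, t_s=t_all, conc_nmol_mol=c_all,
                         temp_k=temp_k, pressure_hpa=pressure_hpa,
                         geometry=geometry, true_flux=float(true_flux),
                         **meta)


def simulate_flux_records(config: SimConfig, climate: pd.DataFrame | None = None,
                          species=("NO", "N2O"),
                          geometry: ChamberGeometry | None = None,
                          treatments=("control", "warmed")) -> pd.DataFrame:
    """Simulate every chamber closure and estimate its flux.

    For each plot-day, each chamber carries a persistent lognormal
    heterogeneity factor (unit mean) on the true flux; each closure is
    forward-modelled with analyzer noise and passed through the hybrid
    estimator.  Noise substreams are keyed by (species, plot, chamber) so
    enlarging the design never perturbs existing chambers.

    Returns a flux-record table: date, plot, chamber, treatment, species,
    estimated flux with both terms and diagnostics, and the true flux.
    """
    geometry = geometry or ChamberGeometry()
    climate = climate if climate is not None else simulate_climate(config)
    climate = climate[climate["treatment"].isin(treatments)]
    daily = daily_true_fluxes(config, climate, species=species)
    closed, post = _closure_time_grid(geometry)
    frames = []
    for sp_idx, sp in enumerate(species):
        sub = daily[daily["species"] == sp]
        ambient = config.ambient(sp)
        noise_sd = config.analyzer_noise_sd(sp)
        win = (closed >= 360.0)  # samples the estimator may see (post-flush)
        t_used = closed[win]
        for plot_id, plot_daily in sub.groupby("plot_id", sort=False):
            p_key = _plot_key(plot_id)
            n_days = len(plot_daily)
            temp_k = plot_daily["temp_mineral"].to_numpy() + 273.15
            true_day = plot_daily["true_flux"].to_numpy()
            rng_ch = config.rng(_S_CHAMBER, p_key)
            sd = config.chamber_lognormal_sd
            factors = np.exp(rng_ch.normal(-sd * sd / 2, sd,
                                           config.chambers_per_plot))
            for ch in range(config.chambers_per_plot):
                rng = config.rng(_S_CLOSURE, sp_idx, p_key, ch)
                n_cl = n_days * config.closures_per_day
                f_true = np.repeat(true_day * factors[ch],
                                   config.closures_per_day)
                t_k = np.repeat(temp_k, config.closures_per_day)
                c = closure_concentration(
                    t_used, f_true, sp, geometry, ambient, t_k,
                    config.pressure_hpa, geometry.flush_minutes * 60.0)
                amb_meas = np.full(n_cl, float(ambient))
                if noise_sd > 0:
                    c = c + rng.normal(0.0, noise_sd, size=c.shape)
                    amb_meas = amb_meas + rng.normal(
                        0.0, noise_sd / math.sqrt(len(post)), size=n_cl)
                est = compute_flux_batch(t_used, c, sp, t_k,
                                         config.pressure_hpa, amb_meas,
                                         geometry)
                frames.append(pd.DataFrame({
                    "date": np.repeat(plot_daily["date"].to_numpy(),
                                      config.closures_per_day),
                    "plot_id": plot_id,
                    "chamber_id": f"{plot_id}-C{ch + 1}",
                    "treatment": plot_daily["treatment"].iloc[0],
                    "species": sp,
                    "flux": est["flux"],
                    "slope_nmol_mol_h": est["slope"],
                    "slope_r2": est["r2"],
                    "accumulation": est["accumulation"],
                    "dynamic": est["dynamic"],
                    "qc_flags": "",
                    "true_flux": f_true,
                }))
    return pd.concat(frames, ignore_index=True)


def simulate_incubation(config: SimConfig) -> pd.DataFrame:
    """Synthetic one-week incubation across the 5–25 °C gradient.

    Before/after NH4+ and NO3- pools per (layer, treatment, temperature,
    replicate); net rates follow R = a·e^(bT) with warming-treatment
    multipliers < 1 in the O horizon (moisture-limited substrate supply)
    and no effect in the mineral layer, emulating the field contrast.
    """
    rng = config.rng(_S_INC)
    rows = []
    for layer in ("O", "mineral"):
        a_rm = config.inc_a_rm_o if layer == "O" else config.inc_a_rm_mineral
        for treatment in ("control", "warmed"):
            m_rm = m_rn = 1.0
            if treatment == "warmed" and layer == "O":
                m_rm, m_rn = config.inc_warm_mult_rm_o, config.inc_warm_mult_rn_o
            for temp in config.inc_temps:
                r_m = m_rm * a_rm * math.exp(config.inc_b * temp)
                r_n = m_rn * config.inc_nitrif_frac * a_rm \
                    * math.exp(config.inc_b * temp)
                for rep in range(config.inc_replicates):
                    nh4_b = max(rng.normal(8.0, 1.5), 0.5)
                    no3_b = max(rng.normal(5.0, 1.0), 0.5)
                    noise = rng.normal(0.0, config.inc_noise_sd, size=2) \
                        if config.inc_noise_sd > 0 else np.zeros(2)
                    rows.append({
                        "sample_id": f"{layer}-{treatment}-{temp:g}-{rep + 1}",
                        "layer": layer, "treatment": treatment,
                        "temp_C": temp,
                        "nh4_before": nh4_b, "no3_before": no3_b,
                        "nh4_after": max(nh4_b + (r_m - r_n) * config.inc_days
                                         + noise[0], 0.0),
                        "no3_after": max(no3_b + r_n * config.inc_days
                                         + noise[1], 0.0),
                        "days": config.inc_days,
                    })
    return pd.DataFrame(rows)


def make_study_table(seed: int = 1234, n_sites: int = 10,
                     target_r2: float = 0.45, slope: float = 0.012,
                     intercept: float = 0.02) -> pd.DataFrame:
    """Synthetic stand-in for a cross-study warming-site table.

    Ten temperate-forest warming sites with plausible covariates; the
    RRn–ΔWFPS relation is constructed (residuals orthogonalized against
    the predictor and scaled) so an OLS of RRn on ΔWFPS has exactly the
    requested R².  This is a synthetic stand-in with the published
    site-table schema, not transcribed study data.
    """
    rng = np.random.default_rng(seed)
    map_mm = np.sort(rng.uniform(450.0, 1450.0, n_sites))
    dwfps = -28.0 + 0.022 * map_mm + rng.normal(0.0, 4.0, n_sites)
    dwfps = np.clip(dwfps, -30.0, 12.0)
    delta_t = np.round(rng.uniform(1.0, 4.0, n_sites), 1)
    signal = slope * dwfps
    resid = rng.normal(0.0, 1.0, n_sites)
    resid -= resid.mean()
    x = dwfps - dwfps.mean()
    resid -= (resid @ x) / (x @ x) * x
    var_sig = signal.var()
    resid *= math.sqrt(var_sig * (1.0 - target_r2) / target_r2) / resid.std()
    rrn_vals = intercept + signal + resid
    n2o_control = rng.uniform(3.0, 35.0, n_sites)
    df = pd.DataFrame({
        "site_id": [f"SYN{i + 1:02d}" for i in range(n_sites)],
        "mat_C": np.round(rng.uniform(0.0, 10.0, n_sites), 1),
        "map_mm": np.round(map_mm, 0),
        "ndep": np.round(rng.uniform(5.0, 25.0, n_sites), 1),
        "ph": np.round(rng.uniform(4.0, 6.5, n_sites), 2),
        "soc": np.round(rng.uniform(20.0, 120.0, n_sites), 1),
        "cn": np.round(rng.uniform(10.0, 20.0, n_sites), 1),
        "bd": np.round(rng.uniform(0.6, 1.2, n_sites), 2),
        "soil_temp": np.round(rng.uniform(5.0, 15.0, n_sites), 1),
        "delta_t": delta_t,
        "wfps": np.round(rng.uniform(25.0, 65.0, n_sites), 1),
        "delta_wfps_pct": dwfps,
        "n2o_control": n2o_control,
        "n2o_warmed": n2o_control * (1.0 + rrn_vals * delta_t),
        "rrn": rrn_vals,
    })
    return df
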