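"""Chamber-based NO and N2O flux estimation and temporal aggregation.

The automated chambers are vented: during a 20-min closure the analyzer
withdraws air which is replaced by ambient makeup air at flow Q, so the
soil flux appears partly as a concentration rise (accumulation) and
partly as a steady chamber-minus-ambient offset (dynamic/dilution term).
The hybrid estimator sums both:

    F = [ dC/dt · V/A  +  (C_out - C_in) · Q/A ] · M/V0 · P/P0 · T0/T

with dC/dt from ordinary least squares over a species-specific window
(min 6-10 for NO, 6-20 for N2O), C_out the window-mean chamber
concentration, and C_in the ambient concentration recorded in the 30 s
after the chamber opens.  Concentrations are dry mole fractions
(nmol mol⁻¹); the trailing factor is the single ppb→µg N m⁻³ conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (CONSTANTS, KG_HA_PER_UGM2H_DAY, M_N,
                        mole_fraction_to_mass)

logger = logging.getLogger(__name__)

#: OLS regression window per species, minutes since closure.
REGRESSION_WINDOWS_MIN = {"NO": (6.0, 10.0), "N2O": (6.0, 20.0)}


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber system geometry and plumbing."""

    volume_m3: float = 0.091       # chamber + tubing + analyzer volume
    area_m2: float = 0.18          # covered soil area
    flow_m3_h: float = 0.18        # analyzer withdrawal / makeup flow (3 L min⁻¹)
    closure_minutes: float = 20.0
    flush_minutes: float = 3.0     # lids unlocked to purge the gas line
    ambient_window_s: float = 30.0  # post-opening ambient segment

    def __post_init__(self):
        for name in ("volume_m3", "area_m2", "flow_m3_h", "closure_minutes",
                     "flush_minutes", "ambient_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def turnover_h(self) -> float:
        """Headspace turnover time V/Q in hours (≈30 min with defaults)."""
        return self.volume_m3 / self.flow_m3_h


@dataclass
class ClosureSeries:
    """One chamber-closure event: timestamped mole fractions plus context.

    ``t_s`` is seconds since closure; samples with t_s beyond the closure
    duration form the post-opening ambient segment.  ``ambient_c`` may be
    given directly; otherwise it is taken as the mean of that segment.
    """

    species: str
    t_s: np.ndarray
    conc_nmol_mol: np.ndarray
    temp_k: float
    pressure_hpa: float
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    chamber_id: str = "C1"
    plot_id: str = "P1"
    treatment: str = "control"
    start: object = None
    ambient_c: float | None = None
    true_flux: float | None = None  # set by the closure simulator, for recovery tests

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.conc_nmol_mol = np.asarray(self.conc_nmol_mol, dtype=float)
        if self.t_s.shape != self.conc_nmol_mol.shape:
            raise ValueError("t_s and conc_nmol_mol must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("samples must be strictly time-ordered")
        if self.temp_k <= 0 or self.pressure_hpa <= 0:
            raise ValueError("chamber temperature and pressure must be positive")
        if self.species not in M_N:
            raise ValueError(f"unknown species {self.species!r}")

    def resolve_ambient(self) -> float:
        if self.ambient_c is not None:
            return float(self.ambient_c)
        post = self.t_s > self.geometry.closure_minutes * 60.0
        if not np.any(post):
            raise ValueError("no post-opening ambient segment and no ambient_c")
        return float(np.mean(self.conc_nmol_mol[post]))


@dataclass
class QCConfig:
    """Quality-control settings for :func:`compute_flux`."""

    min_r2: float | None = None     # optional minimum slope-fit R² (off by default)
    spike_mad: float = 5.0          # drop window samples > this many MADs from median
    min_samples: int = 4


@dataclass
class FluxRecord:
    """Estimated flux for one closure, with both estimator terms kept."""

    species: str
    flux: float                     # µg N m⁻² h⁻¹ (NaN when QC-invalid)
    slope_nmol_mol_h: float
    slope_r2: float
    accumulation: float             # µg N m⁻² h⁻¹
    dynamic: float                  # µg N m⁻² h⁻¹
    chamber_id: str = "C1"
    plot_id: str = "P1"
    treatment: str = "control"
    timestamp: object = None
    qc_flags: tuple = ()
    true_flux: float | None = None


def _window_mask(t_s: np.ndarray, species: str) -> np.ndarray:
    lo, hi = REGRESSION_WINDOWS_MIN[species]
    return (t_s >= lo * 60.0) & (t_s <= hi * 60.0)


def compute_flux(closure: ClosureSeries, qc: QCConfig | None = None) -> FluxRecord:
    """Hybrid accumulation + dynamic flux estimate for one closure.

    Returns a flagged record with ``flux`` NaN when fewer than
    ``qc.min_samples`` usable samples remain in the regression window;
    non-finite concentrations raise.
    """
    qc = qc or QCConfig()
    if not np.all(np.isfinite(closure.conc_nmol_mol)):
        raise ValueError("non-finite concentrations in closure series")
    geom = closure.geometry
    mask = _window_mask(closure.t_s, closure.species)
    t = closure.t_s[mask] / 3600.0  # hours
    c = closure.conc_nmol_mol[mask]
    flags: list[str] = []

    if len(c) >= qc.min_samples:
        med = np.median(c)
        mad = np.median(np.abs(c - med))
        if mad > 0:
            keep = np.abs(c - med) <= qc.spike_mad * mad
            if not np.all(keep):
                flags.append("spikes_removed")
                t, c = t[keep], c[keep]

    ambient = closure.resolve_ambient()
    meta = dict(species=closure.species, chamber_id=closure.chamber_id,
                plot_id=closure.plot_id, treatment=closure.treatment,
                timestamp=closure.start, true_flux=closure.true_flux)

    if len(c) < qc.min_samples:
        flags.append("too_few_samples")
        return FluxRecord(flux=np.nan, slope_nmol_mol_h=np.nan, slope_r2=np.nan,
                          accumulation=np.nan, dynamic=np.nan,
                          qc_flags=tuple(flags), **meta)

    tbar = t.mean()
    dt = t - tbar
    slope = float(dt @ (c - c.mean()) / (dt @ dt))
    resid = c - (c.mean() + slope * dt)
    sst = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 1.0
    c_chamber = float(c.mean())

    conv = mole_fraction_to_mass(closure.species, closure.temp_k,
                                 closure.pressure_hpa)
    acc = slope * geom.volume_m3 / geom.area_m2 * conv
    dyn = (c_chamber - ambient) * geom.flow_m3_h / geom.area_m2 * conv
    flux = acc + dyn
    if qc.min_r2 is not None and r2 < qc.min_r2:
        flags.append("low_r2")
    return FluxRecord(flux=flux, slope_nmol_mol_h=slope, slope_r2=r2,
                      accumulation=acc, dynamic=dyn, qc_flags=tuple(flags),
                      **meta)


def compute_flux_batch(t_s: np.ndarray, conc: np.ndarray, species: str,
                       temp_k, pressure_hpa, ambient_c,
                       geometry: ChamberGeometry | None = None):
    """Vectorized estimator over many closures sharing one sample grid.

    Parameters
    ----------
    t_s : (k,) sample times, seconds since closure (regression-window
        samples only, or a full grid — samples outside the window are
        ignored exactly as in :func:`compute_flux`, minus spike QC).
    conc : (n, k) concentrations, nmol mol⁻¹.
    temp_k, pressure_hpa, ambient_c : scalars or (n,) arrays.

    Returns dict of (n,) arrays: flux, slope, accumulation, dynamic, r2.
    """
    geometry = geometry or ChamberGeometry()
    t_s = np.asarray(t_s, dtype=float)
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    mask = _window_mask(t_s, species)
    t = t_s[mask] / 3600.0
    c = conc[:, mask]
    tbar = t.mean()
    dt = t - tbar
    denom = dt @ dt
    cbar = c.mean(axis=1)
    slope = (c - cbar[:, None]) @ dt / denom
    resid = c - cbar[:, None] - slope[:, None] * dt[None, :]
    sst = ((c - cbar[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - (resid ** 2).sum(axis=1) / sst, 1.0)
    conv = mole_fraction_to_mass(species, np.asarray(temp_k, dtype=float),
                                 np.asarray(pressure_hpa, dtype=float))
    acc = slope * geometry.volume_m3 / geometry.area_m2 * conv
    dyn = (cbar - np.asarray(ambient_c, dtype=float)) \
        * geometry.flow_m3_h / geometry.area_m2 * conv
    return {"flux": acc + dyn, "slope": slope, "accumulation": acc,
            "dynamic": dyn, "r2": r2}


def records_to_frame(records) -> pd.DataFrame:
    """Flatten FluxRecord objects into the tabular layout used downstream."""
    rows = []
    for r in records:
        rows.append({
            "timestamp": r.timestamp, "plot_id": r.plot_id,
            "chamber_id": r.chamber_id, "treatment": r.treatment,
            "species": r.species, "flux": r.flux,
            "slope_nmol_mol_h": r.slope_nmol_mol_h, "slope_r2": r.slope_r2,
            "accumulation": r.accumulation, "dynamic": r.dynamic,
            "qc_flags": ";".join(r.qc_flags), "true_flux": r.true_flux,
        })
    return pd.DataFrame(rows)


def daily_aggregate(records: pd.DataFrame,
                    date_col: str = "date") -> pd.DataFrame:
    """Daily mean fluxes per treatment and species.

    The treatment daily mean is the mean over chambers of chamber means
    (equal chamber weighting, robust to unequal closure counts), and the
    SE is computed across chamber means.  Chamber means within a plot are
    pseudo-replicates of the plot; the chamber-level SE is reported as a
    precision of the daily mean, not an inferential plot-level error.
    QC-flagged or non-finite fluxes are excluded and counted.
    """
    df = records.copy()
    if date_col not in df.columns:
        df[date_col] = pd.to_datetime(df["timestamp"]).dt.normalize()
    flagged = df["qc_flags"].fillna("").astype(str).str.len() > 0 \
        if "qc_flags" in df.columns else pd.Series(False, index=df.index)
    bad = flagged | ~np.isfinite(df["flux"])
    day_keys = [date_col, "treatment", "species"]
    chamber_means = (df[~bad]
                     .groupby(day_keys + ["plot_id", "chamber_id"],
                              sort=True, observed=True)
                     .agg(flux=("flux", "mean"), n=("flux", "size")))
    if chamber_means.empty:
        logger.warning("daily_aggregate: no QC-passing fluxes")
        return pd.DataFrame(columns=["date", "treatment", "species",
                                     "mean_flux", "se", "n_fluxes",
                                     "n_chambers", "n_excluded"])
    g = chamber_means.groupby(level=day_keys, sort=True)
    out = pd.DataFrame({
        "mean_flux": g["flux"].mean(),
        "se": g["flux"].sem(ddof=1),
        "n_fluxes": g["n"].sum().astype(int),
        "n_chambers": g["flux"].size().astype(int),
    })
    out.loc[out["n_chambers"] < 2, "se"] = np.nan
    excluded = (df[bad].groupby(day_keys, sort=True, observed=True).size()
                .reindex(out.index, fill_value=0))
    out["n_excluded"] = excluded.astype(int)
    out = out.reset_index()
    if date_col != "date":
        out = out.rename(columns={date_col: "date"})
    return out


@dataclass
class CumulativeFlux:
    """Time-integrated flux over a period, in kg N ha⁻¹."""

    label: str
    treatment: str
    species: str
    kg_n_ha: float
    coverage: float                 # fraction of period days observed or gap-filled
    flagged: bool = False           # True when gaps exceeded the interpolation cap


SNOW_MONTHS = (12, 1, 2, 3)  # December through March


def _filled_daily_series(daily: pd.DataFrame, start, end,
                         max_gap_days: int = 7):
    """Reindex daily means onto the full period and fill short gaps.

    Returns (values, coverage, flagged): linear interpolation fills
    interior gaps of at most ``max_gap_days``; longer gaps (and missing
    edges) stay NaN, drop coverage below 1 and set the flag.
    """
    s = (daily.set_index("date")["mean_flux"]
         .reindex(pd.date_range(start, end, freq="D")))
    filled = s.interpolate(method="linear", limit=max_gap_days,
                           limit_area="inside")
    coverage = float(filled.notna().mean())
    return filled, coverage, bool(coverage < 1.0)


def cumulative_flux(daily: pd.DataFrame, start=None, end=None,
                    label: str = "period", snow_zero: bool | None = None,
                    max_gap_days: int = 7) -> CumulativeFlux:
    """Integrate daily mean fluxes to kg N ha⁻¹ over [start, end].

    Each daily mean represents the whole day, so the integral is the sum
    of daily means × 24 h (trapezoidal integration of the piecewise-
    constant daily series); 1 µg N m⁻² h⁻¹ over one day = 2.4e-4 kg N ha⁻¹.

    ``snow_zero`` applies the snow-cover annualization rule — fluxes
    during December–March are taken as negligible (zero).  Default: on
    for NO, off for N2O (freeze-thaw N2O in late winter is real signal).
    Days still missing after gap filling contribute zero and are reported
    through ``coverage``/``flagged``.
    """
    if daily.empty:
        raise ValueError("cumulative_flux: empty daily series")
    daily = daily.sort_values("date")
    for col in ("treatment", "species"):
        if daily[col].nunique() > 1:
            raise ValueError(f"cumulative_flux expects a single {col}")
    species = daily["species"].iloc[0]
    treatment = daily["treatment"].iloc[0]
    start = pd.Timestamp(start) if start is not None else daily["date"].min()
    end = pd.Timestamp(end) if end is not None else daily["date"].max()
    if start > end:
        raise ValueError("empty period: start after end")
    if snow_zero is None:
        snow_zero = species == "NO"
    filled, coverage, flagged = _filled_daily_series(daily, start, end,
                                                     max_gap_days)
    if snow_zero:
        in_snow = filled.index.month.isin(SNOW_MONTHS)
        filled = filled.copy()
        filled[in_snow] = 0.0
        coverage = float(filled.notna().mean())
        flagged = coverage < 1.0
    total = float(filled.fillna(0.0).sum()) * KG_HA_PER_UGM2H_DAY
    return CumulativeFlux(label=label, treatment=treatment, species=species,
                          kg_n_ha=total, coverage=coverage, flagged=flagged)


#: Season calendar as {label: set of months}; must partition the year.
DEFAULT_SEASONS = {"growing": {5, 6, 7, 8, 9, 10},
                   "dormant": {11, 12, 1, 2, 3, 4}}


def seasonal_partition(daily: pd.DataFrame, calendar: dict | None = None,
                       start=None, end=None, snow_zero: bool | None = None,
                       max_gap_days: int = 7) -> list[CumulativeFlux]:
    """Split the cumulative flux by season; shares sum to the period total.

    ``calendar`` maps season labels to sets of calendar months; the
    windows must be non-overlapping and exhaustive.  Gap filling and the
    snow policy are applied once on the full period so that per-season
    values add up exactly to :func:`cumulative_flux` over the same period.
    """
    calendar = calendar or DEFAULT_SEASONS
    months = [m for s in calendar.values() for m in s]
    if len(months) != len(set(months)):
        raise ValueError("season windows overlap")
    if set(months) != set(range(1, 13)):
        raise ValueError("season windows must cover all 12 months")
    if daily.empty:
        raise ValueError("seasonal_partition: empty daily series")
    daily = daily.sort_values("date")
    species = daily["species"].iloc[0]
    treatment = daily["treatment"].iloc[0]
    start = pd.Timestamp(start) if start is not None else daily["date"].min()
    end = pd.Timestamp(end) if end is not None else daily["date"].max()
    if snow_zero is None:
        snow_zero = species == "NO"
    filled, _, _ = _filled_daily_series(daily, start, end, max_gap_days)
    if snow_zero:
        filled = filled.copy()
        filled[filled.index.month.isin(SNOW_MONTHS)] = 0.0
    out = []
    for lab, mset in calendar.items():
        sel = filled[filled.index.month.isin(mset)]
        out.append(CumulativeFlux(
            label=lab, treatment=treatment, species=species,
            kg_n_ha=float(sel.fillna(0.0).sum()) * KG_HA_PER_UGM2H_DAY,
            coverage=float(sel.notna().mean()) if len(sel) else 1.0,
            flagged=bool(len(sel) and sel.isna().any())))
    return out
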