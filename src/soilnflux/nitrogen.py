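"""N2 upscaling from N2O, and net N-transformation rate kinetics.

Direct field N2 flux measurement is infeasible against the atmospheric
background, so daily N2 is approximated from the denitrification
completeness ratio, an empirical linear function of soil moisture
calibrated with an in-situ 15N tracer:

    F_N2 = max(0, 0.13·WFPS − 1.10) · F_N2O

Net N mineralization and nitrification rates come from one-week
incubations of field soil across 5–25 °C:

    R_M = [(NH4_after + NO3_after) − (NH4_before + NO3_before)] / T
    R_N = (NO3_after − NO3_before) / T

and are extrapolated to field temperatures with an Arrhenius-type
exponential R = a·e^(bT).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import chamber

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class N2ScalingModel:
    """Moisture-driven N2:N2O ratio model (slope per %WFPS).

    The ratio has no temperature term: a temperature-gradient incubation
    showed consistent moisture regulation of N2:N2O across 5–25 °C with
    no significant temperature effect, so temperature is deliberately
    absent from this model's structure.
    """

    slope: float = 0.13
    intercept: float = 1.10
    validity_wfps: tuple = (15.0, 75.0)  # field-observed WFPS range; configurable

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("ratio slope must be positive")

    def ratio(self, wfps):
        """N2:N2O ratio, clamped at zero below its root (≈8.5 % WFPS)."""
        return np.maximum(0.0, self.slope * np.asarray(wfps, dtype=float)
                          - self.intercept)


def estimate_n2(n2o_flux, wfps, model: N2ScalingModel | None = None):
    """Daily N2 flux (µg N m⁻² h⁻¹) from N2O flux and WFPS.

    Negative N2O fluxes (chamber uptake days) give a missing N2 value
    (NaN) — scaling an uptake to a negative N2 efflux would be
    non-physical.  WFPS outside the model's calibrated validity range
    warns but still evaluates.
    """
    model = model or N2ScalingModel()
    wfps = np.asarray(wfps, dtype=float)
    if np.any(wfps < 0) or np.any(wfps > 100):
        raise ValueError("WFPS must lie in [0, 100]")
    lo, hi = model.validity_wfps
    if np.any((wfps < lo) | (wfps > hi)):
        warnings.warn(
            f"WFPS outside the N2:N2O calibration range [{lo}, {hi}] %",
            stacklevel=2)
    n2o = np.asarray(n2o_flux, dtype=float)
    neg = n2o < 0
    if np.any(neg):
        logger.info("estimate_n2: %d negative N2O flux value(s) -> N2 missing",
                    int(np.sum(neg)))
    out = np.where(neg, np.nan, model.ratio(wfps) * n2o)
    return out if out.ndim else float(out)


def seasonal_n2(daily_n2o: pd.DataFrame, wfps_by_date: pd.Series,
                model: N2ScalingModel | None = None,
                start=None, end=None, label: str = "growing",
                max_gap_days: int = 7) -> chamber.CumulativeFlux:
    """Growing-season cumulative N2 (kg N ha⁻¹) from daily N2O and WFPS.

    ``daily_n2o`` is a daily-aggregate frame (one treatment, species
    N2O); ``wfps_by_date`` a date-indexed WFPS series for the same
    treatment.  Daily N2 is formed via :func:`estimate_n2` and integrated
    with the same machinery as the measured species.  The published N2
    estimate is a growing-season quantity, hence the default label.
    """
    df = daily_n2o.copy().sort_values("date")
    if df["species"].nunique() != 1 or df["species"].iloc[0] != "N2O":
        raise ValueError("seasonal_n2 expects a daily N2O frame")
    wfps = wfps_by_date.reindex(pd.DatetimeIndex(df["date"]))
    missing = wfps.isna()
    if missing.any():
        logger.warning("seasonal_n2: %d days lack WFPS; dropped",
                       int(missing.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # validity warning handled per-day upstream
        n2 = estimate_n2(df["mean_flux"].to_numpy(), wfps.to_numpy(), model)
    out = df[["date", "treatment"]].copy()
    out["species"] = "N2"
    out["mean_flux"] = n2
    out = out.dropna(subset=["mean_flux"])
    if out.empty:
        raise ValueError("no usable N2 days in the requested period")
    return chamber.cumulative_flux(out, start=start, end=end, label=label,
                                   snow_zero=False, max_gap_days=max_gap_days)


@dataclass
class RateResult:
    """Net N mineralization and nitrification rates, mg N kg⁻¹ d⁻¹.

    Net rates may be negative (immobilization / NO3 consumption); no
    clipping is applied.
    """

    r_m: float
    r_n: float

    @property
    def net_ammonification(self) -> float:
        """R_M − R_N: the NH4-pool component of net mineralization."""
        return self.r_m - self.r_n


def net_rates(nh4_before, no3_before, nh4_after, no3_after,
              days: float = 7.0) -> RateResult:
    """Net N mineralization (R_M) and nitrification (R_N) from pool changes."""
    if days <= 0:
        raise ValueError("incubation duration must be positive")
    r_m = ((nh4_after + no3_after) - (nh4_before + no3_before)) / days
    r_n = (no3_after - no3_before) / days
    return RateResult(r_m=float(r_m), r_n=float(r_n))


def net_rates_frame(inc: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`net_rates` over an incubation table.

    Expects columns nh4_before, no3_before, nh4_after, no3_after, days;
    appends r_m and r_n.
    """
    if (inc["days"] <= 0).any():
        raise ValueError("incubation duration must be positive")
    out = inc.copy()
    out["r_m"] = ((inc["nh4_after"] + inc["no3_after"])
                  - (inc["nh4_before"] + inc["no3_before"])) / inc["days"]
    out["r_n"] = (inc["no3_after"] - inc["no3_before"]) / inc["days"]
    return out


@dataclass
class ArrheniusFit:
    """Exponential temperature dependence of a net rate: R = a·e^(bT)."""

    a: float
    b: float
    r2: float
    t_range: tuple

    def predict(self, temp, guard_c: float = 5.0):
        """Rate at a query temperature (°C); warns beyond ±guard_c of the fit range."""
        temp_arr = np.asarray(temp, dtype=float)
        lo, hi = self.t_range
        if np.any((temp_arr < lo - guard_c) | (temp_arr > hi + guard_c)):
            warnings.warn(
                f"extrapolating more than {guard_c} °C beyond the fitted "
                f"range [{lo}, {hi}] °C", stacklevel=2)
        out = self.a * np.exp(self.b * temp_arr)
        return out if out.ndim else float(out)


def fit_arrhenius(temps, rates) -> ArrheniusFit:
    """Least-squares fit of R = a·e^(bT) over an incubation gradient."""
    t = np.asarray(temps, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 incubation temperatures")
    if np.ptp(t) == 0:
        raise ValueError("all incubation temperatures equal")
    pos = r > 0
    if pos.sum() >= 2:
        b0, loga0 = np.polyfit(t[pos], np.log(r[pos]), 1)
        p0 = [float(np.exp(loga0)), float(b0)]
    else:
        p0 = [max(r.mean(), 1e-6), 0.0]
    popt, _ = curve_fit(lambda T, a, b: a * np.exp(b * T), t, r, p0=p0,
                        maxfev=20000, xtol=1e-12, ftol=1e-12)
    a, b = float(popt[0]), float(popt[1])
    pred = a * np.exp(b * t)
    sst = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - float(((r - pred) ** 2).sum()) / sst if sst > 0 else 1.0
    return ArrheniusFit(a=a, b=b, r2=r2,
                        t_range=(float(t.min()), float(t.max())))


def predict_rate(fit: ArrheniusFit, temp) -> float:
    """Convenience wrapper: rate at a field temperature (°C)."""
    return fit.predict(temp)
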