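"""Warming effect sizes and the cross-study moisture regression.

Two standard effect metrics for manipulation experiments:

  * lnRR = ln(X_W / X_C), the log response ratio;
  * RRn  = ((X_W − X_C)/X_C) / ΔT, the response ratio standardized to
    1 °C of realized warming, which makes studies with different
    warming magnitudes comparable.

The cross-study synthesis regresses per-site N2O RRn on the
warming-induced relative change in soil moisture (ΔWFPS, %) by ordinary
least squares — an unweighted cross-site regression, not a formal
random-effects meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def lnrr(x_w, x_c):
    """Log response ratio ln(X_W) − ln(X_C); NaN for non-positive inputs.

    Non-positive means cannot be log-transformed; they yield NaN (with a
    log message) rather than raising, since whole tables are processed.
    """
    x_w = np.asarray(x_w, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    bad = (x_w <= 0) | (x_c <= 0)
    if np.any(bad):
        logger.info("lnrr: %d non-positive pair(s) -> NaN", int(np.sum(bad)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, np.log(x_w) - np.log(x_c))
    return out if out.ndim else float(out)


def rrn(x_w, x_c, delta_t):
    """Warming response standardized to 1 °C: ((X_W − X_C)/X_C) / ΔT."""
    if np.any(np.asarray(delta_t, dtype=float) <= 0):
        raise ValueError("realized warming ΔT must be positive")
    x_c = np.asarray(x_c, dtype=float)
    if np.any(x_c == 0):
        raise ValueError("control mean of zero: response ratio undefined")
    out = ((np.asarray(x_w, dtype=float) - x_c) / x_c) / np.asarray(
        delta_t, dtype=float)
    return out if out.ndim else float(out)


@dataclass
class EffectSize:
    """Warming effect for one variable, averaged over sampling times."""

    variable: str
    x_w: float
    x_c: float
    relative_effect_pct: float     # mean of (W−C)/C · 100 across times
    lnrr: float                    # mean log response ratio
    se: float                      # bootstrap SE of the relative effect (NaN if n=1)
    n: int


def effect_table(paired: pd.DataFrame, n_boot: int = 1000,
                 seed: int = 0) -> list[EffectSize]:
    """Per-variable warming effects from paired control/warmed summaries.

    ``paired`` has one row per (variable, sampling time) with columns
    variable, x_c, x_w.  The relative effect (warmed−control)/control is
    averaged across sampling times; its SE comes from a seeded bootstrap
    over sampling times (the resampling unit is the sampling occasion).
    Rows with missing members of a pair are skipped with a log message.
    """
    rng = np.random.default_rng(seed)
    out = []
    for var, sub in paired.groupby("variable", sort=False):
        sub = sub.dropna(subset=["x_c", "x_w"])
        if sub.empty or (sub["x_c"] == 0).any():
            logger.info("effect_table: variable %r unpaired or zero control; "
                        "skipped", var)
            continue
        rel = ((sub["x_w"] - sub["x_c"]) / sub["x_c"]).to_numpy()
        if len(rel) > 1:
            idx = rng.integers(0, len(rel), size=(n_boot, len(rel)))
            se = float(rel[idx].mean(axis=1).std(ddof=1) * 100.0)
        else:
            se = np.nan
        out.append(EffectSize(
            variable=var, x_w=float(sub["x_w"].mean()),
            x_c=float(sub["x_c"].mean()),
            relative_effect_pct=float(rel.mean() * 100.0),
            lnrr=float(np.nanmean(lnrr(sub["x_w"].to_numpy(),
                                       sub["x_c"].to_numpy()))),
            se=se, n=len(rel)))
    return out


STUDY_TABLE_COLUMNS = ["site_id", "mat_C", "map_mm", "ndep", "ph", "soc",
                       "cn", "bd", "soil_temp", "delta_t", "wfps",
                       "delta_wfps_pct", "n2o_control", "n2o_warmed"]


@dataclass
class MetaRegressionResult:
    """OLS of per-site RRn on ΔWFPS, with the site table echoed."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    predictor: str = "delta_wfps_pct"
    studies: pd.DataFrame | None = field(default=None, repr=False)


def meta_regression(studies: pd.DataFrame,
                    predictor: str = "delta_wfps_pct",
                    response: str = "rrn") -> MetaRegressionResult:
    """Cross-study OLS of the standardized N2O response on moisture change.

    ``studies`` needs one row per site with either an ``rrn`` column or
    the triple (n2o_control, n2o_warmed, delta_t) from which RRn is
    derived.  At least 4 usable rows are required; a constant predictor
    is a degenerate design and raises.
    """
    df = studies.copy()
    if response not in df.columns:
        df[response] = rrn(df["n2o_warmed"], df["n2o_control"], df["delta_t"])
    df = df.dropna(subset=[predictor, response])
    if len(df) < 4:
        raise ValueError("need at least 4 studies with predictor and response")
    x = df[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: predictor is constant")
    model = sm.OLS(df[response].to_numpy(dtype=float),
                   sm.add_constant(x)).fit()
    return MetaRegressionResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), p_value=float(model.pvalues[1]),
        n=len(df), predictor=predictor, studies=df)


@dataclass
class SpeciesSummary:
    control_kg_ha: float
    warmed_kg_ha: float
    observed_change_pct: float
    expected_increase_pct: float | None = None
    shortfall_pct: float | None = None


@dataclass
class WarmingSummary:
    """Headline warming report across species, plus the total N budget."""

    species: dict                  # name -> SpeciesSummary
    total_control_kg_ha: float
    total_warmed_kg_ha: float
    total_change_pct: float
    total_expected_increase_pct: float | None
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "species": {k: vars(v) for k, v in self.species.items()},
            "total_control_kg_ha": self.total_control_kg_ha,
            "total_warmed_kg_ha": self.total_warmed_kg_ha,
            "total_change_pct": self.total_change_pct,
            "total_expected_increase_pct": self.total_expected_increase_pct,
            "flags": list(self.flags),
        }


def warming_summary(cumulative: dict, q10s: dict | None = None,
                    delta_t: float = 2.0) -> WarmingSummary:
    """Assemble the per-species and total warming response report.

    Parameters
    ----------
    cumulative : dict
        species -> (control_kg_ha, warmed_kg_ha) cumulative fluxes over a
        common period (typically NO, N2O annual and N2 growing-season).
    q10s : dict
        species -> apparent Q10 used for the expected-change yardstick;
        species without a Q10 get observed changes only.

    The total change is the flux-weighted combination of the per-species
    changes (exactly: the relative change of the summed flux).
    """
    q10s = q10s or {}
    flags = []
    species = {}
    tot_c = tot_w = 0.0
    exp_tot = 0.0
    exp_ok = True
    for name, (ctrl, warm) in cumulative.items():
        if not (np.isfinite(ctrl) and np.isfinite(warm)) or ctrl <= 0:
            flags.append(f"{name}: unusable cumulative values")
            continue
        obs = (warm / ctrl - 1.0) * 100.0
        entry = SpeciesSummary(control_kg_ha=float(ctrl),
                               warmed_kg_ha=float(warm),
                               observed_change_pct=float(obs))
        if name in q10s:
            factor = q10s[name] ** (delta_t / 10.0)
            entry.expected_increase_pct = (factor - 1.0) * 100.0
            entry.shortfall_pct = (warm / (ctrl * factor) - 1.0) * 100.0
            exp_tot += ctrl * factor
        else:
            exp_ok = False
        species[name] = entry
        tot_c += ctrl
        tot_w += warm
    if not species:
        raise ValueError("no usable species in warming_summary")
    return WarmingSummary(
        species=species, total_control_kg_ha=tot_c, total_warmed_kg_ha=tot_w,
        total_change_pct=(tot_w / tot_c - 1.0) * 100.0,
        total_expected_increase_pct=(exp_tot / tot_c - 1.0) * 100.0
        if exp_ok and tot_c > 0 else None,
        flags=tuple(flags))
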