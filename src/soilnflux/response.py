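"""Temperature and moisture response models for gaseous N fluxes.

Fluxes are binned against same-day soil state (0.5 °C temperature bins,
1 % WFPS bins) and the response functions are fitted to the bin means:

  * temperature: F = A·e^(k·T), apparent sensitivity Q10 = e^(10k);
  * moisture: a quadratic in WFPS whose (downward) vertex is the optimum.

The Q10-expected counterfactual F_control·Q10^(ΔT/10) gives the flux a
warmed plot should show if temperature were the only control, the
yardstick against which observed warming responses are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the log-linear initializer estimates."""

    def __init__(self, msg, a0=None, k0=None):
        super().__init__(msg)
        self.a0, self.k0 = a0, k0


def bin_fluxes(matched: pd.DataFrame, variable: str, width: float,
               flux_col: str = "mean_flux",
               season: str | None = None) -> pd.DataFrame:
    """Average fluxes in left-closed, right-open bins of a soil variable.

    ``matched`` must carry the flux column and the binning variable
    (e.g. daily fluxes joined to same-day soil temperature or WFPS);
    an optional ``season`` filters on a 'season' column first.
    Empty bins are dropped.  Returns columns bin_center, bin_left,
    mean_flux, n.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    df = matched
    if season is not None:
        df = df[df["season"] == season]
    df = df.dropna(subset=[variable, flux_col])
    if df.empty:
        raise ValueError("no matched flux/soil-state records to bin")
    left = np.floor(df[variable] / width) * width
    g = df.groupby(left)[flux_col]
    out = pd.DataFrame({"bin_left": g.mean().index.values,
                        "mean_flux": g.mean().values,
                        "n": g.size().values})
    out["bin_center"] = out["bin_left"] + width / 2.0
    out["bin_width"] = width
    return out[["bin_center", "bin_left", "bin_width", "mean_flux", "n"]]


@dataclass
class TempResponseFit:
    """Fitted exponential temperature response F = A·e^(kT)."""

    a: float            # µg N m⁻² h⁻¹ at 0 °C
    k: float            # per °C
    q10: float          # e^(10k), kept consistent with k by construction
    r2: float
    n_bins: int
    t_range: tuple

    def predict(self, temp):
        return self.a * np.exp(self.k * np.asarray(temp, dtype=float))


def q10_from_k(k: float) -> float:
    """Apparent Q10 from the exponential rate constant: e^(10k)."""
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    return float(np.exp(10.0 * k))


def fit_temperature_response(bins: pd.DataFrame, weighted: bool = False,
                             x_col: str = "bin_center",
                             y_col: str = "mean_flux") -> TempResponseFit:
    """Nonlinear least squares of F = A·e^(kT) on bin means.

    Requires at least 5 bins spanning at least 5 °C.  A log-linear
    regression on the positive bin means provides the initializer only;
    the reported parameters come from the nonlinear fit on the original
    scale.  ``weighted=True`` weights bins by their observation counts
    (default is unweighted, one point per bin).
    """
    t = np.asarray(bins[x_col], dtype=float)
    f = np.asarray(bins[y_col], dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 bins for the temperature fit")
    if t.max() - t.min() < 5.0:
        raise ValueError("bins must span at least 5 °C")
    pos = f > 0
    if pos.sum() < 2:
        raise ValueError("need positive mean fluxes to initialize the fit")
    k0, loga0 = np.polyfit(t[pos], np.log(f[pos]), 1)
    a0 = float(np.exp(loga0))
    sigma = None
    if weighted:
        n = np.asarray(bins["n"], dtype=float)
        sigma = 1.0 / np.sqrt(np.maximum(n, 1.0))
    try:
        popt, _ = curve_fit(lambda T, a, k: a * np.exp(k * T), t, f,
                            p0=[a0, k0], sigma=sigma, maxfev=20000,
                            xtol=1e-12, ftol=1e-12)
    except RuntimeError as err:
        raise FitConvergenceError(str(err), a0=a0, k0=float(k0)) from err
    a, k = float(popt[0]), float(popt[1])
    pred = a * np.exp(k * t)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float(((f - pred) ** 2).sum()) / sst if sst > 0 else 1.0
    return TempResponseFit(a=a, k=k, q10=q10_from_k(k), r2=r2, n_bins=len(t),
                           t_range=(float(t.min()), float(t.max())))


@dataclass
class MoistureResponseFit:
    """Quadratic moisture response; optimum only for a concave fit."""

    c2: float
    c1: float
    c0: float
    optimum_wfps: float | None
    r2: float
    wfps_range: tuple

    def predict(self, wfps):
        w = np.asarray(wfps, dtype=float)
        return self.c2 * w ** 2 + self.c1 * w + self.c0


def fit_moisture_response(bins: pd.DataFrame, x_col: str = "bin_center",
                          y_col: str = "mean_flux") -> MoistureResponseFit:
    """Least-squares quadratic on WFPS bin means.

    The optimum −c1/(2·c2) is reported only when the parabola opens
    downward (c2 < 0) and the vertex lies inside the fitted WFPS range;
    otherwise it is None (monotone or convex responses have no interior
    optimum).
    """
    w = np.asarray(bins[x_col], dtype=float)
    f = np.asarray(bins[y_col], dtype=float)
    if len(w) < 6:
        raise ValueError("need at least 6 bins for the moisture fit")
    if np.ptp(w) == 0:
        raise ValueError("degenerate design: all bins at the same WFPS")
    c2, c1, c0 = np.polyfit(w, f, 2)
    pred = np.polyval([c2, c1, c0], w)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float(((f - pred) ** 2).sum()) / sst if sst > 0 else 1.0
    optimum = None
    if c2 < 0:
        vertex = -c1 / (2.0 * c2)
        if w.min() <= vertex <= w.max():
            optimum = float(vertex)
    return MoistureResponseFit(c2=float(c2), c1=float(c1), c0=float(c0),
                               optimum_wfps=optimum, r2=r2,
                               wfps_range=(float(w.min()), float(w.max())))


def q10_expected_flux(control_flux, q10: float, delta_t: float):
    """Counterfactual flux under ΔT of warming: F_control · Q10^(ΔT/10).

    Works at any granularity (per closure, per day, or on cumulative
    values) since the factor is flux-independent.
    """
    if q10 <= 0:
        raise ValueError("Q10 must be positive")
    return np.asarray(control_flux, dtype=float) * q10 ** (delta_t / 10.0) \
        if np.ndim(control_flux) else float(control_flux) * q10 ** (delta_t / 10.0)


@dataclass
class ShortfallReport:
    """Observed warming response versus the Q10-expected response."""

    expected_increase_pct: float   # (Q10^(ΔT/10) − 1)·100
    observed_change_pct: float     # (warmed/control − 1)·100
    shortfall_pct: float           # (warmed / expected − 1)·100; negative = below expectation
    control: float
    warmed: float
    expected: float


def expected_vs_observed(control: float, warmed: float, q10: float,
                         delta_t: float) -> ShortfallReport:
    """Compare an observed warming response with its Q10 expectation."""
    if control == 0:
        raise ValueError("zero control flux: relative change undefined")
    factor = q10 ** (delta_t / 10.0)
    expected = control * factor
    return ShortfallReport(
        expected_increase_pct=(factor - 1.0) * 100.0,
        observed_change_pct=(warmed / control - 1.0) * 100.0,
        shortfall_pct=(warmed / expected - 1.0) * 100.0,
        control=float(control), warmed=float(warmed), expected=float(expected))


def composite_expected_increase(control_fluxes: dict, q10s: dict,
                                delta_t: float) -> float:
    """Flux-weighted Q10-expected increase (%) over several species.

    Weights each species' expected fractional increase by its control
    flux — equivalently, the expected relative change of the summed flux.
    """
    tot = sum(control_fluxes.values())
    if tot <= 0:
        raise ValueError("total control flux must be positive")
    expected = sum(f * q10s[s] ** (delta_t / 10.0)
                   for s, f in control_fluxes.items())
    return (expected / tot - 1.0) * 100.0
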