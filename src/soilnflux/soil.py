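"""Soil moisture physics and treatment-contrast summaries.

Water-filled pore space (WFPS) expresses volumetric water content as a
percentage of total pore volume, with porosity derived from bulk density
and the quartz particle density (2.65 g cm⁻³):

    WFPS (%) = VWC / (1 - BD/2.65) * 100

The organic surface horizon (O horizon) is reported gravimetrically
(g H2O g⁻¹ soil) and has no meaningful bulk-density-based porosity, so
WFPS is computed for mineral layers only.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .constants import CONSTANTS

logger = logging.getLogger(__name__)

DEFAULT_BULK_DENSITY = 0.70  # g cm⁻³, 0-10 cm mineral layer


def compute_wfps(vwc, bd: float = DEFAULT_BULK_DENSITY,
                 particle_density: float = CONSTANTS.particle_density):
    """Water-filled pore space (%) from volumetric water content.

    Parameters
    ----------
    vwc : float or array
        Volumetric water content, m³ m⁻³, in [0, 1].
    bd : float
        Bulk density, g cm⁻³; must be below the particle density.
    particle_density : float
        Particle density, g cm⁻³ (quartz default 2.65).

    Values implying WFPS above 100 % (supersaturation) are capped at 100
    with a warning rather than rejected, since field probes occasionally
    overshoot porosity after heavy rain.
    """
    if bd <= 0 or bd >= particle_density:
        raise ValueError(
            f"bulk density {bd} g/cm³ must lie in (0, {particle_density}) "
            "for a positive porosity")
    vwc = np.asarray(vwc, dtype=float)
    if np.any(vwc < 0) or np.any(vwc > 1):
        raise ValueError("volumetric water content must lie in [0, 1]")
    porosity = 1.0 - bd / particle_density
    wfps = vwc / porosity * 100.0
    if np.any(wfps > 100.0):
        warnings.warn("VWC exceeds porosity; WFPS capped at 100 %",
                      stacklevel=2)
        wfps = np.minimum(wfps, 100.0)
    return wfps if wfps.ndim else float(wfps)


def invert_wfps(wfps, bd: float = DEFAULT_BULK_DENSITY,
                particle_density: float = CONSTANTS.particle_density):
    """Volumetric water content from WFPS (%); inverse of :func:`compute_wfps`."""
    porosity = 1.0 - bd / particle_density
    if porosity <= 0:
        raise ValueError("bulk density implies non-positive porosity")
    return np.asarray(wfps, dtype=float) / 100.0 * porosity


def delta_wfps(wfps_warmed, wfps_control):
    """Relative warming-induced change in WFPS, in percent.

    ΔWFPS (%) = (WFPS_W - WFPS_C) / WFPS_C * 100; negative means drying.
    """
    wfps_warmed = np.asarray(wfps_warmed, dtype=float)
    wfps_control = np.asarray(wfps_control, dtype=float)
    if np.any(wfps_control == 0):
        raise ValueError("control WFPS of zero: relative change undefined")
    out = (wfps_warmed - wfps_control) / wfps_control * 100.0
    return out if out.ndim else float(out)


def microbial_biomass(flush_c=None, flush_n=None,
                      kec: float = 0.45, ken: float = 0.54):
    """Microbial biomass C and N from chloroform-fumigation flushes.

    The fumigated-minus-unfumigated extractable flush is divided by the
    extraction-efficiency conversion factors (0.45 for C, 0.54 for N).
    Negative flushes (fumigated below unfumigated, a measurement artifact)
    are flagged and returned as missing.

    Returns (MBC, MBN); either is None when the corresponding flush is None.
    """
    def _convert(flush, k, label):
        if flush is None:
            return None
        flush = np.asarray(flush, dtype=float)
        neg = flush < 0
        if np.any(neg):
            logger.warning("%d negative %s flush value(s) set to missing",
                           int(np.sum(neg)), label)
            flush = np.where(neg, np.nan, flush)
        out = flush / k
        return out if out.ndim else float(out)

    return _convert(flush_c, kec, "C"), _convert(flush_n, ken, "N")


def treatment_profile(records: pd.DataFrame,
                      moisture_col: str = "moisture") -> pd.DataFrame:
    """Per-layer warming effects on temperature and moisture.

    Parameters
    ----------
    records : DataFrame
        Columns: date, plot_id, treatment ('control'|'warmed'), layer,
        temp_C and a moisture column (native units per layer: m³ m⁻³ for
        mineral layers, g H2O g⁻¹ for the O horizon).

    Returns
    -------
    DataFrame indexed by layer with warmed-minus-control differences:
    annual means are formed per (layer, year, treatment) first, the
    treatment difference is taken per year, and the mean and SE across
    years are reported (SE is NaN with a single year).
    Layers missing either treatment are skipped with a log message.
    """
    df = records.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    rows = []
    for layer, sub in df.groupby("layer", sort=False):
        annual = (sub.groupby(["year", "treatment"])[["temp_C", moisture_col]]
                  .mean().unstack("treatment"))
        have = annual.columns.get_level_values("treatment").unique()
        if not {"control", "warmed"}.issubset(set(have)):
            logger.info("layer %r lacks both treatments; skipped", layer)
            continue
        d_t = annual[("temp_C", "warmed")] - annual[("temp_C", "control")]
        d_m = annual[(moisture_col, "warmed")] - annual[(moisture_col, "control")]
        d_t, d_m = d_t.dropna(), d_m.dropna()
        rows.append({
            "layer": layer,
            "delta_temp_mean": d_t.mean(),
            "delta_temp_se": d_t.sem() if len(d_t) > 1 else np.nan,
            "delta_moisture_mean": d_m.mean(),
            "delta_moisture_se": d_m.sem() if len(d_m) > 1 else np.nan,
            "n_years": len(d_t),
        })
    return pd.DataFrame(rows).set_index("layer") if rows else pd.DataFrame(
        columns=["delta_temp_mean", "delta_temp_se", "delta_moisture_mean",
                 "delta_moisture_se", "n_years"])
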