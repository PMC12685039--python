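"""End-to-end pipeline orchestration with a config file and manifest.

Stages (simulate → fluxes → aggregate → respond → n2 → rates → effects →
meta) each read and write only their declared files under one output
directory; a manifest records the config hash, seed, per-stage row
counts and file hashes.  Re-running with an identical config reproduces
byte-identical numeric outputs — all randomness flows from config seeds
and no stage reads the wall clock.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import chamber, effects, io, nitrogen, response, synthetic
from .chamber import ChamberGeometry
from .nitrogen import N2ScalingModel
from .synthetic import SimConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fluxes", "aggregate", "respond", "n2", "rates",
          "effects", "meta")

#: files produced by each stage; also serve as dependency markers
STAGE_OUTPUTS = {
    "simulate": ["climate.csv", "incubation.csv"],
    "fluxes": ["flux_records.csv"],
    "aggregate": ["daily_fluxes.csv", "cumulative_fluxes.csv"],
    "respond": ["response_fits.json"],
    "n2": ["n2_fluxes.json"],
    "rates": ["net_rates.csv", "arrhenius_fits.json"],
    "effects": ["warming_summary.json"],
    "meta": ["meta_regression.json"],
}

STAGE_DEPS = {
    "simulate": [],
    "fluxes": ["simulate"],
    "aggregate": ["fluxes"],
    "respond": ["simulate", "aggregate"],
    "n2": ["simulate", "aggregate"],
    "rates": ["simulate"],
    "effects": ["simulate", "aggregate", "respond", "n2"],
    "meta": [],
}


class StageDependencyError(RuntimeError):
    """A stage was run before its upstream artifacts exist."""


def _from_mapping(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {name} key(s): {sorted(unknown)}")
    for k, v in data.items():
        if isinstance(v, list):
            data[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    n2_model: N2ScalingModel = field(default_factory=N2ScalingModel)
    snow_zero_no: bool = True       # NO annualization: negligible flux Dec-Mar
    max_gap_days: int = 7
    temp_bin_width: float = 0.5     # °C
    wfps_bin_width: float = 1.0     # %
    field_temp_control: float = 15.0   # growing-season mineral temps for
    field_temp_warmed: float = 17.0    # rate extrapolation, °C
    study_table: str | None = None  # path; None -> bundled synthetic stand-in

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "geometry": dataclasses.asdict(self.geometry),
            "n2_model": dataclasses.asdict(self.n2_model),
            "snow_zero_no": self.snow_zero_no,
            "max_gap_days": self.max_gap_days,
            "temp_bin_width": self.temp_bin_width,
            "wfps_bin_width": self.wfps_bin_width,
            "field_temp_control": self.field_temp_control,
            "field_temp_warmed": self.field_temp_warmed,
            "study_table": self.study_table,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        if "sim" in data:
            data["sim"] = _from_mapping(SimConfig, dict(data["sim"]), "sim")
        if "geometry" in data:
            data["geometry"] = _from_mapping(ChamberGeometry,
                                             dict(data["geometry"]), "geometry")
        if "n2_model" in data:
            data["n2_model"] = _from_mapping(N2ScalingModel,
                                             dict(data["n2_model"]), "n2_model")
        return cls(**data)

    def save(self, path) -> None:
        io.dump_yaml(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.load_yaml(path))

    @property
    def hash(self) -> str:
        return io.config_hash(self.to_dict())


def bundled_study_table() -> pd.DataFrame:
    """The packaged synthetic 10-site warming table."""
    with resources.as_file(resources.files("soilnflux.data")
                           / "synthetic_warming_sites.csv") as p:
        return io.read_csv(p)


def _meta(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.hash, "seed": cfg.sim.seed,
            "generator": "soilnflux"}


def _require(out_dir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        for fname in STAGE_OUTPUTS[dep]:
            if not (out_dir / fname).exists():
                raise StageDependencyError(
                    f"stage {stage!r} needs {fname} from stage {dep!r}; "
                    f"run `soilnflux {dep}` first")


def _read_daily(out_dir: Path) -> pd.DataFrame:
    df = io.read_csv(out_dir / "daily_fluxes.csv")
    df["date"] = pd.to_datetime(df["date"])
    return df


def _read_climate(out_dir: Path) -> pd.DataFrame:
    df = io.read_csv(out_dir / "climate.csv")
    df["date"] = pd.to_datetime(df["date"])
    return df


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> dict:
    climate = synthetic.simulate_climate(cfg.sim)
    inc = synthetic.simulate_incubation(cfg.sim)
    io.write_csv(climate, out_dir / "climate.csv", _meta(cfg))
    io.write_csv(inc, out_dir / "incubation.csv", _meta(cfg))
    return {"climate_rows": len(climate), "incubation_rows": len(inc)}


def stage_fluxes(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "fluxes")
    climate = _read_climate(out_dir)
    records = synthetic.simulate_flux_records(cfg.sim, climate,
                                              geometry=cfg.geometry)
    io.write_csv(records, out_dir / "flux_records.csv", _meta(cfg))
    return {"flux_records": len(records)}


def stage_aggregate(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "aggregate")
    records = io.read_csv(out_dir / "flux_records.csv")
    records["date"] = pd.to_datetime(records["date"])
    daily = chamber.daily_aggregate(records)
    io.write_csv(daily, out_dir / "daily_fluxes.csv", _meta(cfg))
    rows = []
    for (trt, sp), sub in daily.groupby(["treatment", "species"]):
        snow = cfg.snow_zero_no if sp == "NO" else False
        cum = chamber.cumulative_flux(sub, label="full_period",
                                      snow_zero=snow,
                                      max_gap_days=cfg.max_gap_days)
        seasons = chamber.seasonal_partition(sub, snow_zero=snow,
                                             max_gap_days=cfg.max_gap_days)
        for c in [cum] + seasons:
            rows.append({"label": c.label, "treatment": c.treatment,
                         "species": c.species, "kg_n_ha": c.kg_n_ha,
                         "coverage": c.coverage, "flagged": c.flagged})
    cum_df = pd.DataFrame(rows)
    io.write_csv(cum_df, out_dir / "cumulative_fluxes.csv", _meta(cfg))
    return {"daily_rows": len(daily), "cumulative_rows": len(cum_df)}


def _joined_daily(cfg: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Daily fluxes joined to same-day treatment-mean soil state."""
    daily = _read_daily(out_dir)
    climate = _read_climate(out_dir)
    state = (climate.groupby(["date", "treatment"], as_index=False)
             [["temp_mineral", "wfps"]].mean())
    state["season"] = np.where(pd.DatetimeIndex(state["date"]).month.isin(
        range(5, 11)), "growing", "dormant")
    return daily.merge(state, on=["date", "treatment"], how="left")


def stage_respond(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "respond")
    joined = _joined_daily(cfg, out_dir)
    fits = {}
    for (trt, sp), sub in joined.groupby(["treatment", "species"]):
        grow = sub[sub["season"] == "growing"]
        entry = {}
        try:
            bins_t = response.bin_fluxes(grow, "temp_mineral",
                                         cfg.temp_bin_width)
            tfit = response.fit_temperature_response(bins_t)
            entry["temperature"] = {
                "a": tfit.a, "k": tfit.k, "q10": tfit.q10, "r2": tfit.r2,
                "n_bins": tfit.n_bins, "t_range": list(tfit.t_range),
                "bins": bins_t.to_dict("list"),
            }
        except (ValueError, response.FitConvergenceError) as err:
            entry["temperature"] = {"error": str(err)}
        try:
            bins_w = response.bin_fluxes(grow, "wfps", cfg.wfps_bin_width)
            mfit = response.fit_moisture_response(bins_w)
            entry["moisture"] = {
                "c2": mfit.c2, "c1": mfit.c1, "c0": mfit.c0,
                "optimum_wfps": mfit.optimum_wfps, "r2": mfit.r2,
                "wfps_range": list(mfit.wfps_range),
            }
        except ValueError as err:
            entry["moisture"] = {"error": str(err)}
        fits[f"{trt}/{sp}"] = entry
    payload = {"meta": _meta(cfg), "fits": fits}
    (out_dir / "response_fits.json").write_text(json.dumps(payload, indent=2))
    return {"fit_groups": len(fits)}


def stage_n2(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "n2")
    daily = _read_daily(out_dir)
    climate = _read_climate(out_dir)
    out = {}
    for trt in sorted(daily["treatment"].unique()):
        n2o = daily[(daily["treatment"] == trt) & (daily["species"] == "N2O")]
        grow = n2o[pd.DatetimeIndex(n2o["date"]).month.isin(range(5, 11))]
        wfps = (climate[climate["treatment"] == trt]
                .groupby("date")["wfps"].mean())
        cum = nitrogen.seasonal_n2(grow, wfps, cfg.n2_model,
                                   max_gap_days=cfg.max_gap_days)
        out[trt] = {"kg_n_ha": cum.kg_n_ha, "coverage": cum.coverage,
                    "label": cum.label}
    payload = {"meta": _meta(cfg), "growing_season_n2": out}
    (out_dir / "n2_fluxes.json").write_text(json.dumps(payload, indent=2))
    return {"treatments": len(out)}


def stage_rates(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "rates")
    inc = io.read_csv(out_dir / "incubation.csv")
    rates = nitrogen.net_rates_frame(inc)
    io.write_csv(rates, out_dir / "net_rates.csv", _meta(cfg))
    fits = {}
    for (layer, trt), sub in rates.groupby(["layer", "treatment"]):
        mean_rates = sub.groupby("temp_C")[["r_m", "r_n"]].mean()
        field_t = (cfg.field_temp_warmed if trt == "warmed"
                   else cfg.field_temp_control)
        entry = {}
        for rate_col in ("r_m", "r_n"):
            fit = nitrogen.fit_arrhenius(mean_rates.index.to_numpy(),
                                         mean_rates[rate_col].to_numpy())
            entry[rate_col] = {"a": fit.a, "b": fit.b, "r2": fit.r2,
                               "t_range": list(fit.t_range),
                               "field_temp": field_t,
                               "field_rate": fit.predict(field_t)}
        fits[f"{layer}/{trt}"] = entry
    payload = {"meta": _meta(cfg), "fits": fits}
    (out_dir / "arrhenius_fits.json").write_text(json.dumps(payload, indent=2))
    return {"rate_rows": len(rates), "fit_groups": len(fits)}


def stage_effects(cfg: PipelineConfig, out_dir: Path) -> dict:
    _require(out_dir, "effects")
    cum = io.read_csv(out_dir / "cumulative_fluxes.csv")
    full = cum[cum["label"] == "full_period"].set_index(
        ["species", "treatment"])["kg_n_ha"]
    n2 = json.loads((out_dir / "n2_fluxes.json").read_text())
    fits = json.loads((out_dir / "response_fits.json").read_text())["fits"]
    cumulative = {}
    for sp in ("NO", "N2O"):
        try:
            cumulative[sp] = (full[(sp, "control")], full[(sp, "warmed")])
        except KeyError:
            logger.warning("species %s missing from cumulative fluxes", sp)
    g = n2["growing_season_n2"]
    if {"control", "warmed"} <= set(g):
        cumulative["N2"] = (g["control"]["kg_n_ha"], g["warmed"]["kg_n_ha"])
    q10s = {}
    for sp in ("NO", "N2O"):
        fit = fits.get(f"control/{sp}", {}).get("temperature", {})
        if "q10" in fit:
            q10s[sp] = fit["q10"]
    summary = effects.warming_summary(cumulative, q10s,
                                      delta_t=cfg.sim.warming_delta_t)
    payload = {"meta": _meta(cfg), "summary": summary.to_dict()}
    (out_dir / "warming_summary.json").write_text(json.dumps(payload, indent=2))
    return {"species": len(summary.species)}


def stage_meta(cfg: PipelineConfig, out_dir: Path) -> dict:
    studies = (io.read_csv(cfg.study_table) if cfg.study_table
               else bundled_study_table())
    res = effects.meta_regression(studies)
    payload = {"meta": _meta(cfg),
               "regression": {"slope": res.slope, "intercept": res.intercept,
                              "r2": res.r2, "p_value": res.p_value,
                              "n": res.n, "predictor": res.predictor},
               "studies": res.studies.drop(columns=["rrn"], errors="ignore")
               .to_dict("records")}
    (out_dir / "meta_regression.json").write_text(json.dumps(payload, indent=2))
    return {"n_studies": res.n}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "fluxes": stage_fluxes,
    "aggregate": stage_aggregate, "respond": stage_respond,
    "n2": stage_n2, "rates": stage_rates, "effects": stage_effects,
    "meta": stage_meta,
}


def run_pipeline(cfg: PipelineConfig, out_dir, stages=("all",)) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "all" in stages:
        stages = STAGES
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        stages = [s for s in STAGES if s in stages]
    cfg.save(out_dir / "config.yaml")
    manifest_path = out_dir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest.update({"config_hash": cfg.hash, "seed": cfg.sim.seed})
    manifest.setdefault("stages", {})
    for stage in stages:
        counts = _STAGE_FUNCS[stage](cfg, out_dir)
        files = {f: io.sha256_file(out_dir / f)
                 for f in STAGE_OUTPUTS[stage] if (out_dir / f).exists()}
        logger.info("stage %s done: %s", stage, counts)
        manifest["stages"][stage] = {"counts": counts, "files": files}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
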