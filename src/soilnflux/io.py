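"""Stable CSV schemas, validated readers/writers and config serialization.

All tabular exchange is CSV with declared headers; files written by the
pipeline carry '#'-prefixed header comments recording the config hash and
seed.  Fitted models and reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# column -> (required, numeric, (min, max) or None)
SCHEMAS: dict[str, dict] = {
    "closures": {
        "chamber_id": (True, False, None),
        "plot_id": (True, False, None),
        "treatment": (True, False, None),
        "species": (True, False, None),
        "t_s": (True, True, (0.0, 86400.0)),
        "conc_nmol_mol": (True, True, None),
        "T_K": (True, True, (150.0, 350.0)),
        "P_hPa": (True, True, (300.0, 1200.0)),
    },
    "soil": {
        "date": (True, False, None),
        "plot_id": (True, False, None),
        "treatment": (True, False, None),
        "layer": (True, False, None),
        "temp_C": (True, True, (-60.0, 60.0)),
        "vwc": (False, True, (0.0, 1.0)),
        "bd": (False, True, (0.05, 2.64)),
        "wfps_pct": (False, True, (0.0, 100.0)),
    },
    "fluxes": {
        "date": (True, False, None),
        "plot_id": (True, False, None),
        "chamber_id": (True, False, None),
        "treatment": (True, False, None),
        "species": (True, False, None),
        "flux": (True, True, None),
        "slope_nmol_mol_h": (False, True, None),
        "slope_r2": (False, True, (0.0, 1.0)),
        "accumulation": (False, True, None),
        "dynamic": (False, True, None),
        "qc_flags": (False, False, None),
    },
    "daily": {
        "date": (True, False, None),
        "treatment": (True, False, None),
        "species": (True, False, None),
        "mean_flux": (True, True, None),
        "se": (False, True, (0.0, np.inf)),
        "n_fluxes": (False, True, (0, np.inf)),
        "n_chambers": (False, True, (0, np.inf)),
    },
    "incubation": {
        "sample_id": (True, False, None),
        "layer": (True, False, None),
        "treatment": (True, False, None),
        "temp_C": (True, True, (-10.0, 60.0)),
        "nh4_before": (True, True, (0.0, np.inf)),
        "no3_before": (True, True, (0.0, np.inf)),
        "nh4_after": (True, True, (0.0, np.inf)),
        "no3_after": (True, True, (0.0, np.inf)),
        "days": (True, True, (0.0, 365.0)),
    },
    "studies": {
        "site_id": (True, False, None),
        "mat_C": (False, True, (-15.0, 30.0)),
        "map_mm": (False, True, (0.0, 6000.0)),
        "delta_t": (True, True, (0.0, 10.0)),
        "wfps": (False, True, (0.0, 100.0)),
        "delta_wfps_pct": (True, True, (-100.0, 100.0)),
        "n2o_control": (True, True, None),
        "n2o_warmed": (True, True, None),
    },
}


@dataclass
class ValidationReport:
    path: str
    schema: str
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(path, schema: str) -> ValidationReport:
    """Column/type/range checks for a CSV against a named schema.

    Missing required columns and out-of-range values are errors; unknown
    extra columns are warnings (forward compatibility).  A malformed CSV
    raises with the offending line number where pandas provides one.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    schema_def = SCHEMAS[schema]
    report = ValidationReport(path=str(path), schema=schema)
    df = read_csv(path)
    for col, (required, numeric, rng) in schema_def.items():
        if col not in df.columns:
            if required:
                report.errors.append(f"missing required column {col!r}")
            continue
        if numeric:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                report.errors.append(
                    f"column {col!r}: {int(bad.sum())} non-numeric value(s)")
            if rng is not None:
                lo, hi = rng
                out = (vals < lo) | (vals > hi)
                if out.any():
                    report.errors.append(
                        f"column {col!r}: {int(out.sum())} value(s) outside "
                        f"[{lo}, {hi}]")
    for col in df.columns:
        if col not in schema_def:
            report.warnings.append(f"unexpected extra column {col!r}")
    return report


def config_hash(obj) -> str:
    """Short stable hash of a (nested) config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write a CSV with '#'-prefixed provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_csv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kwargs)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
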