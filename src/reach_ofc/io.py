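"""Trial-table and summary persistence.

The interchange format is a pair of CSVs -- ``trials.csv`` with one row per
sample and ``meta.csv`` with one row per trial -- plus a JSON schema sidecar
declaring schema id, version, and per-column units. Readers validate the
declared major version, required columns, and per-trial time monotonicity,
and convert any cm-declared length column to SI meters. Simulation summaries
round-trip through HDF5.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis.kinematics import SchemaError
from .experiments import CellResult, SimulationSummary

SCHEMA_ID = "reach-ofc-trial-table"
SCHEMA_VERSION = "1.0"

SAMPLE_UNITS = {"participant": "id", "trial": "id", "t": "s", "x": "m", "y": "m",
                "fx": "N", "fy": "N", "emg_pm": "norm", "emg_pd": "norm"}
META_UNITS = {"participant": "id", "trial": "id", "speed": "label", "block": "count",
              "trial_in_block": "count", "uncertainty": "label", "shift": "m",
              "force_dir": "N", "experiment": "id", "is_calibration": "bool",
              "cal_direction": "label", "cal_force_on_t": "s", "move_onset_t": "s",
              "outcome": "label"}
REQUIRED_SAMPLE_COLS = ("participant", "trial", "t", "x", "y", "fx", "fy")
REQUIRED_META_COLS = ("participant", "trial", "speed", "uncertainty", "shift",
                      "force_dir", "experiment", "is_calibration")
_LENGTH_COLS = {"x", "y", "shift"}


def write_schema(out_dir: str | Path, sample_cols, meta_cols,
                 config_hash: str = "", seed: int | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = {
        "schema": SCHEMA_ID, "version": SCHEMA_VERSION,
        "columns": {"trials": {c: SAMPLE_UNITS.get(c, "unknown") for c in sample_cols},
                    "meta": {c: META_UNITS.get(c, "unknown") for c in meta_cols}},
        "provenance": {"config_hash": config_hash, "seed": seed,
                       "created": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    (out / "trials.schema.json").write_text(json.dumps(schema, indent=1))
    return out


def write_trial_table(samples: pd.DataFrame, meta: pd.DataFrame,
                      out_dir: str | Path, config_hash: str = "",
                      seed: int | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples.to_csv(out / "trials.csv", index=False)
    meta.to_csv(out / "meta.csv", index=False)
    write_schema(out, samples.columns, meta.columns, config_hash, seed)
    return out


def _check_version(version: str) -> None:
    major = version.split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"unsupported schema major version {version!r}")


def _convert_units(df: pd.DataFrame, units: dict[str, str]) -> pd.DataFrame:
    for col, unit in units.items():
        if col in df.columns and col in _LENGTH_COLS and unit == "cm":
            df[col] = df[col] / 100.0
    return df


def read_trial_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read (samples, meta, schema) from a directory written by
    :func:`write_trial_table`; validates schema and converts units to SI."""
    p = Path(path)
    schema_path = p / "trials.schema.json"
    if not schema_path.exists():
        raise SchemaError(f"missing schema sidecar {schema_path}")
    schema = json.loads(schema_path.read_text())
    if schema.get("schema") != SCHEMA_ID:
        raise SchemaError(f"unknown schema id {schema.get('schema')!r}")
    _check_version(schema.get("version", "0"))
    samples = pd.read_csv(p / "trials.csv")
    meta = pd.read_csv(p / "meta.csv")
    missing = [c for c in REQUIRED_SAMPLE_COLS if c not in samples.columns]
    missing += [c for c in REQUIRED_META_COLS if c not in meta.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    samples = _convert_units(samples, schema["columns"].get("trials", {}))
    meta = _convert_units(meta, schema["columns"].get("meta", {}))
    tt = samples.groupby(["participant", "trial"], sort=False)["t"]
    if (tt.apply(lambda s: (np.diff(s.to_numpy()) <= 0).any())).any():
        raise SchemaError("non-monotone time grid in column 't'")
    return samples, meta, schema


# ---------------------------------------------------------------------------
# simulation summaries

def write_summary(summary: SimulationSummary, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = summary.config_hash
        f.attrs["master_seed"] = summary.master_seed
        f.attrs["jump_sizes"] = list(summary.jump_sizes)
        for (unc, speed, jump), cell in summary.cells.items():
            g = f.create_group(f"{unc}/{speed}/{jump:+.3f}")
            g.attrs["dt"] = cell.dt
            for name in ("lateral_pos", "lateral_force", "err_decay", "jump_steps"):
                g.create_dataset(name, data=getattr(cell, name))


def read_summary(path: str | Path) -> SimulationSummary:
    cells = {}
    with h5py.File(path, "r") as f:
        for unc in f:
            for speed in f[unc]:
                for jkey in f[unc][speed]:
                    g = f[unc][speed][jkey]
                    jump = float(jkey)
                    cells[(unc, speed, jump)] = CellResult(
                        uncertainty=unc, speed=speed, jump=jump,
                        dt=float(g.attrs["dt"]),
                        lateral_pos=g["lateral_pos"][...],
                        lateral_force=g["lateral_force"][...],
                        err_decay=g["err_decay"][...],
                        jump_steps=g["jump_steps"][...])
        return SimulationSummary(cells=cells,
                                 config_hash=str(f.attrs["config_hash"]),
                                 master_seed=int(f.attrs["master_seed"]),
                                 jump_sizes=tuple(f.attrs["jump_sizes"]))
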