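"""Readers and writers for the package's plain-text formats.

All tabular output is comma-separated with a column-name header row followed
by a mandatory units row; scenarios and parameter sets are YAML documents.
Readers validate the schema strictly and name the offending field (and row,
where applicable) in their error messages.  Round trips are lossless to
float formatting precision.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import Scenario, Schedule, TimeSeries
from .params import ParameterSet

__all__ = [
    "SchemaError",
    "write_timeseries", "read_timeseries",
    "write_observation_table", "read_observation_table",
    "write_params", "read_params",
    "write_scenario", "read_scenario", "load_protocol", "list_protocols",
    "write_manifest",
]

OBS_COLUMNS = ("time_min", "channel", "mean", "sem", "n")
OBS_UNITS = ("min", "-", "channel units", "channel units", "count")


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


# -- time series ----------------------------------------------------------
def write_timeseries(ts: TimeSeries, path) -> None:
    path = Path(path)
    cols = list(ts.frame.columns)
    units = [ts.units.get(c, "-") for c in cols]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write(",".join(units) + "\n")
        ts.frame.to_csv(fh, header=False, index=False,
                        float_format="%.17g")


def read_timeseries(path) -> TimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        units_row = fh.readline().strip()
        if not header:
            raise SchemaError(f"{path}: empty file")
        cols = header.split(",")
        units = units_row.split(",") if units_row else []
        if len(units) != len(cols) or any(u == "" for u in units):
            raise SchemaError(
                f"{path}: line 2 must be a units row matching the "
                f"{len(cols)} columns")
        if _looks_numeric(units):
            raise SchemaError(f"{path}: missing units row (line 2 is data)")
        frame = pd.read_csv(fh, header=None, names=cols)
    if "time_min" not in cols:
        raise SchemaError(f"{path}: missing required column 'time_min'")
    return TimeSeries(frame=frame, units=dict(zip(cols, units)))


def _looks_numeric(tokens) -> bool:
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


# -- observation tables ---------------------------------------------------
def write_observation_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observation table missing columns: {missing}")
    with open(Path(path), "w") as fh:
        fh.write(",".join(OBS_COLUMNS) + "\n")
        fh.write(",".join(OBS_UNITS) + "\n")
        df[list(OBS_COLUMNS)].to_csv(fh, header=False, index=False,
                                     float_format="%.17g")


def read_observation_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        units_row = fh.readline().strip().split(",")
        if header != list(OBS_COLUMNS):
            raise SchemaError(
                f"{path}: header must be {','.join(OBS_COLUMNS)}, "
                f"got {','.join(header)}")
        if _looks_numeric(units_row):
            raise SchemaError(f"{path}: missing units row (line 2 is data)")
        df = pd.read_csv(fh, header=None, names=header)
    for i, row in df.iterrows():
        line = i + 3  # header + units rows precede the data
        if row["sem"] < 0:
            raise SchemaError(f"{path}:{line}: sem must be >= 0")
        if row["n"] < 1:
            raise SchemaError(f"{path}:{line}: n must be >= 1")
        if not np.isfinite(row["mean"]):
            raise SchemaError(f"{path}:{line}: non-finite mean")
    return df


# -- parameters -----------------------------------------------------------
def write_params(ps: ParameterSet, path) -> None:
    ps.to_yaml(path)


def read_params(path) -> ParameterSet:
    return ParameterSet.from_yaml(path)


# -- scenarios ------------------------------------------------------------
def write_scenario(scenario: Scenario, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def scenario_from_dict(data: dict, source: str = "<dict>") -> Scenario:
    for key in ("mode", "duration_min"):
        if key not in data:
            raise SchemaError(f"{source}: missing required field {key!r}")
    schedules = {}
    for ch, entry in (data.get("schedules") or {}).items():
        for key in ("times", "values"):
            if key not in entry:
                raise SchemaError(
                    f"{source}: schedule {ch!r} missing field {key!r}")
        schedules[ch] = Schedule(
            times=np.asarray(entry["times"], dtype=float),
            values=np.asarray(entry["values"], dtype=float),
            interp=entry.get("interp", "hold"))
    return Scenario(
        duration=float(data["duration_min"]),
        mode=data["mode"],
        schedules=schedules,
        fao_location=data.get("fao_location", "ml"),
        name=data.get("name", "scenario"),
        species_scaling=data.get("species_scaling"))


def read_scenario(path) -> Scenario:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data, source=str(path))


def list_protocols() -> list:
    root = importlib.resources.files("crsim") / "protocols"
    return sorted(p.name[:-5] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_protocol(name: str) -> Scenario:
    """Load one of the packaged study protocols by name."""
    root = importlib.resources.files("crsim") / "protocols"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {list_protocols()}")
    data = yaml.safe_load(text)
    return scenario_from_dict(data, source=f"protocol:{name}")


# -- provenance -----------------------------------------------------------
def write_manifest(manifest: dict, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
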