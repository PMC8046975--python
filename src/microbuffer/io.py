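"""Readers and writers: record CSVs, ground-truth JSON, TOML configs.

The record CSV dialect is ``timestamp,site,position,variable,value`` with
ISO 8601 timestamps (local solar time, no zone); NDVI CSVs carry
``date,ndvi``.  Configs are read with the standard-library TOML parser; a
small emitter handles the limited structure we write (tables of scalars,
lists, and date strings).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import GroundTruth, SiteConfig, SynthConfig

RECORD_COLUMNS = ["timestamp", "site", "position", "variable", "value"]


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records[RECORD_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.10g")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_ndvi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"date", "ndvi"} <= set(df.columns):
        raise ValueError("NDVI CSV needs 'date' and 'ndvi' columns")
    df["date"] = pd.to_datetime(df["date"])
    df["doy"] = df["date"].dt.dayofyear
    return df


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    if isinstance(obj, (pd.Timestamp, date)):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def dump_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def truth_to_dict(truth: GroundTruth) -> dict:
    d = _jsonable(dataclasses.asdict(truth))
    return d


def write_truth_json(truth: GroundTruth, path) -> None:
    dump_json(truth_to_dict(truth), path)


# ---------------------------------------------------------------------------
# TOML config
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def _site_to_table(site: SiteConfig) -> dict:
    d = dataclasses.asdict(site)
    d["snow_windows"] = {
        pos: [[str(pd.Timestamp(a).date()), str(pd.Timestamp(b).date())]
              for a, b in windows]
        for pos, windows in site.snow_windows.items()}
    return {k: v for k, v in d.items() if v is not None}


def config_to_toml(config: SynthConfig) -> str:
    lines = ["[campaign]"]
    for key in ("start", "end"):
        lines.append(f'{key} = "{getattr(config, key)}"')
    lines.append(f"step_minutes = {config.step_minutes}")
    lines.append(f"seed = {config.seed}")
    for site in config.sites:
        lines.append("")
        lines.append("[[site]]")
        table = _site_to_table(site)
        snow = table.pop("snow_windows")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
        for pos, windows in snow.items():
            lines.append(f"snow_windows_{pos} = {_toml_value(windows)}")
    return "\n".join(lines) + "\n"


def write_config_toml(config: SynthConfig, path) -> None:
    Path(path).write_text(config_to_toml(config))


def read_config_toml(path) -> SynthConfig:
    data = tomllib.loads(Path(path).read_text())
    camp = data.get("campaign", {})
    sites = []
    for tbl in data.get("site", []):
        tbl = dict(tbl)
        snow = {}
        for pos in ("below_canopy", "open_field"):
            key = f"snow_windows_{pos}"
            if key in tbl:
                snow[pos] = tuple((a, b) for a, b in tbl.pop(key))
        if "hourly_slope_profile" in tbl:
            tbl["hourly_slope_profile"] = tuple(tbl["hourly_slope_profile"])
        tbl["snow_windows"] = snow
        sites.append(SiteConfig(**tbl))
    kwargs = {}
    for key in ("start", "end"):
        if key in camp:
            kwargs[key] = pd.Timestamp(camp[key]).date()
    for key in ("step_minutes", "seed"):
        if key in camp:
            kwargs[key] = int(camp[key])
    return SynthConfig(sites=tuple(sites), **kwargs)
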