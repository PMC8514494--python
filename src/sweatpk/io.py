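"""CSV/JSON input-output for measurement tables and fit results.

File dialect: UTF-8 CSV with a header row and decimal points.  On disk,
sampling times are stored in minutes (matching the study schedules) and
converted to hours on read.  Measurement CSV columns:
``time_min, species, replicate, signal, censored`` with censored coded
0/1.  Fit results serialize to JSON (parameters, CIs, loss, adjusted
R^2, seed, per-start log) plus a tidy CSV of fitted sweat volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, MeasurementTable
from .model import SPECIES, ConcentrationTrajectory, InputError

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_fit_result",
    "write_trajectory",
    "read_calibration",
    "config_hash",
]

_MEASUREMENT_COLUMNS = ("time_min", "species", "replicate", "signal",
                        "censored")


def read_measurements(path) -> MeasurementTable:
    """Read and validate a measurement CSV; times converted to hours.

    Malformed rows are reported with their file line numbers (header is
    line 1).
    """
    df = pd.read_csv(path)
    missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")

    problems = []
    lines = df.index + 2  # header occupies line 1
    bad = ~df["species"].isin(SPECIES)
    for ln, sp in zip(lines[bad], df.loc[bad, "species"]):
        problems.append(f"line {ln}: unknown species '{sp}'")
    t = pd.to_numeric(df["time_min"], errors="coerce")
    for ln in lines[t.isna() | (t < 0)]:
        problems.append(f"line {ln}: invalid time_min")
    s = pd.to_numeric(df["signal"], errors="coerce")
    for ln in lines[s.isna() | (s < 0) | ~np.isfinite(s)]:
        problems.append(f"line {ln}: invalid signal")
    c = pd.to_numeric(df["censored"], errors="coerce")
    for ln in lines[~c.isin([0, 1])]:
        problems.append(f"line {ln}: censored must be 0 or 1")
    if problems:
        raise InputError(f"{path}: " + "; ".join(problems[:20]))

    out = pd.DataFrame(
        {
            "time_h": t / 60.0,
            "species": df["species"],
            "replicate": df["replicate"].astype(str),
            "signal": s,
            "censored": c.astype(bool),
        }
    )
    return MeasurementTable(out)


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a measurement table in the on-disk dialect (minutes, 0/1)."""
    df = table.data
    out = pd.DataFrame(
        {
            "time_min": df["time_h"] * 60.0,
            "species": df["species"],
            "replicate": df["replicate"],
            "signal": df["signal"],
            "censored": df["censored"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (dataclass or dict)."""
    try:
        payload = asdict(obj)
    except TypeError:
        payload = obj if isinstance(obj, dict) else repr(obj)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_fit_result(result: FitResult, path, volumes_csv=None,
                     extra_meta: dict | None = None) -> None:
    """Serialize a FitResult to JSON, optionally plus a sweat-volume CSV.

    Every artifact records the package version and the master seed.
    """
    names = result.parameter_names()
    payload = {
        "package_version": __version__,
        "seed": result.seed,
        "parameters": dict(zip(names, map(float, result.x))),
        "confidence_intervals": (
            {k: list(v) for k, v in result.ci.items()} if result.ci else None
        ),
        "loss": result.loss,
        "loss_alpha": result.alpha,
        "loss_scale": result.loss_scale,
        "adjusted_r2": result.adjusted_r2,
        "n_obs": result.n_obs,
        "df": result.df,
        "starts": [asdict(s) for s in result.starts],
    }
    if extra_meta:
        payload.update(extra_meta)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
    if volumes_csv is not None:
        pd.DataFrame(
            {
                "timepoint_index": np.arange(result.volumes.volumes.size),
                "v_sweat_uL": result.volumes.volumes,
            }
        ).to_csv(volumes_csv, index=False)


def write_trajectory(traj: ConcentrationTrajectory, path) -> None:
    """Tidy trajectory CSV: time_h, species, concentration_ug_per_L."""
    traj.to_frame().to_csv(path, index=False)


def read_calibration(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration CSV with columns level_pg_per_uL, signal."""
    df = pd.read_csv(path)
    missing = {"level_pg_per_uL", "signal"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return (df["level_pg_per_uL"].to_numpy(dtype=float),
            df["signal"].to_numpy(dtype=float))
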