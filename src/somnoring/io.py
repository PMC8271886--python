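"""Plain-text file formats for nights, features and cohorts.

Per-night files are simple columnar CSVs:
  accelerometer  ``t,x,y,z``        (s, g) at nominal 50 Hz
  temperature    ``t,celsius``      (s, °C) at one sample / 10 s
  IBI            ``t,interval_ms``  (beat time in s, interval in ms)
  hypnogram      ``epoch,stage``

A cohort manifest is a CSV with columns
``subject_id,night_id,acc_path,temp_path,ibi_path,hypnogram_path``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, SensorStreams, read_hypnogram_csv, write_hypnogram_csv
from .hrv import IbiSeries
from .simulate import SyntheticNight

MANIFEST_COLUMNS = ["subject_id", "night_id", "acc_path", "temp_path", "ibi_path",
                    "hypnogram_path"]


def read_acc_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["t", "x", "y", "z"]:
        raise ValueError(f"expected columns t,x,y,z in {path}")
    return df


def read_temp_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["t", "celsius"]:
        raise ValueError(f"expected columns t,celsius in {path}")
    return df


def read_ibi_csv(path) -> IbiSeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["t", "interval_ms"]:
        raise ValueError(f"expected columns t,interval_ms in {path}")
    return IbiSeries(t=df["t"].to_numpy(float), interval_ms=df["interval_ms"].to_numpy(float))


def write_ibi_csv(ibi: IbiSeries, path) -> None:
    pd.DataFrame({"t": ibi.t, "interval_ms": ibi.interval_ms}).to_csv(path, index=False)


def write_night_dir(night: SyntheticNight, out_dir) -> dict[str, str]:
    """Write one night's CSVs (plus truth bookkeeping) under ``out_dir/night_id``."""
    d = Path(out_dir) / night.night_id
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "acc_path": str(d / "acc.csv"),
        "temp_path": str(d / "temp.csv"),
        "ibi_path": str(d / "ibi.csv"),
        "hypnogram_path": str(d / "hypnogram.csv"),
    }
    night.streams.acc.round(5).to_csv(paths["acc_path"], index=False)
    night.streams.temp.round(3).to_csv(paths["temp_path"], index=False)
    write_ibi_csv(night.streams.ibi, paths["ibi_path"])
    write_hypnogram_csv(night.hypnogram, paths["hypnogram_path"])
    truth_dir = d / "truth"
    truth_dir.mkdir(exist_ok=True)
    for key in ("ibi_ectopic_idx", "temp_artifact_idx"):
        np.savetxt(truth_dir / f"{key}.csv", np.asarray(night.truth[key], dtype=int),
                   fmt="%d", header=key, comments="")
    for key in ("acc_burst_epochs", "acc_shift_epochs"):
        np.savetxt(truth_dir / f"{key}.csv", np.asarray(night.truth[key], dtype=int),
                   fmt="%d", header=key, comments="")
    return paths


def write_cohort(nights: list[SyntheticNight], out_dir) -> str:
    """Write every night plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for night in nights:
        paths = write_night_dir(night, out_dir)
        rows.append({"subject_id": night.subject_id, "night_id": night.night_id, **paths})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return str(manifest)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def load_night_streams(row: pd.Series) -> tuple[SensorStreams, Hypnogram]:
    """Load one manifest row into streams + reference hypnogram."""
    hyp = read_hypnogram_csv(row["hypnogram_path"])
    streams = SensorStreams(
        acc=read_acc_csv(row["acc_path"]) if _has(row, "acc_path") else None,
        temp=read_temp_csv(row["temp_path"]) if _has(row, "temp_path") else None,
        ibi=read_ibi_csv(row["ibi_path"]) if _has(row, "ibi_path") else None,
        subject_id=str(row["subject_id"]), night_id=str(row["night_id"]),
    )
    return streams, hyp


def _has(row: pd.Series, key: str) -> bool:
    v = row.get(key)
    return isinstance(v, str) and len(v) > 0 and os.path.exists(v)
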