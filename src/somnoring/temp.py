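"""Finger skin temperature features.

The ring's thermistor samples the palm side of the finger base every 10 s.
Values outside the physiologically plausible 31–40 °C range are sensor
artifacts (ring off, airflow) and are masked before aggregation; the bounds
themselves are valid readings. Each 30-s epoch (nominally 3 samples) is
summarized by mean, min, max and sample standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochGrid

TEMP_RANGE_C = (31.0, 40.0)


def mask_artifacts(celsius: np.ndarray,
                   valid_range: tuple[float, float] = TEMP_RANGE_C) -> np.ndarray:
    """Replace out-of-range samples with NaN; bounds are inclusive."""
    v = np.asarray(celsius, dtype=float).copy()
    lo, hi = valid_range
    v[(v < lo) | (v > hi)] = np.nan
    return v


def temp_epoch_features(t: np.ndarray, celsius: np.ndarray, grid: EpochGrid) -> pd.DataFrame:
    """Per-epoch mean/min/max/std over the masked samples.

    Standard deviation is the sample (n-1) estimate and needs at least two
    valid samples; an epoch with no valid samples has all features missing.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(celsius, dtype=float)
    idx = np.floor((t - grid.night_start) / grid.epoch_len).astype(int)
    in_grid = (idx >= 0) & (idx < grid.n_epochs)
    idx, v = idx[in_grid], v[in_grid]
    n = grid.n_epochs
    out = {k: np.full(n, np.nan) for k in ("temp_mean", "temp_min", "temp_max", "temp_std")}
    n_valid = np.zeros(n, dtype=int)
    valid = ~np.isnan(v)
    np.add.at(n_valid, idx[valid], 1)
    for e in np.unique(idx[valid]):
        ev = v[(idx == e) & valid]
        out["temp_mean"][e] = np.mean(ev)
        out["temp_min"][e] = np.min(ev)
        out["temp_max"][e] = np.max(ev)
        if len(ev) >= 2:
            out["temp_std"][e] = np.std(ev, ddof=1)
    out["temp_n_valid"] = n_valid
    return pd.DataFrame(out, index=pd.RangeIndex(n, name="epoch"))


def extract_temp_features(temp: pd.DataFrame, grid: EpochGrid) -> pd.DataFrame:
    """Mask artifacts then aggregate to the epoch grid."""
    masked = mask_artifacts(temp["celsius"].to_numpy(dtype=float))
    return temp_epoch_features(temp["t"].to_numpy(dtype=float), masked, grid)
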