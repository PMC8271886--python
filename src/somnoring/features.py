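"""Feature registry, per-night robust normalization, and feature-set assembly.

Physiological baselines (nightly heart rate, HRV, skin temperature) differ
far more between people than between sleep stages within a person. Almost
every feature is therefore re-expressed per night as a robust z-score,

    z = (x - median) / (p95 - p5),

computed over the night's non-missing values. Features whose *absolute*
magnitude is informative are exempt: the per-axis movement maxima and the
MAD maximum (a large absolute movement means wake regardless of the night's
baseline), and the circadian columns, whose scale is fixed by construction.

The four nested feature sets mirror the sensor ablation: ACC, ACC+T,
ACC+T+HRV, and ACC+T+HRV+C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NORM_EPS = 1e-9

FEATURE_SETS = ("ACC", "ACC+T", "ACC+T+HRV", "ACC+T+HRV+C")

#: families included in each nested feature set
SET_FAMILIES = {
    "ACC": ("acc",),
    "ACC+T": ("acc", "temp"),
    "ACC+T+HRV": ("acc", "temp", "hrv"),
    "ACC+T+HRV+C": ("acc", "temp", "hrv", "circadian"),
}

#: accelerometer columns kept on their absolute scale (plus smoothed variants)
ABS_ACC_BASES = ("acc_x_max", "acc_y_max", "acc_z_max", "mad_max")

#: scale-fixed bookkeeping columns (counts / fractions), never normalized
_SCALE_FIXED_PREFIXES = ("temp_n_valid", "coverage_")


def family_of(column: str) -> str:
    """Feature family of a column name, by naming convention."""
    if column.startswith("circ_"):
        return "circadian"
    if column.startswith("temp_"):
        return "temp"
    if column.endswith("_1min") or column.endswith("_5min"):
        return "hrv"
    if column.startswith(("acc_", "mad_", "angle_")):
        return "acc"
    raise ValueError(f"column {column!r} belongs to no known feature family")


def normalize_flag(column: str) -> bool:
    """Whether a column is subject to per-night robust normalization."""
    if column.startswith("circ_"):
        return False
    if any(column == b or column.startswith(b + "_r") for b in ABS_ACC_BASES):
        return False
    if any(column.startswith(p) for p in _SCALE_FIXED_PREFIXES):
        return False
    return True


@dataclass
class FeatureMatrix:
    """Epochs x named features for one night, with per-column normalize flags."""

    data: pd.DataFrame
    flags: pd.Series

    def __post_init__(self) -> None:
        if not self.flags.index.equals(self.data.columns):
            raise ValueError("flags must be indexed by the feature columns")

    @classmethod
    def from_frame(cls, data: pd.DataFrame) -> "FeatureMatrix":
        flags = pd.Series({c: normalize_flag(c) for c in data.columns})
        return cls(data=data, flags=flags.reindex(data.columns))

    @property
    def n_epochs(self) -> int:
        return len(self.data)


def robust_normalize_night(values: np.ndarray, flag: bool = True,
                           eps: float = NORM_EPS) -> np.ndarray:
    """Robust per-night z-score of one feature column.

    z = (x - median) / (p95 - p5) over the night's non-missing values; if
    the percentile range degenerates (below ``eps``) the non-missing
    entries become exactly 0. Unflagged columns pass through unchanged.
    """
    v = np.asarray(values, dtype=float)
    if not flag:
        return v.copy()
    finite = ~np.isnan(v)
    if not finite.any():
        return v.copy()
    med = np.nanmedian(v)
    p5, p95 = np.nanpercentile(v, [5, 95])
    rng = p95 - p5
    out = v.copy()
    if rng < eps:
        out[finite] = 0.0
    else:
        out[finite] = (v[finite] - med) / rng
    return out


def normalize_matrix(fm: FeatureMatrix) -> FeatureMatrix:
    """Apply :func:`robust_normalize_night` column-wise per the flags."""
    data = {c: robust_normalize_night(fm.data[c].to_numpy(), bool(fm.flags[c]))
            for c in fm.data.columns}
    return FeatureMatrix(pd.DataFrame(data, index=fm.data.index), fm.flags.copy())


def assemble_features(night_features: pd.DataFrame, feature_set: str,
                      normalize: bool = True) -> FeatureMatrix:
    """Select one night's columns for a feature set and normalize them.

    Raises if any requested family has no columns, listing what is missing.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}")
    families = SET_FAMILIES[feature_set]
    cols = [c for c in night_features.columns if family_of(c) in families]
    present = {family_of(c) for c in cols}
    missing = [f for f in families if f not in present]
    if missing:
        raise ValueError(f"feature families missing from input: {missing}")
    fm = FeatureMatrix.from_frame(night_features[cols])
    return normalize_matrix(fm) if normalize else fm
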