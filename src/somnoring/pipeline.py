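"""Night-level feature extraction: sensors in, epoch feature table out."""

from __future__ import annotations

import pandas as pd

from .acc import extract_acc_features, smooth_features
from .circadian import circadian_columns
from .core import EpochGrid, SensorStreams
from .hrv import clean_ibi, extract_hrv_features
from .model import NightRecord
from .simulate import SyntheticNight
from .temp import extract_temp_features

SMOOTH_RADII = (2, 10)  # +/- 1 min and +/- 5 min of epochs


def extract_night_features(streams: SensorStreams, grid: EpochGrid,
                           smooth_radii: tuple[int, ...] = SMOOTH_RADII) -> pd.DataFrame:
    """Extract every feature family available in the streams for one night.

    Accelerometer features get centered rolling mean/max smoothing over
    ``smooth_radii`` epochs. Missing streams simply contribute no columns;
    circadian columns depend only on the grid and are always present.
    """
    parts = []
    if streams.acc is not None:
        acc = extract_acc_features(streams.acc, grid)
        parts.append(smooth_features(acc, radii=smooth_radii))
    if streams.temp is not None:
        parts.append(extract_temp_features(streams.temp, grid))
    if streams.ibi is not None:
        ibi = streams.ibi if streams.ibi.usable is not None else clean_ibi(streams.ibi)
        parts.append(extract_hrv_features(ibi, grid))
    parts.append(circadian_columns(grid))
    return pd.concat(parts, axis=1)


def night_record(night: SyntheticNight,
                 smooth_radii: tuple[int, ...] = SMOOTH_RADII) -> NightRecord:
    """Turn a simulated night into a training-ready record."""
    feats = extract_night_features(night.streams, night.hypnogram.grid,
                                   smooth_radii=smooth_radii)
    return NightRecord(subject_id=night.subject_id, night_id=night.night_id,
                       features=feats, hypnogram=night.hypnogram)


def cohort_records(nights: list[SyntheticNight],
                   smooth_radii: tuple[int, ...] = SMOOTH_RADII) -> list[NightRecord]:
    return [night_record(n, smooth_radii=smooth_radii) for n in nights]
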