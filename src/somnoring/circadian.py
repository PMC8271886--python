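"""Sensor-independent circadian and homeostatic features.

The two-process model of sleep regulation describes sleep depth as the
interaction of a ~24-h circadian rhythm and a homeostatic sleep pressure
that builds during wake and decays exponentially during sleep, fastest in
the deep-NREM-rich first hours. Three per-epoch columns encode this:

- ``circ_cos``: cosine with a 24-h period, phase-anchored so its peak falls
  at the night midpoint (the most stable part of sleep);
- ``circ_decay``: exp(-t / tau) with tau defaulting to 2 h, the decaying
  homeostatic pressure;
- ``circ_linear``: elapsed night fraction in [0, 1], capturing the
  early-deep / late-REM asymmetry of sleep architecture.

All three are parameterized only by the night's duration — they never see
sensor data — and are exempt from per-night normalization because their
scale is already fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochGrid

DECAY_TAU_H = 2.0
PERIOD_H = 24.0

CIRCADIAN_COLUMNS = ("circ_cos", "circ_decay", "circ_linear")


def circadian_columns(grid: EpochGrid, tau_h: float = DECAY_TAU_H,
                      period_h: float = PERIOD_H) -> pd.DataFrame:
    """The three circadian/homeostatic columns for one night grid.

    Times are epoch midpoints in seconds since night start; two nights of
    equal duration produce identical columns.
    """
    if grid.duration <= 0:
        raise ValueError("night duration must be positive")
    if tau_h <= 0:
        raise ValueError("decay constant must be positive")
    t = grid.midpoints() - grid.night_start
    dur = grid.duration
    cos = np.cos(2.0 * np.pi * (t - dur / 2.0) / (period_h * 3600.0))
    decay = np.exp(-t / (tau_h * 3600.0))
    linear = t / dur
    return pd.DataFrame(
        {"circ_cos": cos, "circ_decay": decay, "circ_linear": linear},
        index=pd.RangeIndex(grid.n_epochs, name="epoch"),
    )
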