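"""Domain types shared by the whole pipeline.

Sleep is scored on a fixed grid of successive 30-s epochs. A night is
described by an :class:`EpochGrid` (how many epochs, starting when), a
:class:`Hypnogram` (one stage label per epoch), and the raw sensor streams
bundled in :class:`SensorStreams`. Stage vocabularies follow AASM
conventions: the raw five-class scoring {W, N1, N2, N3, REM}, the
four-class view {wake, light, deep, REM} where light = N1 + N2 and
deep = N3, and the two-class view {wake, sleep}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EPOCH_LEN_S = 30.0

RAW_STAGES = ("W", "N1", "N2", "N3", "REM")
FOUR_STAGES = ("wake", "light", "deep", "REM")
TWO_STAGES = ("wake", "sleep")

#: vocabulary name -> allowed labels
VOCABS: Mapping[str, tuple[str, ...]] = {
    "raw": RAW_STAGES,
    "four": FOUR_STAGES,
    "two": TWO_STAGES,
}

RAW_TO_FOUR = {"W": "wake", "N1": "light", "N2": "light", "N3": "deep", "REM": "REM"}
FOUR_TO_TWO = {"wake": "wake", "light": "sleep", "deep": "sleep", "REM": "sleep"}


@dataclass(frozen=True)
class EpochGrid:
    """Half-open 30-s epoch grid: epoch i covers [start + 30i, start + 30(i+1))."""

    n_epochs: int
    epoch_len: float = EPOCH_LEN_S
    night_start: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_len != EPOCH_LEN_S:
            raise ValueError("epoch length is fixed at 30 s")
        if self.n_epochs < 1:
            raise ValueError("grid needs at least one epoch")

    @classmethod
    def from_duration(cls, duration_s: float, night_start: float = 0.0) -> "EpochGrid":
        """Build a grid from a night duration; a trailing partial epoch is dropped."""
        n = int(np.floor(duration_s / EPOCH_LEN_S))
        return cls(n_epochs=n, night_start=night_start)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def edges(self) -> np.ndarray:
        """Epoch boundary times (length n_epochs + 1), seconds from night start."""
        return self.night_start + self.epoch_len * np.arange(self.n_epochs + 1)

    def midpoints(self) -> np.ndarray:
        return self.night_start + self.epoch_len * (np.arange(self.n_epochs) + 0.5)


@dataclass
class Hypnogram:
    """Stage label per epoch on a night grid."""

    grid: EpochGrid
    stages: np.ndarray
    vocab: str = "raw"

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.vocab not in VOCABS:
            raise ValueError(f"unknown vocabulary {self.vocab!r}")
        if len(self.stages) != self.grid.n_epochs:
            raise ValueError(
                f"hypnogram length {len(self.stages)} != grid n_epochs {self.grid.n_epochs}"
            )
        allowed = set(VOCABS[self.vocab])
        for i, s in enumerate(self.stages):
            if s not in allowed:
                raise ValueError(f"unknown stage label {s!r} at epoch {i}")

    def __len__(self) -> int:
        return self.grid.n_epochs

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.stages == s)) for s in VOCABS[self.vocab]}


def collapse_stages(h: Hypnogram, scheme: str) -> Hypnogram:
    """Collapse a hypnogram to the four-stage or two-stage vocabulary.

    N1 and N2 merge into light sleep, N3 becomes deep; for the two-stage
    scheme every non-wake stage becomes sleep. Four-stage input may be
    collapsed further to two-stage.
    """
    if scheme not in ("two", "four"):
        raise ValueError("scheme must be 'two' or 'four'")
    if h.vocab == scheme:
        return Hypnogram(h.grid, h.stages.copy(), vocab=scheme)
    if h.vocab == "raw":
        four = np.array([RAW_TO_FOUR[s] for s in h.stages], dtype=object)
    elif h.vocab == "four" and scheme == "two":
        four = h.stages
    else:
        raise ValueError(f"cannot collapse vocabulary {h.vocab!r} to {scheme!r}")
    if scheme == "four":
        return Hypnogram(h.grid, four, vocab="four")
    two = np.array([FOUR_TO_TWO[s] for s in four], dtype=object)
    return Hypnogram(h.grid, two, vocab="two")


def stage_durations(h: Hypnogram) -> dict[str, float]:
    """Minutes per stage plus total sleep time (TST) for a collapsed hypnogram.

    Each epoch contributes 0.5 min. TST is the total non-wake time.
    """
    if h.vocab == "raw":
        raise ValueError("collapse the hypnogram before computing durations")
    per_epoch_min = h.grid.epoch_len / 60.0
    out = {s: c * per_epoch_min for s, c in h.counts().items()}
    out["TST"] = sum(v for s, v in out.items() if s != "wake")
    return out


@dataclass
class SensorStreams:
    """One night of raw sensor data aligned to a common clock (s from night start).

    acc: DataFrame(t, x, y, z), nominal 50 Hz, units g.
    temp: DataFrame(t, celsius), nominal one sample / 10 s.
    ibi: IbiSeries (see :mod:`somnoring.hrv`) or None.
    """

    acc: pd.DataFrame | None = None
    temp: pd.DataFrame | None = None
    ibi: object | None = None
    subject_id: str = ""
    night_id: str = ""
    hand: str = ""

    def __post_init__(self) -> None:
        for name in ("acc", "temp"):
            df = getattr(self, name)
            if df is not None and len(df) > 1:
                t = np.asarray(df["t"], dtype=float)
                if not np.all(np.diff(t) > 0):
                    raise ValueError(f"{name} timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# Hypnogram file format: CSV with header ``epoch,stage``; epoch is the 0-based
# index. Raw files use {W,N1,N2,N3,REM}; collapsed files use upper-case
# {WAKE,LIGHT,DEEP,REM} or {WAKE,SLEEP}.
# ---------------------------------------------------------------------------

_FILE_LABEL = {"wake": "WAKE", "light": "LIGHT", "deep": "DEEP", "REM": "REM", "sleep": "SLEEP"}
_LABEL_FILE = {v: k for k, v in _FILE_LABEL.items()}


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    labels = h.stages if h.vocab == "raw" else [_FILE_LABEL[s] for s in h.stages]
    pd.DataFrame({"epoch": np.arange(len(h)), "stage": labels}).to_csv(path, index=False)


def read_hypnogram_csv(path, night_start: float = 0.0) -> Hypnogram:
    df = pd.read_csv(path)
    if list(df.columns) != ["epoch", "stage"]:
        raise ValueError(f"expected columns epoch,stage in {path}")
    epochs = df["epoch"].to_numpy()
    if not np.array_equal(epochs, np.arange(len(df))):
        raise ValueError("hypnogram epochs must be a gap-free 0-based index")
    labels = [str(s) for s in df["stage"]]
    if set(labels) <= set(RAW_STAGES):
        stages, vocab = labels, "raw"
    else:
        stages = [_LABEL_FILE.get(s, s) for s in labels]
        vocab = "two" if set(stages) <= set(TWO_STAGES) else "four"
    grid = EpochGrid(n_epochs=len(df), night_start=night_start)
    return Hypnogram(grid, np.array(stages, dtype=object), vocab=vocab)
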