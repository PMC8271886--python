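"""Gradient-boosted sleep stagers and grouped cross-validation.

The classifier is a LightGBM gradient-boosted tree ensemble with DART
(dropout) boosting and 500 estimators, predicting one stage label per 30-s
epoch from the normalized feature matrix. LightGBM handles missing feature
values natively, so epochs with unusable sensor data keep their row.

Evaluation uses 5-fold cross-validation with folds grouped by subject:
all nights of a subject land in the same fold, so a night is always
predicted by a model that never saw that person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import GroupKFold

from .core import EpochGrid, Hypnogram, collapse_stages
from .features import FEATURE_SETS, FeatureMatrix, assemble_features


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one stager.

    feature_set: one of ACC, ACC+T, ACC+T+HRV, ACC+T+HRV+C (nested).
    scheme: 'two' (wake/sleep) or 'four' (wake/light/deep/REM).
    """

    feature_set: str = "ACC+T+HRV+C"
    scheme: str = "four"
    n_estimators: int = 500
    boosting: str = "dart"
    seed: int = 0
    num_leaves: int = 31
    max_bin: int = 63
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.scheme not in ("two", "four"):
            raise ValueError("scheme must be 'two' or 'four'")
        if self.boosting not in ("dart", "gbdt"):
            raise ValueError("boosting must be 'dart' or 'gbdt'")


@dataclass
class TrainedStager:
    """A fitted ensemble plus the feature contract it was trained under."""

    estimator: LGBMClassifier
    feature_names: list[str]
    config: ModelConfig
    training_fingerprint: str = ""


@dataclass
class NightRecord:
    """One night ready for training: extracted (unnormalized) features + truth."""

    subject_id: str
    night_id: str
    features: pd.DataFrame
    hypnogram: Hypnogram


@dataclass
class CVResult:
    """Per-night out-of-fold predictions and the fold assignment."""

    predictions: dict[str, Hypnogram]
    references: dict[str, Hypnogram]
    fold_map: dict[str, int]
    config: ModelConfig


def _labels_for(night: NightRecord, scheme: str) -> np.ndarray:
    h = night.hypnogram
    if h.vocab != scheme:
        h = collapse_stages(h, scheme)
    return h.stages


def build_training_set(nights: list[NightRecord], config: ModelConfig
                       ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack per-night normalized feature matrices into (X, y, subject groups)."""
    xs, ys, gs = [], [], []
    for night in nights:
        fm = assemble_features(night.features, config.feature_set)
        xs.append(fm.data)
        ys.append(_labels_for(night, config.scheme))
        gs.append(np.repeat(night.subject_id, fm.n_epochs))
    X = pd.concat(xs, ignore_index=True)
    return X, np.concatenate(ys), np.concatenate(gs)


def train(X: pd.DataFrame | FeatureMatrix, y: np.ndarray,
          config: ModelConfig) -> TrainedStager:
    """Fit the boosted-tree stager; deterministic given the config seed."""
    if isinstance(X, FeatureMatrix):
        X = X.data
    y = np.asarray(y, dtype=object)
    classes = np.unique(y.astype(str))
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class {classes!r}")
    est = LGBMClassifier(
        boosting_type=config.boosting,
        n_estimators=config.n_estimators,
        num_leaves=config.num_leaves,
        max_bin=config.max_bin,
        learning_rate=config.learning_rate,
        random_state=config.seed,
        verbose=-1,
    )
    est.fit(X, y.astype(str))
    return TrainedStager(estimator=est, feature_names=list(X.columns), config=config,
                         training_fingerprint=f"n={len(X)};p={X.shape[1]}")


def predict_hypnogram(stager: TrainedStager, features: pd.DataFrame | FeatureMatrix,
                      grid: EpochGrid | None = None) -> Hypnogram:
    """One label per epoch for a night's (already normalized) feature matrix."""
    if isinstance(features, FeatureMatrix):
        features = features.data
    missing = [c for c in stager.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"features missing required columns: {missing}")
    X = features[stager.feature_names]
    labels = stager.estimator.predict(X)
    if grid is None:
        grid = EpochGrid(n_epochs=len(X))
    return Hypnogram(grid, np.asarray(labels, dtype=object), vocab=stager.config.scheme)


def predict_night(stager: TrainedStager, night: NightRecord) -> Hypnogram:
    fm = assemble_features(night.features, stager.config.feature_set)
    return predict_hypnogram(stager, fm, grid=night.hypnogram.grid)


def cross_validate(nights: list[NightRecord], config: ModelConfig, k: int = 5) -> CVResult:
    """Grouped k-fold CV: each night predicted once, never by its own subject's model."""
    subjects = sorted({n.subject_id for n in nights})
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects < {k} folds")
    night_subjects = np.array([n.subject_id for n in nights])
    splitter = GroupKFold(n_splits=k)
    predictions: dict[str, Hypnogram] = {}
    references: dict[str, Hypnogram] = {}
    fold_map: dict[str, int] = {}
    idx = np.arange(len(nights))
    for fold, (tr, te) in enumerate(splitter.split(idx, groups=night_subjects)):
        X, y, _ = build_training_set([nights[i] for i in tr], config)
        stager = train(X, y, config)
        for i in te:
            night = nights[i]
            predictions[night.night_id] = predict_night(stager, night)
            references[night.night_id] = collapse_stages(night.hypnogram, config.scheme) \
                if night.hypnogram.vocab != config.scheme else night.hypnogram
            fold_map[night.night_id] = fold
    return CVResult(predictions, references, fold_map, config)
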