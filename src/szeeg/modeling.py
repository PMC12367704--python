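"""Ensemble classifiers, cross-validation folds and the four report metrics.

The four model names follow the common EEG-classification quartet (random
forest plus three gradient-boosting flavours).  Each name resolves to the
corresponding library when it is installed and otherwise to a scikit-learn
stand-in with equivalent behaviour for tabular features:

    rf       -> sklearn RandomForestClassifier
    xgboost  -> xgboost.XGBClassifier        | sklearn GradientBoosting
    catboost -> catboost.CatBoostClassifier  | sklearn HistGradientBoosting
    lightgbm -> lightgbm.LGBMClassifier      | sklearn HistGradientBoosting

Learners are interchangeable adapters: swapping them changes scores only,
never fold structure, table handling or metric code.  SCZ is the positive
class for precision/recall/F1, and all metrics are reported on the percent
scale as mean +/- sd over folds.
"""

from __future__ import annotations

import importlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .core import ConfigurationError, InputError
from .features import META_COLUMNS, feature_columns

POSITIVE_CLASS = "SCZ"
MODEL_NAMES = ("rf", "xgboost", "catboost", "lightgbm")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


def _optional(module: str) -> object | None:
    try:
        return importlib.import_module(module)
    except ImportError:
        return None


@dataclass
class ModelConfig:
    """A named learner plus hyperparameter overrides and its seed."""

    model: str = "catboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        name = self.model.lower()
        if name not in MODEL_NAMES:
            raise ConfigurationError(
                f"unknown model {self.model!r}; choose from {MODEL_NAMES}"
            )
        self.model = name


def make_estimator(mc: ModelConfig):
    """Instantiate the configured learner (library defaults + fixed seed)."""
    hp = dict(mc.hyperparameters)
    if mc.model == "rf":
        return RandomForestClassifier(random_state=mc.seed, **hp)
    if mc.model == "xgboost":
        xgb = _optional("xgboost")
        if xgb is not None:
            return xgb.XGBClassifier(random_state=mc.seed, **hp)
        return GradientBoostingClassifier(random_state=mc.seed, **hp)
    # catboost / lightgbm
    lib = _optional(mc.model)
    if lib is not None:
        if mc.model == "catboost":
            return lib.CatBoostClassifier(
                random_seed=mc.seed, verbose=0, **hp
            )
        return lib.LGBMClassifier(random_state=mc.seed, verbose=-1, **hp)
    return HistGradientBoostingClassifier(random_state=mc.seed, **hp)


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and binary labels (1 = SCZ) from a feature table."""
    x = table[feature_columns(table)].to_numpy(dtype=np.float64)
    y = (table["group"].to_numpy() == POSITIVE_CLASS).astype(np.int64)
    return x, y


@dataclass
class FoldAssignment:
    """Disjoint train/test index pairs covering every row exactly once."""

    unit: str
    n_folds: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __iter__(self):
        return iter(self.folds)

    def test_fold_of_rows(self, n_rows: int) -> np.ndarray:
        out = np.full(n_rows, -1, dtype=int)
        for k, (_, test) in enumerate(self.folds):
            out[test] = k
        return out


def make_folds(
    table: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    unit: str = "window",
) -> FoldAssignment:
    """Stratified k-fold assignment of table rows.

    unit='window' splits rows independently; note that windows of one
    subject can then land in both train and test folds, which is optimistic
    whenever per-subject idiosyncrasies exist.  unit='subject' keeps all
    windows of a subject in one fold (leakage-safe).
    """
    if n_folds < 2:
        raise ConfigurationError(f"n_folds={n_folds} must be >= 2")
    _, y = split_xy(table)
    if unit == "window":
        if n_folds > len(table):
            raise ConfigurationError("more folds than rows")
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        folds = list(splitter.split(np.zeros(len(y)), y))
    elif unit == "subject":
        groups = table["subject_id"].to_numpy()
        if n_folds > len(np.unique(groups)):
            raise ConfigurationError("more folds than subjects")
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        folds = list(splitter.split(np.zeros(len(y)), y, groups))
    else:
        raise ConfigurationError(f"unit must be 'window' or 'subject', got {unit!r}")
    return FoldAssignment(unit, n_folds, seed, folds)


def fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, precision, recall and F1 (percent) from binary labels.

    Computed straight from the confusion counts with the positive class
    coded 1; an empty precision/recall denominator scores 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(len(y_true), 1)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {
        "accuracy": 100.0 * acc,
        "precision": 100.0 * prec,
        "recall": 100.0 * rec,
        "f1": 100.0 * f1,
    }


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation metrics (percent scale)."""

    model: ModelConfig
    n_folds: int
    per_fold: pd.DataFrame  # columns: fold + METRIC_NAMES
    fold_assignment: FoldAssignment

    def mean(self, metric: str = "accuracy") -> float:
        return float(self.per_fold[metric].mean())

    def sd(self, metric: str = "accuracy") -> float:
        return float(self.per_fold[metric].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "mean": self.mean(m), "sd": self.sd(m)}
            for m in METRIC_NAMES
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": self.model.model,
            "seed": self.model.seed,
            "n_folds": self.n_folds,
            "fold_unit": self.fold_assignment.unit,
            "per_fold": self.per_fold.to_dict(orient="records"),
            "aggregate": {
                m: {"mean": self.mean(m), "sd": self.sd(m)}
                for m in METRIC_NAMES
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cross_validate(
    table: pd.DataFrame,
    mc: ModelConfig,
    folds: FoldAssignment,
    feature_subset: Sequence[str] | None = None,
) -> CVResult:
    """Fit on each fold's training rows and score its held-out rows.

    ``feature_subset`` restricts the model to the named columns without
    touching fold structure (used by the feature-selection curve).
    """
    x, y = split_xy(table)
    if len(np.unique(y)) < 2:
        raise InputError("feature table must contain both groups")
    if feature_subset is not None:
        cols = feature_columns(table)
        missing = [c for c in feature_subset if c not in cols]
        if missing:
            raise InputError(f"unknown feature columns {missing[:5]}")
        # a subset is a set: keep canonical column order so that the full
        # subset reproduces the full-feature fit exactly
        idx = sorted(cols.index(c) for c in feature_subset)
        x = x[:, idx]
    rows = []
    for k, (train, test) in enumerate(folds):
        est = make_estimator(mc)  # fresh estimator per fold
        est.fit(x[train], y[train])
        rows.append(
            {"fold": k, **fold_metrics(y[test], est.predict(x[test]))}
        )
    return CVResult(mc, folds.n_folds, pd.DataFrame(rows), folds)
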