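"""Importance-ranked feature selection with a nested-subset accuracy curve.

The default procedure ranks all features once by the base model's importance
scores (averaged over the cross-validation folds' fitted models) and then
evaluates the model on nested ranking prefixes of growing size, returning
the accuracy-vs-size curve and the prefix at its maximum.  A stricter
``elimination_ranking`` variant re-fits and re-ranks after each elimination
round instead of trusting a single full-model ranking; it is much more
expensive at 760 features and gives a ranking consumed by the same curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from .core import ConfigurationError, InputError
from .features import feature_columns, parse_feature_name
from .modeling import FoldAssignment, ModelConfig, cross_validate, make_estimator, split_xy


def _fold_importances(est, x_test, y_test, n_features, seed, n_repeats):
    """Importance scores of one fitted model.

    Uses the library's native importances when the estimator exposes them;
    otherwise held-out permutation importance (needed for the scikit-learn
    HistGradientBoosting stand-in, which has no impurity importances).
    Scores are shifted to be non-negative.
    """
    imp = getattr(est, "feature_importances_", None)
    if imp is None:
        res = permutation_importance(
            est, x_test, y_test, n_repeats=n_repeats, random_state=seed
        )
        imp = res.importances_mean
    imp = np.asarray(imp, dtype=np.float64)
    if imp.shape != (n_features,):
        raise ConfigurationError(
            f"model returned {imp.shape} importances for {n_features} features"
        )
    return np.clip(imp, 0.0, None) if imp.min() < 0 else imp


def importance_ranking(
    table: pd.DataFrame,
    mc: ModelConfig,
    folds: FoldAssignment,
    n_repeats: int = 3,
) -> list[str]:
    """Feature names in descending mean importance over CV folds.

    Ties break deterministically toward earlier canonical column order.
    """
    cols = feature_columns(table)
    x, y = split_xy(table)
    scores = np.zeros(len(cols))
    for train, test in folds:
        est = make_estimator(mc)
        est.fit(x[train], y[train])
        scores += _fold_importances(
            est, x[test], y[test], len(cols), mc.seed, n_repeats
        )
    scores /= folds.n_folds
    order = np.argsort(-scores, kind="stable")
    return [cols[i] for i in order]


def elimination_ranking(
    table: pd.DataFrame,
    mc: ModelConfig,
    step: int = 1,
    n_repeats: int = 3,
) -> list[str]:
    """Recursive-elimination ranking: re-fit and re-score after each round.

    Each round fits the base model on all rows with the surviving features
    and drops the ``step`` least important; the elimination order, reversed,
    is the ranking (last survivor = most important).
    """
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    x, y = split_xy(table)
    cols = feature_columns(table)
    alive = list(range(len(cols)))
    eliminated: list[int] = []
    while alive:
        est = make_estimator(mc)
        est.fit(x[:, alive], y)
        imp = _fold_importances(
            est, x[:, alive], y, len(alive), mc.seed, n_repeats
        )
        order = np.argsort(imp, kind="stable")  # ascending importance
        drop = order[: min(step, len(alive))]
        for pos in sorted(drop, reverse=True):
            eliminated.append(alive.pop(pos))
    return [cols[i] for i in reversed(eliminated)]


@dataclass
class RFETrace:
    """Ranking, accuracy-vs-subset-size curve and the optimal prefix."""

    ranking: list[str]
    sizes: list[int]
    curve: list[float]  # mean CV accuracy (percent) per evaluated size
    optimal_size: int
    base_model: ModelConfig
    curve_sd: list[float] = field(default_factory=list)

    @property
    def optimal_subset(self) -> list[str]:
        return self.ranking[: self.optimal_size]

    @property
    def optimal_accuracy(self) -> float:
        return max(self.curve)

    def to_dict(self) -> dict:
        return {
            "base_model": self.base_model.model,
            "seed": self.base_model.seed,
            "ranking": self.ranking,
            "sizes": self.sizes,
            "curve": self.curve,
            "curve_sd": self.curve_sd,
            "optimal_size": self.optimal_size,
            "optimal_subset": self.optimal_subset,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RFETrace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ranking=d["ranking"], sizes=d["sizes"], curve=d["curve"],
            optimal_size=d["optimal_size"],
            base_model=ModelConfig(model=d["base_model"], seed=d["seed"]),
            curve_sd=d.get("curve_sd", []),
        )


def rfe_curve(
    table: pd.DataFrame,
    ranking: list[str],
    mc: ModelConfig,
    folds: FoldAssignment,
    stride: int = 1,
) -> RFETrace:
    """Cross-validated accuracy of the model on each ranking prefix.

    Sizes run 1, 1+stride, ... and always include the full feature count, so
    the last curve point is the full-feature CV accuracy under identical
    folds and seeds.  The optimal size is the accuracy argmax, ties broken
    toward the smaller subset.
    """
    cols = feature_columns(table)
    if sorted(ranking) != sorted(cols):
        raise InputError("ranking must cover exactly the table's feature columns")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    total = len(ranking)
    sizes = list(range(1, total + 1, stride))
    if sizes[-1] != total:
        sizes.append(total)
    curve, curve_sd = [], []
    for k in sizes:
        res = cross_validate(table, mc, folds, feature_subset=ranking[:k])
        curve.append(res.mean("accuracy"))
        curve_sd.append(res.sd("accuracy"))
    best = int(np.argmax(curve))  # first occurrence = smallest size on ties
    return RFETrace(
        ranking=list(ranking), sizes=sizes, curve=curve,
        optimal_size=sizes[best], base_model=mc, curve_sd=curve_sd,
    )


def select_features(
    table: pd.DataFrame,
    mc: ModelConfig,
    folds: FoldAssignment,
    stride: int = 1,
    rescoring: bool = False,
) -> RFETrace:
    """Rank features and evaluate nested prefixes in one call."""
    if rescoring:
        ranking = elimination_ranking(table, mc, step=max(1, stride))
    else:
        ranking = importance_ranking(table, mc, folds)
    return rfe_curve(table, ranking, mc, folds, stride=stride)


def export_subset(
    subset: list[str] | RFETrace,
    band_names: tuple[str, ...] = ("Delta", "Theta", "Alpha", "Beta", "Gamma"),
) -> pd.DataFrame:
    """Family x band cross-tabulation of a feature subset with margins."""
    if isinstance(subset, RFETrace):
        subset = subset.optimal_subset
    families = ("RP", "FuzEn", "PLI")
    counts = pd.DataFrame(
        0, index=list(families), columns=list(band_names), dtype=int
    )
    for name in subset:
        key = parse_feature_name(name)
        counts.loc[key.family, key.band] += 1
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    counts.index.name = "family"
    return counts
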