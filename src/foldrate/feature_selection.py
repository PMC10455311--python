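"""Iterative weighted-importance feature selection.

Feature importance is accumulated over many grouped train/test
partitions (50 under the default 10 x 5-fold protocol): each
partition's model contributes its per-feature importance scores
multiplied by that partition's test performance (accuracy for
classification, Pearson correlation for regression).  Features are
ranked by the summed weighted score; nested subsets of increasing size
are then evaluated by repeated cross-validation and the best-performing
size is chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor

from foldrate.evaluation import CVProtocol, make_partitions, run_cv
from foldrate.metrics import regression_metrics
from foldrate.models import GBTConfig, ModelError, _as_label_values, undersample_balanced


class SelectionError(ValueError):
    pass


@dataclass
class SelectionTrace:
    """Outcome of one selection run.

    ``rounds`` lists (feature, weighted score) in selection order;
    ``subset_performance`` maps subset size -> CV metric (accuracy or
    PCC); ``chosen_size`` is the argmax of that curve.
    """

    rounds: list[tuple[str, float]]
    subset_performance: dict[int, float] = field(default_factory=dict)
    chosen_size: int = 0

    @property
    def chosen_features(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.rounds[: self.chosen_size])

    def write(self, ranking_path: str | Path, curve_path: str | Path | None = None):
        pd.DataFrame(
            [
                {"rank": i + 1, "feature": name, "score": score}
                for i, (name, score) in enumerate(self.rounds)
            ]
        ).to_csv(ranking_path, sep="\t", index=False)
        if curve_path is not None:
            pd.DataFrame(
                sorted(self.subset_performance.items()),
                columns=["subset_size", "cv_metric"],
            ).to_csv(curve_path, sep="\t", index=False)


def combine_weighted(
    importances: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Sum per-partition importance vectors, each scaled by its
    partition weight.  Linear in the importances for fixed weights."""
    if len(importances) != len(weights):
        raise SelectionError("importances and weights must align")
    total = np.zeros_like(np.asarray(importances[0], dtype=float))
    for imp, w in zip(importances, weights):
        total = total + w * np.asarray(imp, dtype=float)
    return total


def _partition_weight(task, model, X_test, y_test) -> float:
    if task == "classify":
        return float(np.mean(model.predict(X_test) == y_test))
    pred = model.predict(X_test)
    if np.std(pred) == 0 or np.std(y_test) == 0:
        return 0.0
    return float(regression_metrics(pred, y_test).pcc)


def weighted_importance(
    partitions: Sequence[tuple[np.ndarray, np.ndarray]],
    X,
    y,
    task: str,
    feature_names: Sequence[str],
    config: GBTConfig = GBTConfig(),
    importance_type: str = "gain",
) -> dict[str, float]:
    """Per-feature score summed over partitions, each weighted by the
    partition's test performance.

    Classification partitions are balanced by under-sampling before the
    model is fitted; partitions with a single-class test set are skipped
    with a warning.  ``importance_type`` is ``"gain"`` (total impurity
    gain, default) or ``"split"`` (number of times a feature is used).
    """
    X = np.asarray(X, dtype=float)
    if task == "classify":
        y = _as_label_values(y)
    else:
        y = np.asarray(y, dtype=float)
    if X.shape[1] != len(feature_names):
        raise SelectionError("feature_names must match the matrix width")

    per_partition: list[np.ndarray] = []
    weights: list[float] = []
    seeds = iter(
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(config.seed).spawn(len(partitions))
    )
    for train_idx, test_idx in partitions:
        seed = next(seeds)
        if task == "classify":
            if len(set(y[test_idx])) < 2:
                warnings.warn(
                    "partition skipped: single-class test set", stacklevel=2
                )
                continue
            per_class = min(
                np.sum(y[train_idx] == c) for c in set(y[train_idx])
            )
            if per_class == 0:
                warnings.warn(
                    "partition skipped: training side lacks a class",
                    stacklevel=2,
                )
                continue
            idx = train_idx[
                _relative_balanced(y[train_idx], int(per_class), seed)
            ]
            model = GradientBoostingClassifier(**config.tree_params(seed))
        else:
            idx = train_idx
            model = GradientBoostingRegressor(**config.tree_params(seed))
        model.fit(X[idx], y[idx])
        weights.append(_partition_weight(task, model, X[test_idx], y[test_idx]))
        per_partition.append(_importances(model, importance_type))
    if not per_partition:
        raise SelectionError("every partition was skipped")
    scores = combine_weighted(per_partition, weights)
    return dict(zip(feature_names, scores))


def _relative_balanced(y_sub, per_class: int, seed: int) -> np.ndarray:
    try:
        return undersample_balanced(y_sub, per_class, seed)
    except ModelError as exc:  # pragma: no cover - guarded above
        raise SelectionError(str(exc)) from exc


def _importances(model, importance_type: str) -> np.ndarray:
    if importance_type == "gain":
        return model.feature_importances_
    if importance_type == "split":
        counts = np.zeros(model.n_features_in_)
        for est in model.estimators_.ravel():
            tree = est.tree_
            used = tree.feature[tree.feature >= 0]
            np.add.at(counts, used, 1)
        return counts
    raise SelectionError(f"unknown importance type {importance_type!r}")


def select_features(
    X,
    y,
    groups: Sequence,
    task: str,
    feature_names: Sequence[str],
    max_size: int,
    config: GBTConfig = GBTConfig(),
    protocol: CVProtocol = CVProtocol(),
    importance_type: str = "gain",
    mode: str = "forward",
) -> SelectionTrace:
    """Rank features by weighted importance, then pick the subset size
    whose nested prefix maximises the repeated-CV metric.

    ``mode="forward"`` (default) accumulates features from the top of
    the ranking; ``mode="backward"`` drops features from the bottom,
    which yields the same nested family evaluated from the other end.
    Ranking ties break lexicographically by feature name.
    """
    if max_size < 1:
        raise SelectionError(f"max_size must be >= 1, got {max_size}")
    if max_size > len(feature_names):
        raise SelectionError("max_size exceeds the number of features")
    X = np.asarray(X, dtype=float)
    partitions = make_partitions(groups, protocol)
    scores = weighted_importance(
        partitions, X, y, task, feature_names, config, importance_type
    )
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))

    name_to_col = {n: i for i, n in enumerate(feature_names)}
    sizes = (
        range(1, max_size + 1)
        if mode == "forward"
        else range(max_size, 0, -1)
    )
    eval_protocol = replace(protocol, seed=protocol.seed + 1)
    performance: dict[int, float] = {}
    for size in sizes:
        cols = [name_to_col[name] for name, _ in ranked[:size]]
        result = run_cv(
            X[:, cols], y, groups, task, config, eval_protocol
        )
        pooled = result["pooled"]
        metric = pooled.acc if task == "classify" else pooled.pcc
        performance[size] = float(metric) if metric is not None else float("nan")
    chosen = max(
        performance, key=lambda s: (performance[s], -s)
    )
    return SelectionTrace(
        rounds=ranked[:max_size],
        subset_performance=performance,
        chosen_size=chosen,
    )
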