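"""Cross-validation drivers: repeated grouped 5-fold CV and blind-test
evaluation.

Folds keep all records sharing a (protein, position) group on one side.
The headline CV numbers are pooled over folds (summed confusion counts
for classification, concatenated predictions for regression); per-fold
reports are also returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from foldrate.metrics import (
    ConfusionSummary,
    MetricReport,
    classification_metrics,
    regression_metrics,
)
from foldrate.models import (
    CLASS_VALUES,
    GBTConfig,
    _as_label_values,
    train_classifier,
    train_regressor,
)
from foldrate.variant_data import VariantError, validate_group_disjoint


@dataclass(frozen=True)
class CVProtocol:
    """Repeated grouped k-fold protocol (default 10 x 5-fold)."""

    n_repeats: int = 10
    n_folds: int = 5
    balanced: bool = True
    seed: int = 0

    def repeat_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [
            int(c.generate_state(1)[0] % (2**31))
            for c in ss.spawn(self.n_repeats)
        ]


def grouped_kfold(
    groups: Sequence, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-disjoint k-fold partition of ``range(len(groups))``.

    Unique groups are shuffled with the seed and dealt into folds of
    near-equal group count; each fold's records form one test set.
    """
    keys = list(groups)
    by_group: dict = {}
    for i, key in enumerate(keys):
        by_group.setdefault(key, []).append(i)
    order = sorted(by_group)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    folds = []
    chunks = np.array_split(np.arange(len(order)), n_folds)
    for chunk in chunks:
        test = np.sort(
            np.concatenate([by_group[order[g]] for g in chunk])
            if len(chunk)
            else np.array([], dtype=int)
        )
        mask = np.ones(len(keys), dtype=bool)
        mask[test] = False
        folds.append((np.where(mask)[0], test))
    return folds


def make_partitions(
    groups: Sequence, protocol: CVProtocol
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All train/test index pairs of the repeated grouped CV (50 pairs
    under the default protocol)."""
    partitions = []
    for rep_seed in protocol.repeat_seeds():
        partitions.extend(grouped_kfold(groups, protocol.n_folds, rep_seed))
    return partitions


def _adaptive_per_class(labels, config: GBTConfig) -> GBTConfig:
    """Cap the per-class sample size at the smallest class present so
    small folds remain trainable."""
    y = _as_label_values(labels)
    smallest = min(np.sum(y == c) for c in set(y))
    return replace(config, per_class=int(min(config.per_class, smallest)))


def _fit_predict(task, X, y, train_idx, test_idx, config, fold_seed):
    cfg = replace(config, seed=fold_seed)
    if task == "classify":
        cfg = _adaptive_per_class(y[train_idx], cfg)
        model = train_classifier(X[train_idx], y[train_idx], cfg)
        return np.array(model.predict(X[test_idx]))
    model = train_regressor(X[train_idx], y[train_idx], cfg)
    return model.predict(X[test_idx])


def run_cv(
    X,
    y,
    groups: Sequence,
    task: str,
    config: GBTConfig = GBTConfig(),
    protocol: CVProtocol = CVProtocol(),
) -> dict:
    """Repeated grouped cross-validation.

    Returns ``{"fold_reports": [...], "pooled": MetricReport,
    "n_folds_run": int, "skipped": int}``.  Classification folds whose
    test side lacks a class are still evaluated (the pooled confusion
    absorbs them); folds whose training side lacks a class are skipped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    if task == "classify":
        y = _as_label_values(y)
    else:
        y = np.asarray(y, dtype=float)
    fold_reports: list[MetricReport] = []
    pooled_z = np.zeros((len(CLASS_VALUES), len(CLASS_VALUES)))
    pooled_pred: list[np.ndarray] = []
    pooled_true: list[np.ndarray] = []
    skipped = 0
    fold_seed_ss = np.random.SeedSequence(protocol.seed + 1)
    fold_seeds = iter(
        int(c.generate_state(1)[0] % (2**31))
        for c in fold_seed_ss.spawn(protocol.n_repeats * protocol.n_folds)
    )
    fold_predictions: list[tuple[np.ndarray, np.ndarray]] = []
    for train_idx, test_idx in make_partitions(groups, protocol):
        fold_seed = next(fold_seeds)
        if task == "classify" and len(set(y[train_idx])) < len(
            set(y)
        ):
            warnings.warn(
                "fold skipped: training side lacks a class", stacklevel=2
            )
            skipped += 1
            continue
        pred = _fit_predict(task, X, y, train_idx, test_idx, config, fold_seed)
        fold_predictions.append((test_idx, pred))
        if task == "classify":
            conf = ConfusionSummary.from_labels(
                y[test_idx], pred, classes=CLASS_VALUES
            )
            pooled_z += conf.z
            fold_reports.append(classification_metrics(conf))
        else:
            pooled_pred.append(pred)
            pooled_true.append(y[test_idx])
            fold_reports.append(regression_metrics(pred, y[test_idx]))
    if task == "classify":
        pooled = classification_metrics(
            ConfusionSummary.from_matrix(pooled_z, CLASS_VALUES)
        )
    else:
        pooled = regression_metrics(
            np.concatenate(pooled_pred), np.concatenate(pooled_true)
        )
    return {
        "fold_reports": fold_reports,
        "fold_predictions": fold_predictions,
        "pooled": pooled,
        "n_folds_run": len(fold_reports),
        "skipped": skipped,
    }


def run_blind_test(
    X_train,
    y_train,
    groups_train: Sequence,
    X_test,
    y_test,
    groups_test: Sequence,
    task: str,
    config: GBTConfig = GBTConfig(),
) -> MetricReport:
    """Train on one set, evaluate once on a group-disjoint held-out set.

    Raises on any (protein, position) overlap between the two sides.
    """
    validate_group_disjoint(groups_train, groups_test)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if task == "classify":
        y_train = _as_label_values(y_train)
        y_test = _as_label_values(y_test)
        cfg = _adaptive_per_class(y_train, config)
        model = train_classifier(X_train, y_train, cfg)
        pred = np.array(model.predict(X_test))
        return classification_metrics(
            ConfusionSummary.from_labels(y_test, pred, classes=CLASS_VALUES)
        )
    y_train = np.asarray(y_train, dtype=float)
    model = train_regressor(X_train, y_train, config)
    return regression_metrics(model.predict(X_test), np.asarray(y_test, float))
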