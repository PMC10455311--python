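"""Gradient-boosted tree predictors: the balanced voting ensemble for
three-class classification and the regression model.

The classifier deals with class imbalance by repeated under-sampling:
ten sub-models are each trained on an independent class-balanced subset
(default 80 records per class) and combined by voting, either by
summing class probabilities (default) or by majority with a fixed
tie-break order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor

from foldrate.variant_data import CLASS_ORDER, Label

CLASS_VALUES = tuple(lab.value for lab in CLASS_ORDER)

BUNDLE_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class GBTConfig:
    """Hyperparameters shared by every gradient-boosted sub-model.

    Deliberately small and fixed: no early stopping, no tuning, seeds
    threaded everywhere so that training is reproducible.
    """

    n_estimators: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    subsample: float = 1.0
    n_sub_models: int = 10
    per_class: int = 80
    vote_rule: str = "probability_sum"  # or "majority"
    seed: int = 0

    def tree_params(self, random_state: int) -> dict:
        return dict(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            subsample=self.subsample,
            random_state=random_state,
        )


@dataclass
class Prediction:
    """One predicted outcome: a label with class scores, or a numeric
    folding-rate change."""

    label: str | None = None
    class_scores: dict | None = None
    delta_lnkf_hat: float | None = None


def _as_label_values(labels: Sequence) -> np.ndarray:
    return np.array(
        [lab.value if isinstance(lab, Label) else str(lab) for lab in labels]
    )


def _sub_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def undersample_balanced(
    labels: Sequence, per_class: int, seed: int
) -> np.ndarray:
    """Indices of a class-balanced subset, ``per_class`` per class,
    drawn without replacement; deterministic per seed."""
    y = _as_label_values(labels)
    rng = np.random.default_rng(seed)
    picked = []
    for cls in sorted(set(y)):
        pool = np.where(y == cls)[0]
        if len(pool) < per_class:
            raise ModelError(
                f"class {cls!r} has only {len(pool)} members, "
                f"cannot draw {per_class}"
            )
        picked.append(rng.choice(pool, size=per_class, replace=False))
    return np.sort(np.concatenate(picked))


def _feature_matrix(X, feature_names: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [n for n in feature_names if n not in X.columns]
            if missing:
                raise ModelError(f"missing features: {missing[:10]}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ModelError(
            f"feature dimension mismatch: got {X.shape[1]}, model expects "
            f"{len(feature_names)}"
        )
    return X, tuple(feature_names) if feature_names else None


@dataclass
class EnsembleClassifier:
    """Ten balanced gradient-boosted sub-models with a voting rule."""

    sub_models: list
    feature_names: tuple[str, ...]
    config: GBTConfig
    classes: tuple[str, ...] = CLASS_VALUES

    def predict_proba(self, X) -> np.ndarray:
        """Summed sub-model class probabilities, renormalised per row."""
        X, _ = _feature_matrix(X, self.feature_names)
        total = np.zeros((X.shape[0], len(self.classes)))
        for model in self.sub_models:
            proba = model.predict_proba(X)
            cols = {c: i for i, c in enumerate(model.classes_)}
            for j, cls in enumerate(self.classes):
                if cls in cols:
                    total[:, j] += proba[:, cols[cls]]
        return total / total.sum(axis=1, keepdims=True)

    def predict(self, X) -> list[str]:
        if self.config.vote_rule == "majority":
            return self._predict_majority(X)
        proba = self.predict_proba(X)
        return [self.classes[i] for i in proba.argmax(axis=1)]

    def _predict_majority(self, X) -> list[str]:
        X, _ = _feature_matrix(X, self.feature_names)
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=int)
        for model in self.sub_models:
            pred = model.predict(X)
            for j, cls in enumerate(self.classes):
                votes[:, j] += pred == cls
        # argmax breaks ties by the fixed class order
        return [self.classes[i] for i in votes.argmax(axis=1)]

    def predict_one(self, vector) -> Prediction:
        proba = self.predict_proba(np.atleast_2d(vector))[0]
        scores = dict(zip(self.classes, proba))
        if self.config.vote_rule == "majority":
            label = self._predict_majority(np.atleast_2d(vector))[0]
        else:
            label = self.classes[int(np.argmax(proba))]
        return Prediction(label=label, class_scores=scores)


@dataclass
class RegressionModel:
    """A single gradient-boosted regressor for the log rate change."""

    model: GradientBoostingRegressor
    feature_names: tuple[str, ...]
    config: GBTConfig

    def predict(self, X) -> np.ndarray:
        X, _ = _feature_matrix(X, self.feature_names)
        return self.model.predict(X)

    def predict_one(self, vector) -> Prediction:
        return Prediction(
            delta_lnkf_hat=float(self.predict(np.atleast_2d(vector))[0])
        )


def train_classifier(
    X,
    labels: Sequence,
    config: GBTConfig = GBTConfig(),
    feature_names: Sequence[str] | None = None,
) -> EnsembleClassifier:
    """Fit the balanced under-sampling voting ensemble.

    Each of the ``n_sub_models`` sub-classifiers trains on its own
    balanced subset drawn with a seed derived from the master seed.
    """
    y = _as_label_values(labels)
    if len(set(y)) < 2:
        raise ModelError("training labels contain a single class")
    X, names = _feature_matrix(X, feature_names)
    if names is None:
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    if not np.isfinite(X).all():
        raise ModelError("feature matrix contains non-finite values")
    sub_models = []
    for sub_seed in _sub_seeds(config.seed, config.n_sub_models):
        idx = undersample_balanced(y, config.per_class, sub_seed)
        clf = GradientBoostingClassifier(**config.tree_params(sub_seed))
        clf.fit(X[idx], y[idx])
        sub_models.append(clf)
    return EnsembleClassifier(
        sub_models=sub_models, feature_names=names, config=config
    )


def train_regressor(
    X,
    targets: Sequence[float],
    config: GBTConfig = GBTConfig(),
    feature_names: Sequence[str] | None = None,
) -> RegressionModel:
    """Fit the gradient-boosted regression predictor."""
    y = np.asarray(targets, dtype=float)
    if y.size < 20:
        raise ModelError(f"need at least 20 examples, got {y.size}")
    if not np.isfinite(y).all():
        raise ModelError("targets contain non-finite values")
    X, names = _feature_matrix(X, feature_names)
    if names is None:
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    model = GradientBoostingRegressor(**config.tree_params(config.seed % 2**31))
    model.fit(X, y)
    return RegressionModel(model=model, feature_names=names, config=config)


def predict_class(model: EnsembleClassifier, vector) -> Prediction:
    return model.predict_one(vector)


def predict_delta(model: RegressionModel, vector) -> float:
    return float(model.predict_one(vector).delta_lnkf_hat)


# ---------------------------------------------------------------------------
# model bundle persistence


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_bundle(model, directory: str | Path) -> None:
    """Persist a model as a directory: config + serialized estimators +
    feature-name manifest with content hashes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    if isinstance(model, EnsembleClassifier):
        task = "classify"
        for i, sub in enumerate(model.sub_models):
            fname = f"sub_model_{i}.joblib"
            joblib.dump(sub, directory / fname)
            files.append(fname)
    elif isinstance(model, RegressionModel):
        task = "regress"
        joblib.dump(model.model, directory / "model.joblib")
        files.append("model.joblib")
    else:
        raise ModelError(f"cannot save object of type {type(model)}")
    (directory / "feature_names.txt").write_text(
        "\n".join(model.feature_names) + "\n"
    )
    files.append("feature_names.txt")
    (directory / "config.json").write_text(
        json.dumps(
            {"task": task, **dataclasses.asdict(model.config)}, indent=2
        )
        + "\n"
    )
    files.append("config.json")
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "task": task,
        "files": {f: _sha256(directory / f) for f in files},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_bundle(directory: str | Path):
    """Load a saved model bundle, validating the manifest hashes."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ModelError(
            f"unsupported bundle format {manifest.get('format_version')}"
        )
    for fname, digest in manifest["files"].items():
        actual = _sha256(directory / fname)
        if actual != digest:
            raise ModelError(f"bundle file {fname} fails hash validation")
    cfg = json.loads((directory / "config.json").read_text())
    task = cfg.pop("task")
    config = GBTConfig(**cfg)
    names = tuple(
        (directory / "feature_names.txt").read_text().strip().splitlines()
    )
    if task == "classify":
        subs = [
            joblib.load(directory / f)
            for f in sorted(
                manifest["files"],
                key=lambda f: (len(f), f),
            )
            if f.startswith("sub_model_")
        ]
        return EnsembleClassifier(
            sub_models=subs, feature_names=names, config=config
        )
    return RegressionModel(
        model=joblib.load(directory / "model.joblib"),
        feature_names=names,
        config=config,
    )
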