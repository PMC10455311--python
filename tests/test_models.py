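import numpy as np
import pytest

from conftest import FAST
from foldrate.metrics import regression_metrics
from foldrate.models import (
    CLASS_VALUES,
    EnsembleClassifier,
    GBTConfig,
    ModelError,
    Prediction,
    load_bundle,
    predict_class,
    predict_delta,
    save_bundle,
    train_classifier,
    train_regressor,
    undersample_balanced,
)


class TestUndersample:
    def test_exact_sizes_per_class(self):
        labels = ["decrease"] * 520 + ["no_effect"] * 136 + ["increase"] * 106
        idx = undersample_balanced(labels, 80, seed=0)
        assert len(idx) == 240
        drawn = np.array(labels)[idx]
        for cls in CLASS_VALUES:
            assert np.sum(drawn == cls) == 80
        assert len(set(idx)) == len(idx)  # without replacement

    def test_deficient_class_reported(self):
        labels = ["decrease"] * 300 + ["no_effect"] * 106
        with pytest.raises(ModelError, match="no_effect"):
            undersample_balanced(labels, 200, seed=0)

    def test_deterministic(self):
        labels = ["a"] * 50 + ["b"] * 50
        a = undersample_balanced(labels, 20, seed=7)
        b = undersample_balanced(labels, 20, seed=7)
        assert np.array_equal(a, b)


class TestClassifier:
    def test_separable_blobs(self, blobs3):
        X, y = blobs3
        model = train_classifier(X[:250], y[:250], FAST)
        acc = np.mean(np.array(model.predict(X[250:])) == y[250:])
        assert acc > 0.8

    def test_sub_model_count(self, blobs3):
        X, y = blobs3
        model = train_classifier(X[:150], y[:150], FAST)
        assert len(model.sub_models) == 10

    def test_shuffled_labels_near_chance(self, blobs3):
        X, y = blobs3
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        model = train_classifier(X[:250], y_shuf[:250], FAST)
        acc = np.mean(np.array(model.predict(X[250:])) == y_shuf[250:])
        assert abs(acc - 1 / 3) < 0.1

    def test_single_class_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(ModelError, match="single class"):
            train_classifier(X, ["decrease"] * 50, FAST)

    def test_scores_sum_to_one(self, blobs3):
        X, y = blobs3
        model = train_classifier(X[:150], y[:150], FAST)
        proba = model.predict_proba(X[150:170])
        assert np.allclose(proba.sum(axis=1), 1.0)
        pred = predict_class(model, X[150])
        assert isinstance(pred, Prediction)
        assert sum(pred.class_scores.values()) == pytest.approx(1.0)
        assert pred.label == max(pred.class_scores, key=pred.class_scores.get)

    def test_reproducible_per_seed(self, blobs3):
        X, y = blobs3
        a = train_classifier(X[:150], y[:150], FAST)
        b = train_classifier(X[:150], y[:150], FAST)
        assert np.array_equal(a.predict_proba(X[150:]), b.predict_proba(X[150:]))

    def test_dimension_mismatch_named(self, blobs3):
        X, y = blobs3
        model = train_classifier(X[:150], y[:150], FAST)
        with pytest.raises(ModelError, match="dimension"):
            model.predict(np.zeros((2, 5)))

    def test_minority_recall_beats_single_model(self):
        # heavy imbalance with overlapping classes: a single model
        # collapses onto the majority; the balanced ensemble does not
        from sklearn.ensemble import GradientBoostingClassifier

        rng = np.random.default_rng(5)
        n_major, n_min = 400, 40
        X = np.vstack(
            [
                rng.normal(0.0, 1.0, (n_major, 4)),
                rng.normal(0.9, 1.0, (n_min, 4)),
                rng.normal(-0.9, 1.0, (n_min, 4)),
            ]
        )
        y = np.array(
            ["decrease"] * n_major + ["increase"] * n_min + ["no_effect"] * n_min
        )
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        train, test = np.arange(0, 360), np.arange(360, len(y))
        cfg = GBTConfig(n_estimators=40, per_class=25, seed=1)
        ens = train_classifier(X[train], y[train], cfg)
        single = GradientBoostingClassifier(
            n_estimators=40, random_state=1
        ).fit(X[train], y[train])

        def minority_recall(pred):
            mask = y[test] != "decrease"
            return np.mean(np.array(pred)[mask] == y[test][mask])

        assert minority_recall(ens.predict(X[test])) > minority_recall(
            single.predict(X[test])
        )


class TestVoting:
    class _Stub:
        classes_ = np.array(CLASS_VALUES)

        def __init__(self, proba):
            self._proba = np.asarray(proba)

        def predict_proba(self, X):
            return np.tile(self._proba, (len(X), 1))

        def predict(self, X):
            return np.array(
                [CLASS_VALUES[int(np.argmax(self._proba))]] * len(X)
            )

    def _ensemble(self, tables, rule):
        return EnsembleClassifier(
            sub_models=[self._Stub(t) for t in tables],
            feature_names=("f0",),
            config=GBTConfig(vote_rule=rule),
        )

    def test_unanimous_agreement(self):
        tables = [(0.8, 0.1, 0.1)] * 10
        for rule in ("probability_sum", "majority"):
            assert self._ensemble(tables, rule).predict([[0.0]]) == ["decrease"]

    def test_majority_tie_break_fixed_order(self):
        # 5 votes each for no_effect and increase: earliest class wins
        tables = [(0.0, 1.0, 0.0)] * 5 + [(0.0, 0.0, 1.0)] * 5
        assert self._ensemble(tables, "majority").predict([[0.0]]) == [
            "no_effect"
        ]

    def test_soft_equals_majority_under_confident_margins(self):
        # sufficient condition: k sub-models put class c ahead by margin
        # m each, and k*m exceeds the maximum opposing mass (10 - k)
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(500):
            # correlated sub-models: most lean towards one class so that
            # confident-agreement cases actually occur
            lead = rng.integers(3)
            tables = rng.dirichlet(np.ones(3) * 0.3, size=10)
            for i in range(10):
                if rng.random() < 0.8:
                    shift = lead - int(np.argmax(tables[i]))
                    tables[i] = np.roll(tables[i], shift)
            argmaxes = tables.argmax(axis=1)
            modal = np.bincount(argmaxes, minlength=3).argmax()
            supporters = np.where(argmaxes == modal)[0]
            k = len(supporters)
            if k < 6:
                continue
            margins = [
                tables[i, modal] - np.max(np.delete(tables[i], modal))
                for i in supporters
            ]
            if k * min(margins) <= (10 - k):
                continue
            checked += 1
            soft = self._ensemble(tables, "probability_sum").predict([[0.0]])
            hard = self._ensemble(tables, "majority").predict([[0.0]])
            assert soft == hard == [CLASS_VALUES[modal]]
        assert checked > 20  # the condition actually triggered


class TestRegressor:
    def test_planted_linear_signal(self):
        rng = np.random.default_rng(2)
        n = 300
        X = rng.normal(0, 1, (n, 6))
        y = 1.2 * X[:, 2] + rng.normal(0, 0.1, n)
        model = train_regressor(X[:200], y[:200], FAST)
        report = regression_metrics(model.predict(X[200:]), y[200:])
        assert report.pcc > 0.9

    def test_constant_targets(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 3))
        model = train_regressor(X, np.full(40, 2.5), FAST)
        assert np.allclose(model.predict(X), 2.5, atol=1e-6)

    def test_permuted_targets_no_skill(self):
        rng = np.random.default_rng(4)
        n = 300
        X = rng.normal(0, 1, (n, 6))
        y = 1.2 * X[:, 2] + rng.normal(0, 0.1, n)
        y_perm = rng.permutation(y)
        model = train_regressor(X[:200], y_perm[:200], FAST)
        report = regression_metrics(model.predict(X[200:]), y_perm[200:])
        assert report.r2 <= 0.1

    def test_too_few_examples(self):
        with pytest.raises(ModelError, match="20"):
            train_regressor(np.zeros((5, 2)), np.zeros(5), FAST)

    def test_nonfinite_target_rejected(self):
        X = np.zeros((25, 2))
        y = np.zeros(25)
        y[3] = np.nan
        with pytest.raises(ModelError, match="non-finite"):
            train_regressor(X, y, FAST)

    def test_predict_delta_finite(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (30, 4))
        model = train_regressor(X, X[:, 0], FAST)
        assert np.isfinite(predict_delta(model, X[0]))


class TestBundle:
    def test_round_trip_classifier(self, blobs3, tmp_path):
        X, y = blobs3
        model = train_classifier(X[:150], y[:150], FAST)
        save_bundle(model, tmp_path / "m")
        loaded = load_bundle(tmp_path / "m")
        assert np.array_equal(
            model.predict_proba(X[150:160]), loaded.predict_proba(X[150:160])
        )
        assert loaded.feature_names == model.feature_names

    def test_round_trip_regressor(self, tmp_path):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 4))
        model = train_regressor(X, X[:, 0], FAST)
        save_bundle(model, tmp_path / "m")
        loaded = load_bundle(tmp_path / "m")
        assert np.array_equal(model.predict(X), loaded.predict(X))

    def test_tampered_bundle_rejected(self, blobs3, tmp_path):
        X, y = blobs3
        model = train_classifier(X[:150], y[:150], FAST)
        save_bundle(model, tmp_path / "m")
        cfg = tmp_path / "m" / "config.json"
        cfg.write_text(cfg.read_text().replace('"per_class": 30', '"per_class": 31'))
        with pytest.raises(ModelError, match="hash"):
            load_bundle(tmp_path / "m")
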