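import numpy as np
import pandas as pd
import pytest

from evsort.sorter import (CellSorter, GateSpec, RFConfig, gate_classify,
                           channel_importance, predict_labels, train_rf)


@pytest.fixture(scope="module")
def separable_toy():
    rng = np.random.default_rng(0)
    y = np.array(["apoptotic"] * 10 + ["ev"] * 10, dtype=object)
    X = rng.normal(size=(20, 2))
    X[10:, 0] += 8.0
    return X, y


class TestTrainRF:
    def test_separable_training_accuracy_is_one(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        assert np.mean(forest.predict(X) == y) == 1.0

    def test_same_seed_same_predictions(self, separable_toy):
        X, y = separable_toy
        rng = np.random.default_rng(1)
        probe = rng.normal(size=(30, 2)) * 4
        cfg = RFConfig(n_trees=100, seed=5)
        p1 = train_rf(X, y, cfg).predict_proba(probe)
        p2 = train_rf(X, y, cfg).predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_heavy_imbalance_does_not_collapse_to_majority(self):
        """~66:1 imbalance (the annotated corpus ratio): the minority class
        must still be predicted on a balanced, well-separated probe set."""
        rng = np.random.default_rng(2)
        n_maj, n_min = 660, 10
        X = np.vstack([rng.normal(size=(n_maj, 3)),
                       rng.normal(size=(n_min, 3)) + 6.0])
        y = np.array(["apoptotic"] * n_maj + ["ev"] * n_min, dtype=object)
        forest = train_rf(X, y, RFConfig(n_trees=200, seed=0))
        probe = np.vstack([rng.normal(size=(50, 3)),
                           rng.normal(size=(50, 3)) + 6.0])
        pred = forest.predict(probe)
        assert {"apoptotic", "ev"} <= set(pred)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_rf(np.zeros((5, 2)), ["ev"] * 5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RFConfig(n_trees=0)


class TestPredictLabels:
    def test_high_probability_goes_to_majority_class(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        res = predict_labels(forest, X[:1])
        assert res.labels[0] == "apoptotic"
        assert res.proba.iloc[0].sum() == pytest.approx(1.0)

    def test_exact_tie_breaks_to_apoptotic(self):
        class FixedForest:
            classes_ = np.array(["apoptotic", "ev"])
            n_features_in_ = 1

            def predict_proba(self, X):
                return np.array([[0.5, 0.5], [0.1, 0.9]])

        res = predict_labels(FixedForest(), np.zeros((2, 1)))
        assert list(res.labels) == ["apoptotic", "ev"]

    def test_partition_property(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        rng = np.random.default_rng(3)
        probe = rng.normal(size=(40, 2)) * 5
        res = predict_labels(forest, probe, object_ids=np.arange(40))
        pops = res.to_population_files()
        ids = pops["apoptotic"].object_ids + pops["ev"].object_ids
        assert sorted(ids) == list(range(40))
        assert "unknown" not in pops

    def test_schema_mismatch_rejected(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=10, seed=0))
        with pytest.raises(ValueError, match="schema"):
            predict_labels(forest, np.zeros((3, 5)))


class TestChannelImportance:
    def test_importances_sum_to_one_and_group(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        frame = channel_importance(forest, ["fluorescence", "brightfield"])
        assert frame["importance"].sum() == pytest.approx(1.0)
        assert set(frame.attrs["median"].index) == {"brightfield",
                                                    "fluorescence"}

    def test_constant_feature_has_negligible_importance(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=200), np.full(200, 3.14)])
        y = np.array(["ev" if v > 0 else "apoptotic" for v in X[:, 0]],
                     dtype=object)
        forest = train_rf(X, y, RFConfig(n_trees=100, seed=0))
        frame = channel_importance(forest, ["fluorescence", "brightfield"])
        assert frame.loc[1, "importance"] < 1e-3

    def test_unmapped_features_rejected(self, separable_toy):
        X, y = separable_toy
        forest = train_rf(X, y, RFConfig(n_trees=10, seed=0))
        with pytest.raises(ValueError):
            channel_importance(forest, ["fluorescence"])


class TestGating:
    @pytest.fixture()
    def spec(self):
        return GateSpec({
            "apoptotic": {"mass": (10.0, 100.0), "area": (5.0, 50.0)},
            "ev": {"mass": (0.0, 12.0), "area": (0.0, 6.0)},
        })

    def test_cell_in_single_gate(self, spec):
        feats = pd.DataFrame({"mass": [5.0], "area": [2.0]})
        assert gate_classify(feats, spec).labels[0] == "ev"

    def test_cell_outside_both_gates_is_unknown(self, spec):
        feats = pd.DataFrame({"mass": [500.0], "area": [2.0]})
        assert gate_classify(feats, spec).labels[0] == "unknown"

    def test_overlap_resolved_to_apoptotic_and_counted(self, spec):
        feats = pd.DataFrame({"mass": [11.0], "area": [5.5]})
        res = gate_classify(feats, spec)
        assert res.labels[0] == "apoptotic"
        assert res.overlap_count == 1

    def test_bounds_closed_low_open_high(self, spec):
        feats = pd.DataFrame({"mass": [10.0, 100.0], "area": [25.0, 25.0]})
        res = gate_classify(feats, spec)
        assert res.labels[0] == "apoptotic"  # lower bound included
        assert res.labels[1] == "unknown"    # upper bound excluded

    def test_missing_feature_rejected(self, spec):
        with pytest.raises(KeyError):
            gate_classify(pd.DataFrame({"mass": [1.0]}), spec)


class TestModelResults:
    def test_fit_predict_summary(self, separable_toy):
        X, y = separable_toy
        model = CellSorter(X, y, feature_channel_map=["fluorescence",
                                                      "brightfield"],
                           config=RFConfig(n_trees=50, seed=0))
        results = model.fit()
        score = results.score(X, y)
        assert score["auc"] == 1.0
        assert score["accuracy_ci"][0] <= score["accuracy"]
        text = results.summary()
        assert "cae_rf" in text and "50" in text
        assert "fluorescence" in text
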