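"""Classifier: architecture arithmetic, splits, label randomization, training."""

import numpy as np
import pytest

from colonytda.classifier import (
    ModelSpec,
    TDANet,
    TrainingConfig,
    TrainingResult,
    build_tdanet,
    count_head_parameters,
    count_parameters,
    count_resnet18_parameters,
    predict,
    randomize_labels,
    split_train_val,
    train_model,
)


def toy_problem(n=20, d=6, n_classes=2, seed=0, separation=4.0):
    """Linearly separable blobs: class k centred at k*separation on axis 0."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n // n_classes)
    X = rng.normal(size=(y.size, d))
    X[:, 0] += separation * y
    return X, np.asarray([f"c{k}" for k in y])


class TestArchitecture:
    def test_standard_layer_sizes(self):
        assert build_tdanet(800, 5).layer_sizes == (800, 20, 20, 20, 5)
        assert build_tdanet(1600, 5).layer_sizes == (1600, 20, 20, 20, 5)
        assert build_tdanet(1, 2).layer_sizes == (1, 20, 20, 20, 2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_tdanet(0, 5)
        with pytest.raises(ValueError):
            ModelSpec((5,))

    def test_parameter_counts(self):
        assert count_parameters(build_tdanet(800, 5)) == 16_965
        assert count_parameters(build_tdanet(1600, 5)) == 32_965
        assert count_parameters(ModelSpec((1, 1))) == 2

    def test_head_parameter_counts(self):
        assert count_head_parameters(512, 5) == 2_565
        assert count_head_parameters(1, 1) == 2
        assert count_head_parameters(512, 1000) == 513_000

    def test_resnet18_with_5_class_head(self):
        assert count_resnet18_parameters(5) == 11_179_077
        # consistency: swapping heads accounts exactly for the difference
        assert count_resnet18_parameters(1000) - count_head_parameters(512, 1000) \
            == count_resnet18_parameters(5) - count_head_parameters(512, 5)


class TestSplit:
    def test_ceiling_rule_on_77_colonies(self):
        train, val = split_train_val(77, 0.70, seed=0)
        assert train.size == 54 and val.size == 23  # ceil(0.7 * 77) = 54

    def test_even_split(self):
        train, val = split_train_val(10, 0.5, seed=1)
        assert train.size == val.size == 5

    def test_disjoint_exhaustive_and_deterministic(self):
        a = split_train_val(31, 0.7, seed=42)
        b = split_train_val(31, 0.7, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert set(a[0]) & set(a[1]) == set()
        assert sorted(set(a[0]) | set(a[1])) == list(range(31))

    def test_stratified_split_keeps_class_balance(self):
        labels = ["a"] * 10 + ["b"] * 10
        train, val = split_train_val(20, 0.7, seed=0, labels=labels)
        assert sum(i < 10 for i in train) == 7 and sum(i >= 10 for i in train) == 7

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(2, 0.9, seed=0)


class TestRandomizeLabels:
    def test_deterministic(self):
        labels = {f"c{i}": "WT" for i in range(30)}
        classes = ["A", "B", "C", "D", "E"]
        assert randomize_labels(labels, classes, 7) == randomize_labels(labels, classes, 7)

    def test_approximately_uniform(self):
        labels = {f"c{i}": "WT" for i in range(5000)}
        out = randomize_labels(labels, ["A", "B", "C", "D", "E"], seed=3)
        counts = np.asarray([sum(v == c for v in out.values()) for c in "ABCDE"])
        assert np.all(np.abs(counts / 5000 - 0.2) < 0.03)

    def test_chance_level_against_fresh_uniform_labels(self):
        """Any fixed prediction scores ~1/5 against i.i.d. uniform relabelings."""
        rng = np.random.default_rng(0)
        preds = np.asarray(["A"] * 50)
        hits = []
        for draw in range(1000):
            fresh = randomize_labels(preds.tolist(), ["A", "B", "C", "D", "E"], seed=draw)
            hits.append((preds == fresh).mean())
        assert np.mean(hits) == pytest.approx(0.2, abs=0.01)


class TestTraining:
    def test_reproducible_given_seed(self):
        X, y = toy_problem(seed=5)
        cfg = TrainingConfig(max_epochs=40, seed=3)
        r1 = train_model(X, y, cfg)
        r2 = train_model(X, y, cfg)
        assert r1.best_val_accuracy == r2.best_val_accuracy
        assert all(np.array_equal(w1, w2) and np.array_equal(b1, b2)
                   for (w1, b1), (w2, b2) in zip(r1.params, r2.params))
        assert r1.history.equals(r2.history)

    def test_learns_separable_classes(self):
        X, y = toy_problem(n=40, seed=1, separation=8.0)
        result = train_model(X, y, TrainingConfig(max_epochs=200, seed=0))
        assert result.best_val_accuracy >= 0.9

    def test_overfit_memorizes_training_set(self):
        X, y = toy_problem(n=10, d=4, seed=2, separation=1.0)
        result = train_model(X, y, TrainingConfig(max_epochs=400, patience=400, seed=0))
        train_pred = result.predict(X[result.train_idx])
        assert np.mean(train_pred == y[result.train_idx]) == 1.0

    def test_best_checkpoint_is_argmax_of_history(self):
        X, y = toy_problem(n=30, seed=3)
        result = train_model(X, y, TrainingConfig(max_epochs=60, patience=3, seed=1))
        hist = result.history
        assert result.best_val_accuracy == hist["val_accuracy"].max()
        assert hist.loc[hist["epoch"] == result.best_epoch, "val_accuracy"].iloc[0] \
            == result.best_val_accuracy

    def test_early_stopping_after_consecutive_decreases(self):
        X, y = toy_problem(n=30, seed=4)
        cfg = TrainingConfig(max_epochs=500, patience=2, seed=7)
        result = train_model(X, y, cfg)
        va = result.history["val_accuracy"].to_numpy()
        if len(va) < cfg.max_epochs:  # stopped early: last `patience` steps all decreased
            assert all(va[-k] < va[-k - 1] for k in range(1, cfg.patience + 1))

    def test_single_class_training_split_rejected(self):
        X = np.random.default_rng(0).normal(size=(3, 3))
        y = np.asarray(["a", "a", "b"])
        # find a seed whose randomized split leaves only class "a" in training
        for seed in range(50):
            train_idx, _ = split_train_val(3, 0.66, seed)
            if set(y[train_idx]) == {"a"}:
                break
        else:
            pytest.fail("no degenerate split found in seed range")
        with pytest.raises(ValueError, match="single class|degenerate"):
            TDANet(X, y, config=TrainingConfig(train_fraction=0.66, seed=seed)).fit()


@pytest.fixture(scope="module")
def fitted():
    X, y = toy_problem(n=20, seed=6)
    return train_model(X, y, TrainingConfig(max_epochs=50, seed=0)), X


class TestPrediction:

    def test_probabilities_sum_to_one(self, fitted):
        result, X = fitted
        probs = predict(result, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_identical_inputs_identical_outputs(self, fitted):
        result, X = fitted
        assert np.array_equal(predict(result, X[:3]), predict(result, X[:3]))

    def test_shape_mismatch_rejected(self, fitted):
        result, _ = fitted
        with pytest.raises(ValueError):
            result.predict_proba(np.zeros((2, 99)))

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        result, X = fitted
        path = tmp_path / "model.json"
        result.save(path)
        loaded = TrainingResult.load(path)
        assert np.allclose(loaded.predict_proba(X), result.predict_proba(X))
        assert loaded.classes == result.classes

    def test_summary_mentions_architecture(self, fitted):
        result, _ = fitted
        text = result.summary()
        assert "best val accuracy" in text and "20 -> 20 -> 20" in text
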