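"""Classifier: shape arithmetic, training behavior, metrics formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from henspec import cnn
from henspec.cnn import (
    ClassificationReport,
    ModelConfig,
    ShapeError,
    TrainConfig,
    build_model,
    evaluate_report,
    predict,
    shape_trace,
    trace_layers,
    train,
)
from henspec.dataset import FeatureDataset

SMALL_CFG = ModelConfig(input_shape=(24, 64, 1))


def _blob_dataset(n_per_class, shape=(24, 64), sep=3.0, seed=0):
    """Two well-separated Gaussian-blob classes of feature maps."""
    rng = np.random.default_rng(seed)
    base = rng.random(shape)
    a = base[None] + rng.normal(0, 0.3, (n_per_class, *shape))
    b = base[None] + sep + rng.normal(0, 0.3, (n_per_class, *shape))
    feats = np.concatenate([a, b])
    labels = np.array(["normal"] * n_per_class + ["abnormal"] * n_per_class)
    perm = rng.permutation(2 * n_per_class)
    return FeatureDataset(features=feats[perm], labels=labels[perm])


class TestShapeTrace:
    def test_reference_stack_on_200_by_300(self):
        trace = dict(shape_trace(ModelConfig(), (200, 300, 1)))
        assert trace["conv1"] == (66, 300, 8)
        assert trace["pool1"] == (33, 150, 8)
        assert trace["conv2"] == (33, 150, 32)
        assert trace["pool2"] == (16, 74, 32)
        assert trace["flatten"] == (37888,)
        assert trace["dense"] == (2,)

    def test_agrees_with_instantiated_model(self):
        """The arithmetic trace matches the real forward pass layer-by-layer."""
        model = build_model(ModelConfig(), seed=0)
        trace = shape_trace(ModelConfig(), (200, 300, 1))
        x = np.random.default_rng(1).random((1, 200, 300, 1)).astype(cnn.DTYPE)
        spatial = iter([s for name, s in trace if name.startswith(("conv", "pool"))])
        for layer in model.layers:
            x = layer.forward(x)
            if isinstance(layer, (cnn._Conv2D, cnn._MaxPool2D)):
                assert x.shape[1:] == next(spatial)
        assert x.shape[1:] == trace[-1][1]  # dense output

    def test_single_window_input(self):
        conv1_spec = ModelConfig().layer_specs()[:1]
        assert trace_layers(conv1_spec, (3, 1, 1)) == [("conv1", (1, 1, 8))]

    def test_too_small_input_names_layer(self):
        with pytest.raises(ShapeError, match="conv1"):
            shape_trace(ModelConfig(), (2, 2, 1))
        with pytest.raises(ShapeError, match="pool2"):
            shape_trace(ModelConfig(), (9, 4, 1))

    def test_empty_layer_list_is_identity(self):
        assert trace_layers([], (5, 6, 7)) == []

    def test_spatial_dims_monotone_nonincreasing(self):
        dims = [(200, 300)] + [
            s[:2] for name, s in shape_trace(ModelConfig(), (200, 300, 1))
            if name.startswith(("conv", "pool"))
        ]
        for (h0, w0), (h1, w1) in zip(dims, dims[1:]):
            assert h1 <= h0 and w1 <= w0

    def test_build_rejects_too_small_input(self):
        with pytest.raises(ShapeError):
            build_model(ModelConfig(input_shape=(2, 2, 1)))


class TestTraining:
    def test_history_lengths_match_epochs(self):
        ds = _blob_dataset(8)
        tr = FeatureDataset(ds.features[:12], ds.labels[:12])
        va = FeatureDataset(ds.features[12:], ds.labels[12:])
        model = build_model(SMALL_CFG, seed=0)
        hist = train(model, tr, va, TrainConfig(epochs=4, seed=1))
        assert len(hist.train_loss) == len(hist.val_acc) == 4

    def test_learns_separable_classes(self):
        """On well-separated synthetic maps the net reaches >= 0.95 train
        accuracy within 30 epochs, with decreasing loss trend."""
        ds = _blob_dataset(24, seed=5)
        tr = FeatureDataset(ds.features[:36], ds.labels[:36])
        va = FeatureDataset(ds.features[36:], ds.labels[36:])
        model = build_model(SMALL_CFG, seed=2)
        hist = train(model, tr, va, TrainConfig(epochs=30, seed=3))
        assert hist.train_acc[-1] >= 0.95
        assert np.mean(hist.train_loss[-5:]) < np.mean(hist.train_loss[:5])

    def test_bitwise_deterministic_history(self):
        ds = _blob_dataset(8, seed=9)
        tr = FeatureDataset(ds.features[:12], ds.labels[:12])
        va = FeatureDataset(ds.features[12:], ds.labels[12:])
        runs = []
        for _ in range(2):
            model = build_model(SMALL_CFG, seed=4)
            runs.append(train(model, tr, va, TrainConfig(epochs=3, seed=5)))
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_acc == runs[1].val_acc

    def test_shape_mismatch_rejected(self):
        ds = _blob_dataset(4, shape=(10, 10))
        model = build_model(SMALL_CFG, seed=0)
        with pytest.raises(ShapeError):
            train(model, ds, ds, TrainConfig(epochs=1))

    def test_save_load_round_trip(self, tmp_path):
        ds = _blob_dataset(6, seed=2)
        model = build_model(SMALL_CFG, seed=1)
        train(model, ds, ds, TrainConfig(epochs=2, seed=2), out_dir=tmp_path / "m")
        back = cnn.SmallScalogramCNN.load(tmp_path / "m")
        l1, p1 = predict(model, ds)
        l2, p2 = predict(back, ds)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestPredict:
    def _trained(self):
        ds = _blob_dataset(6, seed=3)
        model = build_model(SMALL_CFG, seed=0)
        train(model, ds, ds, TrainConfig(epochs=2, seed=1))
        return model, ds

    def test_probabilities_normalized_and_argmax(self):
        model, ds = self._trained()
        labels, probs = predict(model, ds)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, model.classes_[probs.argmax(axis=1)])

    def test_deterministic_given_weights(self):
        model, ds = self._trained()
        _, p1 = predict(model, ds)
        _, p2 = predict(model, ds)
        np.testing.assert_array_equal(p1, p2)


class TestEvaluateReport:
    def test_perfect_predictions(self):
        r = evaluate_report(["a", "n", "a", "n"], ["a", "n", "a", "n"])
        assert r.accuracy == 1.0
        assert all(v == 1.0 for v in r.precision.values())
        assert r.macro_avg["f1"] == 1.0

    def test_f1_harmonic_mean_closed_form(self):
        # Class "a": precision 0.5, recall 1.0 -> F1 = 2/3.
        r = evaluate_report(["a", "n"], ["a", "a"])
        assert r.precision["a"] == pytest.approx(0.5)
        assert r.recall["a"] == pytest.approx(1.0)
        assert r.f1["a"] == pytest.approx(2 / 3)

    def test_hand_counted_confusion_matrix(self):
        truth = ["A", "A", "A", "N", "N"]
        pred = ["A", "A", "N", "N", "N"]
        r = evaluate_report(truth, pred)
        assert r.precision["A"] == pytest.approx(1.0)
        assert r.recall["A"] == pytest.approx(2 / 3)
        assert r.f1["A"] == pytest.approx(0.8)
        assert r.accuracy == pytest.approx(0.8)
        assert r.support == {"A": 3, "N": 2}

    def test_never_predicted_class_zero_precision(self):
        r = evaluate_report(["a", "n"], ["n", "n"])
        assert r.precision["a"] == 0.0 and r.recall["a"] == 0.0 and r.f1["a"] == 0.0

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["a", "n"], 200)
        pred = rng.choice(["a", "n"], 200)
        r = evaluate_report(truth, pred)
        assert r.weighted_avg["recall"] == pytest.approx(r.accuracy)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        truth = rng.choice(["a", "n"], 100)
        pred = rng.choice(["a", "n"], 100)
        r1 = evaluate_report(truth, pred)
        swap = {"a": "n", "n": "a"}
        r2 = evaluate_report([swap[t] for t in truth], [swap[p] for p in pred])
        assert r1.accuracy == pytest.approx(r2.accuracy)
        assert r1.macro_avg["f1"] == pytest.approx(r2.macro_avg["f1"])
        assert r1.precision["a"] == pytest.approx(r2.precision["n"])
        assert r1.recall["n"] == pytest.approx(r2.recall["a"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_f1_between_precision_and_recall(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        truth = rng.choice(["a", "n"], n)
        pred = rng.choice(["a", "n"], n)
        r = evaluate_report(truth, pred, classes=["a", "n"])
        for c in ("a", "n"):
            p, rec, f1 = r.precision[c], r.recall[c], r.f1[c]
            assert min(p, rec) - 1e-12 <= f1 <= max(p, rec) + 1e-12
            if p == rec:
                assert f1 == pytest.approx(p)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_report(["a"], ["a", "n"])

    def test_report_frame_layout(self):
        frame = evaluate_report(["a", "n"], ["a", "n"]).to_frame()
        assert list(frame.index) == ["precision", "recall", "f1-score"]
        assert list(frame.columns) == ["a", "n", "macro avg", "weighted avg"]
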