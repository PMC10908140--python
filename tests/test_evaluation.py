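"""Metrics vs an independent reference, confusion-matrix orientation,
stratified cross-validation, report schema, and Grad-CAM."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from capseeg.data import SegmentSet
from capseeg.evaluation import (ConfusionMatrix, confusion, cross_validate,
                                gradcam_1d, metrics, report)
from capseeg.nn.autograd import Tensor, conv1d_same

from conftest import make_segments


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion([1, 2, 3, 1], [1, 2, 3, 1])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_hand_tally_orientation(self):
        """pred (1,0,1,1) vs actual (1,0,0,1): TP=2, TN=1, FP=1, FN=0,
        with predicted classes on rows and actual on columns."""
        cm = confusion([1, 0, 1, 1], [1, 0, 0, 1])
        # row 0 = predicted 0: [TN, FN]; row 1 = predicted 1: [FP, TP]
        assert np.array_equal(cm.counts, [[1, 0], [1, 2]])

    def test_empty_inputs_zero_matrix(self):
        cm = confusion([], [])
        assert cm.counts.size == 0 and cm.n == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 2], [1])

    def test_label_outside_class_set(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([1, 9], [1, 1], labels=[0, 1])

    def test_serialized_axes_labelled(self):
        d = confusion([0, 1], [0, 1]).to_dict()
        assert d["rows"] == "predicted" and d["columns"] == "actual"


class TestMetrics:
    def test_hand_case(self):
        cm = ConfusionMatrix(counts=np.array([[40, 5], [5, 50]]),
                             labels=np.array([0, 1]))
        fr = metrics(cm)
        assert fr.accuracy == pytest.approx(0.90)
        assert fr.precision[1] == pytest.approx(50 / 55)
        assert fr.recall[1] == pytest.approx(50 / 55)
        assert fr.f1[1] == pytest.approx(50 / 55)
        assert fr.support.tolist() == [45, 55]

    def test_perfect_predictions_all_ones(self):
        fr = metrics(confusion([1, 2, 2], [1, 2, 2]))
        assert fr.accuracy == 1.0
        assert np.all(fr.precision == 1) and np.all(fr.recall == 1)
        assert np.all(fr.f1 == 1)

    def test_degenerate_no_positive_predictions(self):
        fr = metrics(confusion([0, 0, 0], [0, 1, 1], labels=[0, 1]))
        assert fr.precision[1] == 0.0
        assert fr.recall[1] == 0.0
        assert 1 in fr.degenerate["precision"]

    def test_agrees_with_sklearn_on_random_matrices(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 12, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            pred, actual = [], []
            for i in range(k):
                for j in range(k):
                    pred += [i] * counts[i, j]
                    actual += [j] * counts[i, j]
            fr = metrics(ConfusionMatrix(counts=counts,
                                         labels=np.arange(k)))
            p, r, f, s = precision_recall_fscore_support(
                actual, pred, labels=np.arange(k), zero_division=0)
            acc = (np.array(pred) == np.array(actual)).mean()
            assert abs(fr.accuracy - acc) < 1e-12
            assert np.abs(fr.precision - p).max() < 1e-12
            assert np.abs(fr.recall - r).max() < 1e-12
            assert np.abs(fr.f1 - f).max() < 1e-12
            assert np.array_equal(fr.support, s)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(counts=np.zeros((2, 2), dtype=int),
                                    labels=np.array([0, 1])))


class _MajorityClassifier:
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.c = vals[counts.argmax()]
        return self

    def predict(self, X):
        return np.full(len(X), self.c)


class TestCrossValidate:
    def test_majority_classifier_closed_form(self, rng):
        """Stratified folds each hold the global 90/10 split, so a
        majority-class predictor scores 0.9 on every fold."""
        x = rng.normal(size=(200, 4))
        y = np.r_[np.zeros(180, dtype=int), np.ones(20, dtype=int)]
        s = make_segments(x, y, "binary")
        mean, sd, scores = cross_validate(_MajorityClassifier, s, k=10, seed=0)
        assert mean == pytest.approx(0.9, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(scores) == 10

    def test_class_smaller_than_k_rejected(self, rng):
        s = make_segments(rng.normal(size=(12, 3)),
                          [0] * 9 + [1] * 3, "binary")
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(_MajorityClassifier, s, k=5)

    def test_leave_one_out_fold_count(self, rng):
        s = make_segments(rng.normal(size=(20, 3)),
                          [0, 1] * 10, "binary")
        _, _, scores = cross_validate(_MajorityClassifier, s, k=10, seed=0)
        assert len(scores) == 10


class TestReport:
    def test_schema_and_rounding(self):
        fr = metrics(confusion([0, 1, 1, 0], [0, 1, 0, 0]))
        fr.cv_mean, fr.cv_sd = 0.87654, 0.0123
        fr.fold_scores = np.array([0.87, 0.88])
        df = report([{"model": "cnn_caps", "condition": "scaling",
                      "fit_report": fr}])
        assert {"model", "condition", "accuracy_pct", "cv_mean_pct",
                "cv_sd_pct"} <= set(df.columns)
        assert df.loc[0, "accuracy_pct"] == 75.0
        assert df.loc[0, "cv_mean_pct"] == 87.65

    def test_files_written(self, tmp_path):
        fr = metrics(confusion([0, 1], [0, 1]))
        report([{"model": "m", "fit_report": fr}],
               csv_path=tmp_path / "r.csv", json_path=tmp_path / "r.json")
        assert (tmp_path / "r.csv").exists()
        assert (tmp_path / "r.json").exists()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            report([])


class _TinyConvNet:
    """Two-channel conv net with a hand-computable Grad-CAM.

    Channel 0 is the identity kernel, channel 1 twice the identity; the
    class score is h . sum_t A, so dscore/dA_k = h_k everywhere and the raw
    saliency map is ReLU((h0 + 2*h1) * x).
    """

    def __init__(self, h=(1.0, 0.5)):
        self.h = np.asarray(h)
        w = np.zeros((2, 1, 3))
        w[0, 0, 1] = 1.0
        w[1, 0, 1] = 2.0
        self.w = Tensor(w)
        self.b = Tensor(np.zeros(2))
        self.extractor = self
        self.conv_names = ["conv"]
        self.activations = {}

    def eval(self):
        return self

    def zero_grad(self):
        pass

    def forward(self, x):
        a = conv1d_same(Tensor(np.asarray(x)[:, None, :],
                               requires_grad=True), self.w, self.b)
        self.activations = {"conv": a}
        score = (a * Tensor(self.h[None, :, None])).sum(
            axis=2).sum(axis=1).reshape(1, 1)
        return score


class TestGradCam:
    def test_analytic_tiny_network(self, rng):
        x = rng.normal(size=24)
        sm = gradcam_1d(_TinyConvNet(), x, class_index=0, layer="conv")
        expected = np.maximum((1.0 * 1 + 0.5 * 2) * x, 0.0)
        expected /= expected.max()
        assert np.allclose(sm.importance, expected, atol=1e-10)

    def test_map_length_and_range(self, rng):
        from capseeg.architectures import build_model
        from test_architectures import tiny_spec
        model = build_model(tiny_spec("cnn_fully", n_classes=2)).eval()
        x = rng.normal(size=178)
        sm = gradcam_1d(model, x, class_index=1, layer="block3_conv2")
        assert sm.importance.shape == (178,)
        assert sm.importance.min() >= 0.0 and sm.importance.max() <= 1.0

    def test_unknown_layer_lists_available(self, rng):
        from capseeg.architectures import build_model
        from test_architectures import tiny_spec
        model = build_model(tiny_spec("cnn_fully", n_classes=2)).eval()
        with pytest.raises(ValueError, match="block1_conv1"):
            gradcam_1d(model, rng.normal(size=178), 0, "nope")

    def test_csv_export(self, tmp_path, rng):
        sm = gradcam_1d(_TinyConvNet(), rng.normal(size=10), 0, "conv")
        sm.to_csv(tmp_path / "sal.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "sal.csv")
        assert list(df.columns) == ["position", "importance"]
        assert len(df) == 10
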