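"""Metrics, confusion matrices, stratified cross-validation, report tables,
and 1-D Grad-CAM saliency.

Metric definitions, from the confusion-matrix cells (TP, TN, FP, FN):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

For multiclass, precision/recall/F1 are computed one-vs-rest per class, and
macro averages are reported alongside.  Cross-validation is the mean (and
sd) of a per-fold performance over k stratified folds.

Convention note: the confusion matrix here is oriented with *predicted*
classes on the rows and *actual* classes on the columns — the transpose of
the common convention — and the serialized form labels both axes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import SegmentSet
from .nn.autograd import Tensor


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples predicted as class i with actual
    class j (predicted rows x actual columns)."""

    counts: np.ndarray
    labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"rows": "predicted", "columns": "actual",
                "labels": self.labels.tolist(), "counts": self.counts.tolist()}


@dataclass
class FitReport:
    """Per-class and aggregate classification metrics."""

    accuracy: float
    labels: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    degenerate: dict = field(default_factory=dict)
    cv_mean: float | None = None
    cv_sd: float | None = None
    fold_scores: np.ndarray | None = None

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_json(self) -> str:
        d = {"accuracy": self.accuracy, "labels": self.labels.tolist(),
             "precision": self.precision.tolist(),
             "recall": self.recall.tolist(), "f1": self.f1.tolist(),
             "support": self.support.tolist(),
             "macro_precision": self.macro_precision,
             "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
             "degenerate": {k: sorted(v) for k, v in self.degenerate.items()}}
        if self.cv_mean is not None:
            d["cv_mean"] = self.cv_mean
            d["cv_sd"] = self.cv_sd
            d["fold_scores"] = self.fold_scores.tolist()
        return json.dumps(d, indent=2)


def confusion(pred, actual, labels=None) -> ConfusionMatrix:
    pred = np.asarray(pred)
    actual = np.asarray(actual)
    if pred.shape != actual.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs "
            f"{actual.shape[0]} actual labels"
        )
    if labels is None:
        labels = np.unique(np.concatenate([pred, actual])) if pred.size else np.array([])
    labels = np.asarray(labels)
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for p, a in zip(pred, actual):
        if p not in index or a not in index:
            raise ValueError(f"label outside class set: pred={p}, actual={a}")
        counts[index[p], index[a]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def metrics(cm: ConfusionMatrix) -> FitReport:
    """Accuracy plus one-vs-rest precision/recall/F1/support per class.

    Degenerate ratios (zero denominators) are reported as 0 and flagged in
    ``report.degenerate`` under the metric name.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    accuracy = float(np.trace(counts)) / total
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    support = counts.sum(axis=0)  # actual counts per class (columns)
    degenerate: dict = {"precision": set(), "recall": set(), "f1": set()}
    for i in range(k):
        tp = counts[i, i]
        fp = counts[i, :].sum() - tp  # predicted i, actually something else
        fn = counts[:, i].sum() - tp  # actually i, predicted something else
        if tp + fp == 0:
            degenerate["precision"].add(cm.labels[i].item())
        else:
            precision[i] = tp / (tp + fp)
        if tp + fn == 0:
            degenerate["recall"].add(cm.labels[i].item())
        else:
            recall[i] = tp / (tp + fn)
        if precision[i] + recall[i] == 0:
            degenerate["f1"].add(cm.labels[i].item())
        else:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])
    return FitReport(accuracy=accuracy, labels=cm.labels, precision=precision,
                     recall=recall, f1=f1, support=support,
                     degenerate={m: s for m, s in degenerate.items() if s})


def cross_validate(model_factory, s: SegmentSet, k: int = 10, seed: int = 0):
    """Stratified k-fold cross-validation of accuracy.

    ``model_factory()`` must return a fresh estimator with sklearn-style
    ``fit(X, y)`` / ``predict(X)``.  Returns ``(cv_mean, cv_sd,
    fold_scores)``: the mean over folds of the per-fold accuracy, its
    standard deviation, and the individual fold scores.
    """
    counts = s.class_counts()
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(s.signals, s.labels):
        est = model_factory()
        est.fit(s.signals[train_idx], s.labels[train_idx])
        pred = est.predict(s.signals[test_idx])
        scores.append(float((pred == s.labels[test_idx]).mean()))
    scores = np.array(scores)
    return float(scores.mean()), float(scores.std(ddof=0)), scores


def report(results: list, csv_path=None, json_path=None) -> pd.DataFrame:
    """Tabulate run results with the comparison-table column layout.

    Each entry of `results` is a dict with keys ``model``, ``condition``
    (optional), and a :class:`FitReport` under ``fit_report``.  Percentages
    are rendered to two decimals.
    """
    if not results:
        raise ValueError("at least one result required")
    rows = []
    for res in results:
        fr: FitReport = res["fit_report"]
        row = {"model": res["model"],
               "condition": res.get("condition", "any"),
               "accuracy_pct": round(100 * fr.accuracy, 2)}
        if fr.cv_mean is not None:
            row["cv_mean_pct"] = round(100 * fr.cv_mean, 2)
            row["cv_sd_pct"] = round(100 * fr.cv_sd, 2)
        for lab, prec in zip(fr.labels, fr.precision):
            row[f"precision_{lab}_pct"] = round(100 * prec, 2)
        if res.get("missing"):
            row["missing"] = True
        rows.append(row)
    df = pd.DataFrame(rows)
    if csv_path:
        df.to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2, default=str)
    return df


@dataclass
class SaliencyMap:
    """Per-input-position importance, aligned to the input segment."""

    importance: np.ndarray
    layer: str
    class_index: int

    def to_csv(self, path) -> None:
        pd.DataFrame({"position": np.arange(len(self.importance)),
                      "importance": self.importance}).to_csv(path, index=False)


def gradcam_1d(model, segment, class_index: int, layer: str) -> SaliencyMap:
    """Gradient-weighted class activation map for one segment.

    The class score (pre-softmax logit) is differentiated with respect to
    the named convolutional layer's feature maps A_k; the per-channel
    weights w_k are the time-averages of those gradients, the raw map is
    ReLU(Σ_k w_k A_k), linearly upsampled to the input length and normalized
    to [0, 1] when its maximum is positive.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    model.eval()
    logits = model.forward(segment[None, :])
    extractor = model.extractor
    if layer not in extractor.activations:
        raise ValueError(
            f"unknown layer {layer!r}; available: {', '.join(extractor.conv_names)}"
        )
    n_classes = logits.shape[1]
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} outside 0..{n_classes - 1}")
    onehot = np.zeros_like(logits.data)
    onehot[0, class_index] = 1.0
    logits.backward(onehot)
    act = extractor.activations[layer]
    a = act.data[0]            # [C, L']
    g = act.grad[0]            # [C, L']
    w = g.mean(axis=1)         # time-averaged gradient per channel
    raw = np.maximum((w[:, None] * a).sum(axis=0), 0.0)  # [L']
    x_src = np.linspace(0.0, 1.0, num=raw.shape[0])
    x_dst = np.linspace(0.0, 1.0, num=segment.shape[0])
    up = np.interp(x_dst, x_src, raw)
    if up.max() > 0:
        up = up / up.max()
    model.zero_grad()
    return SaliencyMap(importance=up, layer=layer, class_index=class_index)
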