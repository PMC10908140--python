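"""The five model variants: a shared 1-D CNN feature extractor feeding a
dense, capsule, or transformer-encoder head (or their combinations).

The extractor is six convolutional blocks — (2x32, 2x64, 3x128, 3x256,
3x512, 3x512) kernel-3 length-preserving convolutions with SELU — each block
closed by a size-2 floor-mode max-pool and dropout 0.5.  A 178-sample
segment leaves the stack as a (2, 512) feature map; a 40-component PCA
input leaves it as (1, 512) because a pool that would shrink the map below
one step is skipped.

Variants:

- ``cnn_fully``    extractor -> global-max-pool -> dense stack (1024..16) -> softmax
- ``cnn_caps``     extractor -> capsule head with routing-by-agreement
- ``cnn_tf``       extractor -> transformer encoder (16 heads, 2 layers) -> pooled softmax
- ``cnn_tf_fully`` extractor -> transformer (16 heads, 1 layer) -> dense stack
- ``cnn_tf_caps``  extractor -> transformer (8 heads, 1 layer) -> capsule head

Training uses Adam(lr=0.001), batch size 128, 500 epochs by default (the
published protocol); tests and examples run scaled-down copies via
:meth:`ArchitectureSpec.scaled`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import SegmentSet
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (BatchNorm1d, CapsuleHead, ChannelBatchNorm, Conv1d,
                        Dense, Dropout, Module, TransformerBlock,
                        _BatchNormBase)
from .nn.optim import Adam

logger = logging.getLogger("capseeg")

VARIANTS = ("cnn_fully", "cnn_caps", "cnn_tf", "cnn_tf_fully", "cnn_tf_caps")

DEFAULT_CONV_PLAN = ((2, 32), (2, 64), (3, 128), (3, 256), (3, 512), (3, 512))
DEFAULT_DENSE_WIDTHS = (1024, 512, 256, 128, 128, 64, 32, 16)

# head hyperparameters of the published configuration, per variant
_HEAD_DEFAULTS = {
    "cnn_fully": {},
    "cnn_caps": {"num_caps": 16},
    "cnn_tf": {"n_heads": 16, "n_layers": 2},
    "cnn_tf_fully": {"n_heads": 16, "n_layers": 1},
    "cnn_tf_caps": {"n_heads": 8, "n_layers": 1, "num_caps": 16},
}


@dataclass
class ArchitectureSpec:
    """Declarative description of one model variant.

    ``num_caps`` is the capsule width (both the primary-capsule dimension
    d_in and the class-capsule dimension d_out default to it).
    """

    variant: str = "cnn_fully"
    input_len: int = 178
    n_classes: int = 5
    conv_plan: tuple = DEFAULT_CONV_PLAN
    kernel: int = 3
    dropout: float = 0.5
    dense_widths: tuple = DEFAULT_DENSE_WIDTHS
    n_heads: int = 16
    n_layers: int = 1
    num_caps: int = 16
    capsule_d_out: int = None
    routing_iters: int = 3
    mlp_ratio: int = 4
    positional_encoding: bool = False
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 128
    loss: str = "cross_entropy"  # or "margin" for the capsule margin loss
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        channels = [c for _, c in self.conv_plan]
        if any(b > a for a, b in zip(channels[1:], channels)):
            raise ValueError("conv_plan channel widths must be non-decreasing")
        if self.capsule_d_out is None:
            self.capsule_d_out = self.num_caps

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "ArchitectureSpec":
        """Spec with the published head hyperparameters for `variant`."""
        kw = dict(_HEAD_DEFAULTS[variant])
        kw.update(overrides)
        return cls(variant=variant, **kw)

    def scaled(self, factor: int = 8, min_width: int = 4) -> "ArchitectureSpec":
        """Copy with conv channels divided by `factor` (dense widths are
        cheap and stay as stated).  Used for desk-scale training; head
        hyperparameters that must divide the reduced model width are
        clipped accordingly.
        """
        plan = tuple((n, max(min_width, c // factor)) for n, c in self.conv_plan)
        d_model = plan[-1][1]
        return dataclasses.replace(self, conv_plan=plan,
                                   n_heads=min(self.n_heads, d_model))

    @property
    def feature_channels(self) -> int:
        return self.conv_plan[-1][1]

    def feature_len(self) -> int:
        """Time length of the extractor output under the pooling guard."""
        t = self.input_len
        for _ in self.conv_plan:
            if t >= 2:
                t //= 2
        return t


class FeatureExtractor(Module):
    """Six-block conv stack; exposes per-conv-layer activations for Grad-CAM."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.blocks = []
        self.conv_names: list[str] = []
        c_in = 1
        for bi, (n_convs, c_out) in enumerate(spec.conv_plan, start=1):
            convs = []
            for ci in range(1, n_convs + 1):
                conv = self.add_module(Conv1d(c_in, c_out, spec.kernel, rng))
                bn = self.add_module(ChannelBatchNorm(c_out))
                name = f"block{bi}_conv{ci}"
                self.conv_names.append(name)
                convs.append((name, conv, bn))
                c_in = c_out
            drop = self.add_module(Dropout(spec.dropout, rng))
            self.blocks.append((convs, drop))
        self.activations: dict[str, Tensor] = {}

    def forward(self, x: Tensor) -> Tensor:
        """[N, 1, L] -> [N, t, channels] feature map."""
        self.activations = {}
        for convs, drop in self.blocks:
            for name, conv, bn in convs:
                # per the conv-block equation: pool(f(norm(conv(x))))
                x = ag.selu(bn(conv(x)))
                self.activations[name] = x
            if x.shape[2] >= 2:
                x = ag.maxpool1d(x, 2)
            else:
                logger.warning(
                    "skipping max-pool: map length %d cannot be halved", x.shape[2]
                )
            x = drop(x)
        return x.transpose(0, 2, 1)  # [N, t, C]


class DenseHead(Module):
    """Global-max-pool over time, then the 1024..16 dense stack with
    batch-norm + SELU per layer, closed by an n_classes output layer."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.layers = []
        width = spec.feature_channels
        for w in spec.dense_widths:
            dense = self.add_module(Dense(width, w, rng))
            bn = self.add_module(BatchNorm1d(w))
            self.layers.append((dense, bn))
            width = w
        self.out = self.add_module(Dense(width, spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        x = x.max(axis=1)  # global max pool over time: [N, t, C] -> [N, C]
        for dense, bn in self.layers:
            x = ag.selu(bn(dense(x)))
        return self.out(x)


class PooledSoftmaxHead(Module):
    """Time-pooled linear classifier (the bare transformer-variant head)."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.out = self.add_module(Dense(spec.feature_channels, spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.out(x.max(axis=1))


def _sinusoidal_encoding(t: int, d: int) -> np.ndarray:
    pos = np.arange(t)[:, None]
    i = np.arange(d)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return enc


class SeizureClassifier(Module):
    """Full variant: extractor -> optional transformer stack -> head.

    ``forward`` maps raw segments [N, input_len] to class logits [N,
    n_classes]; for capsule heads the logits are the class-capsule lengths.
    """

    def __init__(self, spec: ArchitectureSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.extractor = self.add_module(FeatureExtractor(spec, rng))
        d_model = spec.feature_channels
        t = spec.feature_len()
        self.transformer_blocks = []
        if spec.variant in ("cnn_tf", "cnn_tf_fully", "cnn_tf_caps"):
            if d_model % spec.n_heads:
                raise ValueError(
                    f"model width {d_model} not divisible by n_heads {spec.n_heads}"
                )
            for _ in range(spec.n_layers):
                self.transformer_blocks.append(
                    self.add_module(TransformerBlock(d_model, spec.n_heads, rng,
                                                     spec.mlp_ratio)))
        if spec.variant in ("cnn_caps", "cnn_tf_caps"):
            self.head = self.add_module(
                CapsuleHead(t, d_model, spec.n_classes, rng,
                            d_in=spec.num_caps, d_out=spec.capsule_d_out,
                            r=spec.routing_iters))
        elif spec.variant in ("cnn_fully", "cnn_tf_fully"):
            self.head = self.add_module(DenseHead(spec, rng))
        else:  # cnn_tf
            self.head = self.add_module(PooledSoftmaxHead(spec, rng))
        self.classes_: np.ndarray | None = None

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        n, length = x.shape
        if length != self.spec.input_len:
            raise ValueError(
                f"input length {length} != spec input_len {self.spec.input_len}"
            )
        feats = self.extractor(x.reshape(n, 1, length))
        if self.transformer_blocks and self.spec.positional_encoding:
            feats = feats + Tensor(_sinusoidal_encoding(feats.shape[1],
                                                        feats.shape[2]))
        for block in self.transformer_blocks:
            feats = block(feats)
        return self.head(feats)

    # -- inference helpers --------------------------------------------------
    def predict_proba(self, x) -> np.ndarray:
        was_training = self.training
        self.eval()
        logits = self.forward(x).data
        if was_training:
            self.train()
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x) -> np.ndarray:
        idx = self.predict_proba(x).argmax(axis=1)
        if self.classes_ is not None:
            return self.classes_[idx]
        return idx


def build_feature_extractor(spec: ArchitectureSpec) -> FeatureExtractor:
    return FeatureExtractor(spec, np.random.default_rng(spec.seed))


def build_dense_head(spec: ArchitectureSpec) -> DenseHead:
    return DenseHead(spec, np.random.default_rng(spec.seed))


def build_model(spec: ArchitectureSpec) -> SeizureClassifier:
    return SeizureClassifier(spec)


def _margin_loss(lengths: Tensor, labels: np.ndarray, n_classes: int,
                 m_pos: float = 0.9, m_neg: float = 0.1,
                 lam: float = 0.5) -> Tensor:
    """Capsule margin loss on class-capsule lengths."""
    onehot = np.eye(n_classes)[labels]
    pos = (Tensor(m_pos) - lengths).relu().pow(2.0) * Tensor(onehot)
    neg = (lengths - Tensor(m_neg)).relu().pow(2.0) * Tensor(lam * (1 - onehot))
    return (pos + neg).sum() * (1.0 / lengths.shape[0])


def train(model: SeizureClassifier, train_set: SegmentSet,
          spec: ArchitectureSpec | None = None, epochs: int | None = None):
    """Mini-batch Adam training with cross-entropy (or margin) loss.

    Returns ``(model, history)`` where history maps ``"loss"`` and
    ``"accuracy"`` to per-epoch values.  Deterministic under the
    ArchitectureSpec seed.
    """
    spec = spec or model.spec
    n_epochs = spec.epochs if epochs is None else epochs
    classes = np.unique(train_set.labels)
    if len(classes) > spec.n_classes:
        raise ValueError(
            f"{len(classes)} classes in data exceed spec n_classes {spec.n_classes}"
        )
    model.classes_ = classes
    label_index = {c: i for i, c in enumerate(classes)}
    y = np.array([label_index[l] for l in train_set.labels])
    x = train_set.signals

    opt = Adam(model.parameters(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    history = {"loss": [], "accuracy": []}
    model.train()
    for epoch in range(n_epochs):
        order = rng.permutation(len(y))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(y), spec.batch_size):
            idx = order[start:start + spec.batch_size]
            logits = model.forward(x[idx])
            if spec.loss == "margin":
                loss = _margin_loss(logits, y[idx], spec.n_classes)
            else:
                loss = ag.cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}; "
                    "try a lower learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(epoch_loss / len(y))
        history["accuracy"].append(correct / len(y))
        logger.debug("epoch %d loss %.4f acc %.4f", epoch,
                     history["loss"][-1], history["accuracy"][-1])
    if n_epochs > 0:
        recalibrate_batchnorm(model, x, batch_size=spec.batch_size)
    model.eval()
    return model, history


def recalibrate_batchnorm(model: Module, x: np.ndarray,
                          batch_size: int = 128) -> None:
    """Re-estimate batch-norm running statistics with dropout disabled.

    Dropout interleaved with batch normalization makes the train-mode
    activation variance differ from the eval-mode one, so the running
    statistics tracked during training describe the wrong distribution.
    A post-training pass over the training inputs with frozen weights and
    dropout off replaces them with eval-consistent estimates.
    """
    bns = [m for m in _walk_modules(model) if isinstance(m, _BatchNormBase)]
    if not bns:
        return
    model.eval()  # dropout off
    for bn in bns:
        bn.start_collecting()
    for start in range(0, len(x), batch_size):
        model.forward(x[start:start + batch_size])
    for bn in bns:
        bn.stop_collecting()


def _walk_modules(m: Module):
    yield m
    for child in m._modules:
        yield from _walk_modules(child)


class NetClassifier:
    """sklearn-style ``fit``/``predict`` adapter around a variant spec.

    Lets the neural variants drop into the cross-validation and comparison
    machinery next to the classical estimators.
    """

    def __init__(self, spec: ArchitectureSpec, epochs: int | None = None):
        self.spec = spec
        self.epochs = epochs
        self.model: SeizureClassifier | None = None
        self.history = None

    def fit(self, X, y):
        scheme = "binary" if set(np.unique(y)) <= {0, 1} else "five_class"
        train_set = SegmentSet(signals=np.asarray(X), labels=np.asarray(y),
                               label_scheme=scheme)
        self.model = build_model(self.spec)
        self.model, self.history = train(self.model, train_set, self.spec,
                                         epochs=self.epochs)
        return self

    def predict(self, X):
        if self.model is None:
            raise RuntimeError("fit the classifier first")
        return self.model.predict(np.asarray(X))


def iterate_transformer_hparams(train_set: SegmentSet, test_set: SegmentSet,
                                heads_grid=(1, 2, 4, 8, 16),
                                layers_grid=(1, 2, 4, 8, 16),
                                variant: str = "cnn_tf",
                                base_spec: ArchitectureSpec | None = None,
                                epochs: int | None = None,
                                sort_by_accuracy: bool = False):
    """Train/evaluate every (heads, layers) combination; return result rows.

    Each row is ``{"variant", "num_heads", "num_layers", "accuracy"}`` with
    accuracy measured on `test_set`.
    """
    if not heads_grid or not layers_grid:
        raise ValueError("grids must be non-empty")
    base = base_spec or ArchitectureSpec.for_variant(variant)
    rows = []
    for h in heads_grid:
        for l in layers_grid:
            spec = dataclasses.replace(base, variant=variant, n_heads=h,
                                       n_layers=l)
            model = build_model(spec)
            model, _ = train(model, train_set, spec, epochs=epochs)
            acc = float((model.predict(test_set.signals) == test_set.labels).mean())
            rows.append({"variant": variant, "num_heads": h, "num_layers": l,
                         "accuracy": acc})
    if sort_by_accuracy:
        rows.sort(key=lambda r: -r["accuracy"])
    return rows
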