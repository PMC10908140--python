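"""Trainable layers over the autodiff engine.

Every layer is a :class:`Module` owning parameter Tensors; composition
happens in :mod:`capseeg.architectures`.  Initialization follows the LeCun
normal convention (std = 1/sqrt(fan_in)), which is the standard pairing for
SELU networks.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .functional import EPS


class Module:
    def __init__(self):
        self._params: list[Tensor] = []
        self._modules: list[Module] = []
        self.training = True

    def param(self, arr) -> Tensor:
        t = Tensor(np.asarray(arr, dtype=float), requires_grad=True)
        self._params.append(t)
        return t

    def add_module(self, m: "Module") -> "Module":
        self._modules.append(m)
        return m

    def parameters(self):
        for p in self._params:
            yield p
        for m in self._modules:
            yield from m.parameters()

    def train(self, flag: bool = True):
        self.training = flag
        for m in self._modules:
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x):
        return self.forward(x)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.param(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)))
        self.b = self.param(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Length-preserving 1-D convolution, kernel size 3 by default."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel
        self.w = self.param(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                       (c_out, c_in, kernel)))
        self.b = self.param(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv1d_same(x, self.w, self.b)


class _BatchNormBase(Module):
    """Shared batch-norm machinery.

    Training uses batch statistics (gradients flow through them) and tracks
    running estimates with momentum 0.1; evaluation normalizes with the
    running estimates.  A separate *collecting* mode supports post-training
    re-estimation of the running statistics: dropout interleaved with
    batch-norm shifts the activation variance between train- and eval-mode
    forwards, so after training the statistics are recomputed over the
    training data with dropout disabled (cf. the re-estimation pass used
    with stochastic weight averaging).
    """

    def __init__(self, shape: tuple, axes: tuple, momentum: float,
                 epsilon: float):
        super().__init__()
        self.gamma = self.param(np.ones(shape))
        self.beta = self.param(np.zeros(shape))
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)
        self.momentum = momentum
        self.epsilon = epsilon
        self.axes = axes
        self.collecting = False
        self._n_collected = 0

    def start_collecting(self):
        self.collecting = True
        self._n_collected = 0
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)

    def stop_collecting(self):
        self.collecting = False

    def forward(self, x: Tensor) -> Tensor:
        if self.training or self.collecting:
            mu = x.mean(axis=self.axes, keepdims=True)
            var = ((x - mu).pow(2.0)).mean(axis=self.axes, keepdims=True)
            if self.collecting:  # cumulative average over calibration batches
                self._n_collected += 1
                w = 1.0 / self._n_collected
                self.running_mean = (1 - w) * self.running_mean + w * mu.data
                self.running_var = (1 - w) * self.running_var + w * var.data
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var.data)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        z = (x - mu) * (var + self.epsilon).pow(-0.5)
        return z * self.gamma + self.beta


class BatchNorm1d(_BatchNormBase):
    """Batch normalization over feature vectors [N, F]."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 epsilon: float = 1e-5):
        super().__init__((1, n_features), (0,), momentum, epsilon)


class ChannelBatchNorm(_BatchNormBase):
    """Batch normalization over conv feature maps [N, C, L]: one mean and
    variance per channel, pooled over batch and time (the per-data-map
    normalization inside each conv block)."""

    def __init__(self, n_channels: int, momentum: float = 0.1,
                 epsilon: float = 1e-5):
        super().__init__((1, n_channels, 1), (0, 2), momentum, epsilon)


class LayerNorm(Module):
    """Per-position normalization over the last axis."""

    def __init__(self, width: int, epsilon: float = EPS):
        super().__init__()
        self.gamma = self.param(np.ones(width))
        self.beta = self.param(np.zeros(width))
        self.epsilon = epsilon

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu).pow(2.0)).mean(axis=-1, keepdims=True)
        z = (x - mu) * (var + self.epsilon).pow(-0.5)
        return z * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


def squash_t(s: Tensor) -> Tensor:
    """Autodiff version of the capsule squash over the last axis."""
    sq = (s * s).sum(axis=-1, keepdims=True)
    norm = (sq + EPS**2).pow(0.5)
    return s * (sq / (1.0 + sq) / norm)


class CapsuleHead(Module):
    """Primary-capsule regrouping + routed class capsules.

    Flattens a [N, t, channels] feature map into n_in primary capsules of
    dimension d_in, squashes them, applies the learned transform
    û_j|i = W_ij u_i, runs r iterations of routing-by-agreement, and
    returns the output-capsule lengths — scaled by a learnable logit
    temperature — as class logits.  The temperature matters because raw
    lengths live in (0, 1): a softmax over them could never express a
    class-probability ratio beyond e, so it is the same device cosine-softmax
    classifiers use for norm-bounded scores.
    """

    def __init__(self, t: int, channels: int, n_classes: int,
                 rng: np.random.Generator, d_in: int = 16, d_out: int = 16,
                 r: int = 3, logit_scale: float = 10.0):
        super().__init__()
        total = t * channels
        if total % d_in:
            raise ValueError(
                f"feature map {t}x{channels} ({total} values) not divisible "
                f"by primary capsule dimension {d_in}"
            )
        if r < 1:
            raise ValueError("routing iterations r must be >= 1")
        self.n_in = total // d_in
        self.d_in, self.d_out, self.r = d_in, d_out, r
        self.n_out = n_classes
        self.W = self.param(rng.normal(0.0, 1.0 / np.sqrt(d_in),
                                       (self.n_in, n_classes, d_in, d_out)))
        self.logit_scale = self.param(np.array(float(logit_scale)))

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        u = squash_t(x.reshape(n, self.n_in, self.d_in))
        # û_j|i = W_ij u_i via broadcast matmul
        u5 = u.reshape(n, self.n_in, 1, 1, self.d_in)
        u_hat = (u5 @ self.W).reshape(n, self.n_in, self.n_out, self.d_out)
        b = Tensor(np.zeros((n, self.n_in, self.n_out)))
        for _ in range(self.r):
            c = ag.softmax(b, axis=2)
            s = (u_hat * c.reshape(n, self.n_in, self.n_out, 1)).sum(axis=1)
            v = squash_t(s)  # [n, n_out, d_out]
            b = b + (u_hat * v.reshape(n, 1, self.n_out, self.d_out)).sum(axis=3)
        lengths = ((v * v).sum(axis=-1) + EPS**2).pow(0.5)
        # temperature-scaled lengths as logits; softmax happens in loss/proba
        return lengths * self.logit_scale


class MultiHeadAttention(Module):
    """h-head scaled dot-product self-attention on [N, t, d_model]."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        sd = 1.0 / np.sqrt(d_model)
        self.w_q = self.param(rng.normal(0, sd, (d_model, d_model)))
        self.w_k = self.param(rng.normal(0, sd, (d_model, d_model)))
        self.w_v = self.param(rng.normal(0, sd, (d_model, d_model)))
        self.w_o = self.param(rng.normal(0, sd, (d_model, d_model)))

    def _heads(self, x: Tensor, w: Tensor, n: int, t: int) -> Tensor:
        return (x @ w).reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        q = self._heads(x, self.w_q, n, t)
        k = self._heads(x, self.w_k, n, t)
        v = self._heads(x, self.w_v, n, t)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        w = ag.softmax(scores, axis=-1)
        out = (w @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return out @ self.w_o


class TransformerBlock(Module):
    """Post-norm encoder block: LN(x + MHA(x)), then LN(· + SELU-MLP(·))."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        super().__init__()
        self.mha = self.add_module(MultiHeadAttention(d_model, n_heads, rng))
        self.ln1 = self.add_module(LayerNorm(d_model))
        self.fc1 = self.add_module(Dense(d_model, mlp_ratio * d_model, rng))
        self.fc2 = self.add_module(Dense(mlp_ratio * d_model, d_model, rng))
        self.ln2 = self.add_module(LayerNorm(d_model))

    def forward(self, x: Tensor) -> Tensor:
        h = self.ln1(x + self.mha(x))
        mlp = self.fc2(ag.selu(self.fc1(h)))
        return self.ln2(h + mlp)
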