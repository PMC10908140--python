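"""Reference numerics for the network building blocks, in plain numpy.

These are the mathematically transparent versions of the primitives the
architectures are assembled from — SELU, batch normalization, the capsule
squash nonlinearity and dynamic routing-by-agreement, scaled dot-product and
multi-head attention, and a pre-norm-free transformer block.  Each operates
on plain arrays and is testable in isolation; the trainable layers in
:mod:`capseeg.nn.layers` compute the same functions through the autodiff
engine and are cross-checked against these in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import SELU_ALPHA, SELU_LAMBDA

EPS = 1e-7


@dataclass
class SELUConstants:
    """λ ≈ 1.0507 scales the whole output; α ≈ 1.67326 sets the negative
    saturation level.  Both exceed 1, which is what makes the activation
    self-normalizing."""

    lambda_: float = SELU_LAMBDA
    alpha: float = SELU_ALPHA


def selu(x, constants: SELUConstants = SELUConstants()):
    """SELU(x) = λ·x for x > 0, λ·α·(exp(x) − 1) for x ≤ 0."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, constants.lambda_ * x,
                    constants.lambda_ * constants.alpha
                    * np.expm1(np.minimum(x, 0.0)))


@dataclass
class BatchNormParams:
    """γ/β re-scale and re-translate; E[X]/Var[X] are the normalization
    statistics; ε stabilizes the denominator."""

    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    epsilon: float = 1e-5


def batch_norm(x, p: BatchNormParams):
    """BN(x, γ, β) = β + γ·(x − E[X]) / sqrt(Var[X] + ε), per feature."""
    x = np.asarray(x, dtype=float)
    return p.beta + p.gamma * (x - p.mean) / np.sqrt(p.var + p.epsilon)


def squash(s):
    """v = (‖s‖² / (1 + ‖s‖²)) · (s / ‖s‖) over the last axis.

    Maps any vector to the same direction with norm strictly below 1; the
    zero vector maps to zero (the ε guard makes the limit exact).
    """
    s = np.asarray(s, dtype=float)
    sq = (s * s).sum(axis=-1, keepdims=True)
    norm = np.sqrt(sq + EPS**2)
    return (sq / (1.0 + sq)) * s / norm


@dataclass
class RoutingState:
    """Final state of one routing invocation: logits b [n_in, n_out],
    coupling coefficients c (rows sum to 1 over the output index), totals
    s and outputs v [n_out, d_out]."""

    b: np.ndarray
    c: np.ndarray
    s: np.ndarray
    v: np.ndarray


def dynamic_routing(u_hat, r: int = 3):
    """Routing-by-agreement over prediction vectors û [n_in, n_out, d_out].

    The logits start at zero.  Each of the ``r`` iterations computes
    c_ij = exp(b_ij)/Σ_k exp(b_ik) (softmax over the output capsule j),
    s_j = Σ_i c_ij û_j|i, v_j = squash(s_j), and then reinforces agreement
    with b_ij += û_j|i · v_j.  Returns (v, RoutingState) from the final
    iteration.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if u_hat.ndim != 3:
        raise ValueError("u_hat must be [n_in, n_out, d_out]")
    if r < 1:
        raise ValueError("routing needs at least one iteration")
    n_in, n_out, _ = u_hat.shape
    b = np.zeros((n_in, n_out))
    for _ in range(r):
        b_shift = b - b.max(axis=1, keepdims=True)
        e = np.exp(b_shift)
        c = e / e.sum(axis=1, keepdims=True)
        s = np.einsum("ij,ijd->jd", c, u_hat)
        v = squash(s)
        b = b + np.einsum("ijd,jd->ij", u_hat, v)
    return v, RoutingState(b=b, c=c, s=s, v=v)


@dataclass
class CapsuleLayerParams:
    """Transform tensor W [n_in, n_out, d_in, d_out] plus routing depth r."""

    W: np.ndarray
    r: int = 3

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 4:
            raise ValueError("W must be [n_in, n_out, d_in, d_out]")
        if self.r < 1:
            raise ValueError("r must be >= 1")


def capsule_head(features, params: CapsuleLayerParams):
    """Capsule classification head over a [t, channels] feature map.

    The map is flattened and regrouped into n_in primary capsules of
    dimension d_in (so t·channels must divide evenly), squashed, transformed
    into prediction vectors û_j|i = W_ij u_i, routed for r iterations, and
    the output capsule lengths ‖v_j‖ — the per-class existence
    probabilities — are passed through a softmax to give class scores.
    """
    features = np.asarray(features, dtype=float)
    n_in, n_out, d_in, d_out = params.W.shape
    total = features.size
    if total != n_in * d_in:
        raise ValueError(
            f"feature map of {features.shape} ({total} values) cannot form "
            f"{n_in} primary capsules of dimension {d_in}"
        )
    u = squash(features.reshape(n_in, d_in))
    u_hat = np.einsum("id,ijde->ije", u, params.W)
    v, _ = dynamic_routing(u_hat, params.r)
    lengths = np.linalg.norm(v, axis=-1)
    e = np.exp(lengths - lengths.max())
    return e / e.sum()


def attention(q, k, v):
    """Scaled dot-product attention: softmax(QKᵀ/√d_k)·V, row-wise softmax."""
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    d_k = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    scores = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w = w / w.sum(axis=-1, keepdims=True)
    return w @ v


@dataclass
class AttentionParams:
    """Learned projections for multi-head attention on width d_model.

    w_q/w_k/w_v/w_o are [d_model, d_model]; each head sees a d_model/h slice
    of the projected queries, keys, and values.
    """

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray
    n_heads: int = 1

    def __post_init__(self):
        d = self.w_q.shape[0]
        if d % self.n_heads:
            raise ValueError(f"d_model {d} not divisible by {self.n_heads} heads")

    @property
    def d_model(self) -> int:
        return self.w_q.shape[0]


def multi_head_attention(x, p: AttentionParams):
    """h parallel attention heads on projected slices, concatenated and
    output-projected.  x: [t, d_model] -> [t, d_model]."""
    x = np.asarray(x, dtype=float)
    t, d = x.shape
    if d != p.d_model:
        raise ValueError(f"input width {d} != d_model {p.d_model}")
    h = p.n_heads
    dk = d // h
    q, k, v = x @ p.w_q, x @ p.w_k, x @ p.w_v
    heads = [attention(q[:, i * dk:(i + 1) * dk], k[:, i * dk:(i + 1) * dk],
                       v[:, i * dk:(i + 1) * dk]) for i in range(h)]
    return np.concatenate(heads, axis=1) @ p.w_o


def layer_norm(x, gamma=None, beta=None, eps: float = EPS):
    """Normalize each row of x to zero mean / unit variance, then re-scale."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    z = (x - mu) / np.sqrt(var + eps)
    if gamma is not None:
        z = z * gamma
    if beta is not None:
        z = z + beta
    return z


@dataclass
class TransformerBlockParams:
    """Post-norm encoder block: MHA + residual + LayerNorm, then a two-layer
    SELU MLP + residual + LayerNorm.  The MLP hidden width is conventionally
    4 × d_model."""

    attn: AttentionParams
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    ln1_gamma: np.ndarray = None
    ln1_beta: np.ndarray = None
    ln2_gamma: np.ndarray = None
    ln2_beta: np.ndarray = None


def transformer_block(x, p: TransformerBlockParams):
    """x -> LayerNorm(x + MHA(x)) -> LayerNorm(· + MLP(·))."""
    x = np.asarray(x, dtype=float)
    h = layer_norm(x + multi_head_attention(x, p.attn), p.ln1_gamma, p.ln1_beta)
    mlp = selu(h @ p.w1 + p.b1) @ p.w2 + p.b2
    return layer_norm(h + mlp, p.ln2_gamma, p.ln2_beta)
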