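"""Reference numerics vs naive oracles: SELU, batch-norm, squash, dynamic
routing-by-agreement, attention, multi-head attention, transformer block."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capseeg.nn import functional as F
from capseeg.nn.functional import (AttentionParams, BatchNormParams,
                                   CapsuleLayerParams, SELUConstants,
                                   TransformerBlockParams)

# ---------------------------------------------------------------- oracles


def routing_oracle(u_hat, r):
    """Naive triple-loop transcription of the routing procedure."""
    n_in, n_out, d = u_hat.shape
    b = np.zeros((n_in, n_out))
    for _ in range(r):
        c = np.zeros_like(b)
        for i in range(n_in):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        s = np.zeros((n_out, d))
        for j in range(n_out):
            for i in range(n_in):
                s[j] += c[i, j] * u_hat[i, j]
        v = np.zeros_like(s)
        for j in range(n_out):
            sq = (s[j] ** 2).sum()
            v[j] = (sq / (1 + sq)) * s[j] / np.sqrt(sq + F.EPS**2)
        for i in range(n_in):
            for j in range(n_out):
                b[i, j] += u_hat[i, j] @ v[j]
    return v, c


def attention_oracle(q, k, v):
    n, d = q.shape
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(len(k))])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        for j in range(len(k)):
            out[i] += w[j] * v[j]
    return out


# ---------------------------------------------------------------- SELU


class TestSelu:
    def test_at_one_equals_lambda(self):
        assert F.selu(1.0) == pytest.approx(1.0507, abs=5e-5)

    def test_at_zero(self):
        assert F.selu(0.0) == 0.0

    def test_negative_saturation_recovers_alpha(self):
        c = SELUConstants()
        assert -F.selu(-40.0) / c.lambda_ == pytest.approx(1.67326, abs=5e-6)

    def test_continuous_at_origin(self):
        eps = 1e-9
        assert abs(F.selu(eps) - F.selu(-eps)) < 1e-8

    @given(st.floats(-50, 50))
    @settings(max_examples=50, derandomize=True)
    def test_monotone(self, x):
        # non-decreasing everywhere; strictly increasing away from the
        # deep-negative saturation plateau (float resolution limit)
        assert F.selu(x + 0.1) >= F.selu(x)
        if x > -20:
            assert F.selu(x + 0.1) > F.selu(x)


class TestBatchNorm:
    def test_batch_statistics_normalize(self, rng):
        x = rng.normal(3.0, 2.0, size=(200, 4))
        p = BatchNormParams(gamma=np.ones(4), beta=np.zeros(4),
                            mean=x.mean(0), var=x.var(0))
        z = F.batch_norm(x, p)
        assert np.abs(z.mean(0)).max() < 1e-10
        assert np.allclose(z.var(0), 1.0, atol=1e-4)

    def test_gamma_beta_rescale(self, rng):
        x = rng.normal(size=(500, 3))
        p = BatchNormParams(gamma=np.full(3, 2.0), beta=np.full(3, 3.0),
                            mean=x.mean(0), var=x.var(0))
        z = F.batch_norm(x, p)
        assert np.allclose(z.mean(0), 3.0, atol=1e-10)
        assert np.allclose(z.std(0), 2.0, atol=1e-3)

    def test_constant_feature_outputs_beta(self):
        x = np.full((10, 2), 7.0)
        p = BatchNormParams(gamma=np.ones(2), beta=np.full(2, -1.5),
                            mean=x.mean(0), var=x.var(0))
        assert np.allclose(F.batch_norm(x, p), -1.5)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(F.squash(np.zeros(4)), 0.0)

    def test_unit_vector_halved(self):
        v = F.squash(np.array([1.0, 0.0]))
        assert np.allclose(v, [0.5, 0.0], atol=1e-7)

    def test_norm_below_one_and_monotone(self, rng):
        scales = np.linspace(0.1, 50, 40)
        direction = rng.normal(size=5)
        direction /= np.linalg.norm(direction)
        norms = [np.linalg.norm(F.squash(s * direction)) for s in scales]
        assert all(n < 1 for n in norms)
        assert np.all(np.diff(norms) > 0)
        assert norms[-1] > 0.99  # asymptote toward 1

    def test_direction_preserved(self, rng):
        s = rng.normal(size=6)
        v = F.squash(s)
        cos = v @ s / (np.linalg.norm(v) * np.linalg.norm(s))
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestDynamicRouting:
    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(50):
            n_in = rng.integers(1, 5)
            n_out = rng.integers(1, 4)
            d = rng.integers(1, 5)
            r = int(rng.integers(1, 4))
            u_hat = rng.normal(size=(n_in, n_out, d))
            v, state = F.dynamic_routing(u_hat, r)
            v_o, c_o = routing_oracle(u_hat, r)
            assert np.allclose(v, v_o, atol=1e-10)
            assert np.allclose(state.c, c_o, atol=1e-10)

    def test_single_iteration_closed_form(self, rng):
        """With zero-initialized logits, all couplings are 1/n_out, so
        v_j = squash((1/n_out) * sum_i û_j|i)."""
        u_hat = rng.normal(size=(6, 3, 4))
        v, _ = F.dynamic_routing(u_hat, r=1)
        expected = F.squash(u_hat.sum(axis=0) / u_hat.shape[1])
        assert np.allclose(v, expected, atol=1e-12)

    def test_scalar_instance(self):
        u_hat = np.array([[[2.0, 0.0]]])
        v, state = F.dynamic_routing(u_hat, r=3)
        assert np.allclose(v, F.squash(np.array([2.0, 0.0])), atol=1e-12)
        assert np.allclose(state.c, 1.0)

    def test_coupling_rows_normalize(self, rng):
        u_hat = rng.normal(size=(5, 3, 2)) * 3
        _, state = F.dynamic_routing(u_hat, r=3)
        assert np.allclose(state.c.sum(axis=1), 1.0, atol=1e-10)

    def test_agreement_concentrates_coupling(self, rng):
        """When all inputs predict the same strong output for capsule j,
        coupling mass moves onto j monotonically over iterations."""
        n_in, n_out, d = 4, 3, 4
        u_hat = rng.normal(size=(n_in, n_out, d)) * 0.01
        agreed = np.array([3.0, 0.0, 0.0, 0.0])
        u_hat[:, 1, :] = agreed
        cs = []
        for r in (1, 2, 3):
            _, state = F.dynamic_routing(u_hat, r)
            cs.append(state.c[:, 1].mean())
        assert cs[0] <= cs[1] <= cs[2]
        assert cs[2] > 1.0 / n_out

    def test_invalid_r(self, rng):
        with pytest.raises(ValueError):
            F.dynamic_routing(rng.normal(size=(2, 2, 2)), r=0)


class TestCapsuleHead:
    def test_primary_capsule_count(self, rng):
        t, c, d_in = 2, 512, 16
        W = rng.normal(size=(t * c // d_in, 5, d_in, 16)) * 0.1
        scores = F.capsule_head(rng.normal(size=(t, c)),
                                CapsuleLayerParams(W=W))
        assert W.shape[0] == 64  # 2*512/16 primary capsules
        assert scores.shape == (5,)

    def test_zero_transform_gives_uniform_scores(self, rng):
        W = np.zeros((4, 3, 8, 8))
        scores = F.capsule_head(rng.normal(size=(2, 16)),
                                CapsuleLayerParams(W=W))
        assert np.allclose(scores, 1.0 / 3.0)

    def test_scores_simplex(self, rng):
        W = rng.normal(size=(4, 2, 8, 6))
        scores = F.capsule_head(rng.normal(size=(4, 8)),
                                CapsuleLayerParams(W=W))
        assert scores.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((scores > 0) & (scores < 1))

    def test_indivisible_shape_rejected(self, rng):
        W = rng.normal(size=(4, 2, 8, 6))
        with pytest.raises(ValueError, match="primary capsules"):
            F.capsule_head(rng.normal(size=(3, 10)), CapsuleLayerParams(W=W))


class TestAttention:
    def test_single_token_returns_value(self, rng):
        q, k, v = (rng.normal(size=(1, 6)) for _ in range(3))
        assert np.allclose(F.attention(q, k, v), v, atol=1e-12)

    def test_zero_scores_average_values(self, rng):
        q = np.zeros((3, 4))
        k = rng.normal(size=(3, 4))
        v = rng.normal(size=(3, 4))
        out = F.attention(q, np.zeros_like(k), v)
        assert np.allclose(out, np.tile(v.mean(0), (3, 1)), atol=1e-12)

    def test_matches_naive_loop(self, rng):
        for _ in range(25):
            q, k, v = (rng.normal(size=(3, 4)) for _ in range(3))
            assert np.allclose(F.attention(q, k, v),
                               attention_oracle(q, k, v), atol=1e-12)


class TestMultiHeadAttention:
    def test_one_head_identity_projections_reduce_to_attention(self, rng):
        d = 6
        eye = np.eye(d)
        p = AttentionParams(w_q=eye, w_k=eye, w_v=eye, w_o=eye, n_heads=1)
        x = rng.normal(size=(4, d))
        assert np.allclose(F.multi_head_attention(x, p),
                           F.attention(x, x, x), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        d, h = 8, 4
        mats = [rng.normal(size=(d, d)) for _ in range(4)]
        p = AttentionParams(*mats, n_heads=h)
        x = rng.normal(size=(5, d))
        perm = rng.permutation(5)
        assert np.allclose(F.multi_head_attention(x[perm], p),
                           F.multi_head_attention(x, p)[perm], atol=1e-10)

    def test_head_count_must_divide(self, rng):
        mats = [rng.normal(size=(6, 6)) for _ in range(4)]
        with pytest.raises(ValueError, match="divisible"):
            AttentionParams(*mats, n_heads=4)


class TestTransformerBlock:
    def _params(self, rng, d, h=2, hidden=None):
        hidden = hidden or 4 * d
        mats = [rng.normal(size=(d, d)) * 0.3 for _ in range(4)]
        return TransformerBlockParams(
            attn=AttentionParams(*mats, n_heads=h),
            w1=rng.normal(size=(d, hidden)) * 0.3, b1=np.zeros(hidden),
            w2=rng.normal(size=(hidden, d)) * 0.3, b2=np.zeros(d))

    def test_zero_weights_reduce_to_double_layernorm(self, rng):
        d = 6
        z = np.zeros((d, d))
        p = TransformerBlockParams(
            attn=AttentionParams(z, z, z, z, n_heads=1),
            w1=np.zeros((d, 4 * d)), b1=np.zeros(4 * d),
            w2=np.zeros((4 * d, d)), b2=np.zeros(d))
        x = rng.normal(size=(3, d))
        expected = F.layer_norm(F.layer_norm(x))
        assert np.allclose(F.transformer_block(x, p), expected, atol=1e-10)

    def test_shape_preserved(self, rng):
        p = self._params(rng, 8)
        assert F.transformer_block(rng.normal(size=(5, 8)), p).shape == (5, 8)

    def test_finite_for_many_random_draws(self, rng):
        p = self._params(rng, 4)
        for _ in range(1000):
            out = F.transformer_block(rng.normal(size=(3, 4)) * 10, p)
            assert np.all(np.isfinite(out))
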