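import numpy as np
import pytest

from dtmn import (
    CONTEXT_PRESETS,
    ContextSpec,
    DomainError,
    StructuralError,
    TrainConfig,
    alpha_encode,
    context_preset,
    softmax,
    tdnn_forward,
    train_tdnn,
)
from dtmn.tdnn import TDNNParams, _backward, _forward, tdnn_forward_batch


class TestAlphaEncode:
    def test_indicator(self):
        assert alpha_encode(1, 3).tolist() == [1.0, 0.0, 0.0]

    def test_absent_is_zero_vector(self):
        assert alpha_encode(0, 3).tolist() == [0.0, 0.0, 0.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            alpha_encode(4, 3)


class TestSoftmax:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.floats(-100, 100))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_distribution_and_shift_invariance(self, z, c):
        z = np.array(z)
        t = softmax(z)
        assert abs(t.sum() - 1.0) < 1e-12
        assert np.all(t >= 0)
        np.testing.assert_allclose(softmax(z + c), t, atol=1e-9)

    def test_symmetry(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), 1 / 3)

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(2), 0.0, 0.0])), [0.5, 0.25, 0.25]
        )

    def test_large_logits_stable(self):
        t = softmax(np.array([1000.0, 0.0]))
        assert np.all(np.isfinite(t))
        np.testing.assert_allclose(t, [1.0, 0.0], atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            softmax(np.array([np.nan, 0.0]))


class TestContextSpec:
    def test_published_presets(self):
        assert CONTEXT_PRESETS["tdnn4"].network_context == (-5, -4, -3, -2, -1)
        assert CONTEXT_PRESETS["tdnn4"].layer2_context == (-3, -1)
        assert CONTEXT_PRESETS["tdnn6"].network_context == tuple(range(-9, 0))
        assert CONTEXT_PRESETS["tdnn6"].layer2_context == (-9, -5, -1)
        assert CONTEXT_PRESETS["tdnn1"].window == 1
        assert not CONTEXT_PRESETS["tdnn1"].shallow
        assert CONTEXT_PRESETS["eq2"].shallow

    def test_unknown_preset_rejected(self):
        with pytest.raises(DomainError):
            context_preset("tdnn9")

    def test_nonnegative_offsets_rejected(self):
        with pytest.raises(DomainError):
            ContextSpec("x", (0,), (0,), (0,))

    def test_layer2_outside_network_rejected(self):
        with pytest.raises(DomainError):
            ContextSpec("x", (-2, -1), (-1,), (-3,))


def _small_params(ctx_name="tdnn4", N=4, D=3, H=8, seed=0):
    return TDNNParams.init(context_preset(ctx_name), N, D, hidden_dim=H, seed=seed)


class TestForward:
    @pytest.mark.parametrize("ctx_name", ["tdnn1", "tdnn4", "eq2"])
    def test_output_is_distribution(self, ctx_name, rng):
        p = _small_params(ctx_name)
        K = p.ctx.window
        out = tdnn_forward(p, rng.integers(0, 5, size=K), rng.normal(size=3))
        assert out.shape == (4,)
        assert abs(out.sum() - 1.0) < 1e-9
        assert np.all(out >= 0)

    def test_infer_mode_deterministic(self, rng):
        p = _small_params()
        q = rng.integers(0, 5, size=5)
        f = rng.normal(size=3)
        np.testing.assert_array_equal(tdnn_forward(p, q, f), tdnn_forward(p, q, f))

    def test_zero_weights_give_uniform(self):
        p = _small_params()
        for k in p.trainable_keys():
            if not k.startswith(("g",)):
                p.arrays[k][:] = 0.0
        out = tdnn_forward(p, [1, 2, 3, 4, 1], np.ones(3))
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        p = _small_params()
        with pytest.raises(StructuralError):
            tdnn_forward(p, [1, 2], np.ones(3))
        with pytest.raises(StructuralError):
            tdnn_forward(p, [1, 2, 3, 4, 5], np.ones(7))

    def test_soft_windows_match_onehot_at_vertices(self, rng):
        p = _small_params()
        Q = rng.integers(1, 5, size=(6, 5))
        F = rng.normal(size=(6, 3))
        hard = tdnn_forward_batch(p, Q, F)
        stacks = np.zeros((6, 5, 4))
        for b in range(6):
            for k in range(5):
                stacks[b, k, Q[b, k] - 1] = 1.0
        np.testing.assert_allclose(hard, tdnn_forward_batch(p, stacks, F), atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("ctx_name", ["tdnn4", "eq2"])
    def test_backward_matches_finite_differences(self, ctx_name, rng):
        """Analytic gradients of the cross-entropy agree with numeric ones."""
        p = _small_params(ctx_name, N=3, D=2, H=4, seed=1)
        K = p.ctx.window
        B = 7
        Q = rng.integers(0, 4, size=(B, K))
        F = rng.normal(size=(B, 2))
        tgt = rng.integers(0, 3, size=B)

        def loss():
            P, _ = _forward(p, Q, F, train=True)
            return -np.mean(np.log(P[np.arange(B), tgt]))

        P, cache = _forward(p, Q, F, train=True)
        dZ = P.copy()
        dZ[np.arange(B), tgt] -= 1.0
        dZ /= B
        grads = _backward(p, dZ, cache)
        eps = 1e-6
        for k, g in grads.items():
            arr = p.arrays[k]
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.ravel()[idx]) < 1e-4, k


class TestTraining:
    def test_overfits_separable_two_class_task(self):
        rng = np.random.default_rng(0)
        n = 40
        tgt = np.repeat([1, 2], n // 2)
        F = np.where((tgt == 1)[:, None], 4.0, -4.0) + rng.normal(size=(n, 2))
        Q = np.zeros((n, 1), dtype=np.int64)  # no temporal signal
        cfg = TrainConfig(epochs=50, batch_size=8, seed=0, refine_rounds=0)
        p = train_tdnn((Q, F, tgt), context_preset("tdnn1"), cfg, n_states=2,
                       hidden_dim=8)
        pred = np.argmax(tdnn_forward_batch(p, Q, F), axis=1) + 1
        assert np.array_equal(pred, tgt)

    def test_seed_determinism(self, rng):
        Q = rng.integers(0, 4, size=(30, 5))
        F = rng.normal(size=(30, 3))
        tgt = rng.integers(1, 4, size=30)
        cfg = TrainConfig(epochs=3, batch_size=16, seed=5, refine_rounds=0)
        a = train_tdnn((Q, F, tgt), context_preset("tdnn4"), cfg, 3, hidden_dim=8)
        b = train_tdnn((Q, F, tgt), context_preset("tdnn4"), cfg, 3, hidden_dim=8)
        assert a.loss_trace == b.loss_trace
        for k in a.arrays:
            np.testing.assert_array_equal(a.arrays[k], b.arrays[k])

    def test_zero_learning_rate_is_null_update(self, rng):
        Q = rng.integers(0, 4, size=(20, 5))
        F = rng.normal(size=(20, 3))
        tgt = rng.integers(1, 4, size=20)
        cfg = TrainConfig(epochs=4, learning_rate=0.0, seed=0, refine_rounds=0)
        init = TDNNParams.init(context_preset("tdnn4"), 3, 3, hidden_dim=8, seed=0)
        p = train_tdnn((Q, F, tgt), context_preset("tdnn4"), cfg, 3, hidden_dim=8)
        for k in p.trainable_keys():
            np.testing.assert_array_equal(p.arrays[k], init.arrays[k])
        assert np.allclose(p.loss_trace, p.loss_trace[0])

    def test_loss_decreases_on_learnable_task(self, rng):
        tgt = rng.integers(1, 4, size=120)
        F = np.eye(3)[tgt - 1] * 3 + rng.normal(size=(120, 3))
        Q = np.zeros((120, 5), dtype=np.int64)
        cfg = TrainConfig(epochs=20, batch_size=32, seed=1, refine_rounds=0)
        p = train_tdnn((Q, F, tgt), context_preset("tdnn4"), cfg, 3, hidden_dim=8)
        assert np.all(np.isfinite(p.loss_trace))
        assert p.loss_trace[-1] < p.loss_trace[0]

    def test_empty_examples_rejected(self):
        with pytest.raises(DomainError):
            train_tdnn(
                (np.zeros((0, 5), dtype=int), np.zeros((0, 3)), np.zeros(0, dtype=int)),
                context_preset("tdnn4"), TrainConfig(), 3,
            )

    def test_target_out_of_range_rejected(self, rng):
        Q = np.zeros((4, 5), dtype=np.int64)
        with pytest.raises(DomainError):
            train_tdnn(
                (Q, rng.normal(size=(4, 3)), np.array([1, 2, 3, 9])),
                context_preset("tdnn4"), TrainConfig(refine_rounds=0), 3,
            )


class TestSerialization:
    def test_round_trip(self, rng):
        p = _small_params()
        d = p.to_dict()
        q = TDNNParams.from_dict(d)
        assert q.ctx == p.ctx
        for k in p.arrays:
            np.testing.assert_array_equal(p.arrays[k], q.arrays[k])
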