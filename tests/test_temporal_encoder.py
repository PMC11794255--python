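import numpy as np
import pytest

from stpanel.autodiff import Tensor
from stpanel.temporal import (encode_sequence, gated_cell_step,
                              init_attention, init_gated_cell,
                              temporal_attention)


def zero_cell(input_dim, hidden_dim, prefix="cell"):
    rng = np.random.default_rng(0)
    p = init_gated_cell(input_dim, hidden_dim, rng, prefix=prefix)
    for t in p.values():
        t.data[...] = 0.0
    return p


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def loop_oracle(history, params, prefix="cell0"):
    """Plain nested-loop reference: lags x features, scalar numpy math."""
    n_lags, M, d_in = history.shape
    d = params[f"{prefix}.W_g"].data.shape[1]
    z = np.zeros((M, d))
    out = np.zeros((n_lags, M, d))
    for lag in range(n_lags):
        for m in range(M):
            y = history[lag, m]
            g = sigmoid(y @ params[f"{prefix}.W_g"].data
                        + z[m] @ params[f"{prefix}.U_g"].data
                        + params[f"{prefix}.b_g"].data)
            i = sigmoid(y @ params[f"{prefix}.W_i"].data
                        + z[m] @ params[f"{prefix}.U_i"].data
                        + params[f"{prefix}.b_i"].data)
            cand = np.tanh(y @ params[f"{prefix}.W_z"].data
                           + z[m] @ params[f"{prefix}.U_z"].data
                           + params[f"{prefix}.b_z"].data)
            out[lag, m] = g * z[m] + i * cand
        z = out[lag].copy()
    return out


class TestGatedCell:
    def test_zero_parameters_halve_prior_state(self):
        """All params 0: gates = sigmoid(0) = 0.5, candidate = tanh(0) = 0,
        so z_t = 0.5 z_{t-1}."""
        p = zero_cell(2, 3)
        z_prev = np.array([2.0, -4.0, 6.0])
        z = gated_cell_step(np.ones(2), z_prev, p)
        np.testing.assert_allclose(z.data, 0.5 * z_prev)

    def test_all_zero_inputs_give_zero_state(self):
        p = zero_cell(2, 3)
        z = gated_cell_step(np.zeros(2), np.zeros(3), p)
        np.testing.assert_allclose(z.data, 0.0)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        p = init_gated_cell(2, 3, rng)
        y, z = rng.normal(size=2) * 10, rng.normal(size=3) * 10
        g = sigmoid(y @ p["cell.W_g"].data + z @ p["cell.U_g"].data
                    + p["cell.b_g"].data)
        assert np.all((g > 0) & (g < 1))

    def test_shape_mismatch_rejected(self):
        p = zero_cell(2, 3)
        with pytest.raises(ValueError, match="dimension"):
            gated_cell_step(np.zeros(5), np.zeros(3), p)


class TestEncodeSequence:
    def test_single_lag_equals_one_step(self):
        rng = np.random.default_rng(2)
        p = init_gated_cell(1, 4, rng, prefix="cell0")
        x = rng.normal(size=(1, 3, 1))  # 1 lag, 3 features
        seq = encode_sequence(x, p, n_layers=1)
        step = gated_cell_step(x[0], np.zeros((3, 4)), p, prefix="cell0")
        np.testing.assert_allclose(seq.data[0], step.data)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        p = init_gated_cell(1, 3, rng, prefix="cell0")
        x = rng.normal(size=(3, 2, 1))  # 3 lags, 2 features
        seq = encode_sequence(x, p, n_layers=1)
        np.testing.assert_allclose(seq.data, loop_oracle(x, p), atol=1e-10)

    def test_batched_layout_agrees_with_flat(self):
        rng = np.random.default_rng(4)
        p = init_gated_cell(1, 3, rng, prefix="cell0")
        x = rng.normal(size=(2, 4, 3, 2, 1))  # (B, lags, V, M, 1)
        seq = encode_sequence(x, p, n_layers=1, lag_axis=1)
        for b in range(2):
            for v in range(3):
                ref = loop_oracle(x[b, :, v], p)
                np.testing.assert_allclose(seq.data[b, :, v], ref, atol=1e-12)

    def test_two_layers_feed_forward(self):
        rng = np.random.default_rng(5)
        p = {**init_gated_cell(1, 3, rng, prefix="cell0"),
             **init_gated_cell(3, 3, rng, prefix="cell1")}
        x = rng.normal(size=(4, 2, 1))
        two = encode_sequence(x, p, n_layers=2)
        one = encode_sequence(x, p, n_layers=1)
        # layer 1 consumes layer 0's full state sequence
        manual = loop_oracle(one.data, p, prefix="cell1")
        np.testing.assert_allclose(two.data, manual, atol=1e-12)

    def test_bounded_state_growth(self):
        """Gates in (0,1) and tanh candidate bound |z_t| <= |z_0| + t."""
        rng = np.random.default_rng(6)
        p = init_gated_cell(1, 3, rng, scale=1.0, prefix="cell0")
        x = rng.normal(size=(10, 2, 1)) * 5
        seq = encode_sequence(x, p, n_layers=1)
        for t in range(10):
            assert np.all(np.abs(seq.data[t]) <= t + 1 + 1e-9)

    def test_gradient_flows_through_recursion(self):
        rng = np.random.default_rng(7)
        p = init_gated_cell(1, 2, rng, prefix="cell0")
        x = rng.normal(size=(3, 2, 1))
        loss = (encode_sequence(x, p, n_layers=1) ** 2).sum()
        loss.backward()
        base = float((encode_sequence(x, p, n_layers=1) ** 2).sum().data)
        h = 1e-6
        for key in ("cell0.W_z", "cell0.U_g", "cell0.b_i"):
            flat = p[key].data.reshape(-1)
            orig = flat[0]
            flat[0] = orig + h
            hi = float((encode_sequence(x, p, n_layers=1) ** 2).sum().data)
            flat[0] = orig - h
            lo = float((encode_sequence(x, p, n_layers=1) ** 2).sum().data)
            flat[0] = orig
            fd = (hi - lo) / (2 * h)
            an = p[key].grad.reshape(-1)[0]
            assert abs(an - fd) / max(abs(fd), 1.0) < 1e-4


class TestTemporalAttention:
    def test_identical_states_give_uniform_weights(self):
        rng = np.random.default_rng(8)
        p = init_attention(3, 2, rng)
        z = np.tile(rng.normal(size=3), (4, 1))  # 4 identical feature states
        w, ctx = temporal_attention(z, p)
        np.testing.assert_allclose(w.data, 0.25)
        np.testing.assert_allclose(ctx.data, z[0], atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        p = init_attention(3, 2, rng)
        z = rng.normal(size=(2, 5, 6, 3))
        w, _ = temporal_attention(z, p)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w.data >= 0)

    def test_known_score_gap_weights(self):
        """Scores [1, 0] over two features -> softmax [0.7311, 0.2689]."""
        p = {"attn.Q": Tensor(np.array([[100.0]])),
             "attn.c": Tensor(np.zeros(1)),
             "attn.q": Tensor(np.array([[1.0]]))}
        # tanh saturates: states [1, 0] -> scores ~ [1, 0]
        z = np.array([[1.0], [0.0]])
        w, _ = temporal_attention(z, p)
        np.testing.assert_allclose(w.data, [0.73106, 0.26894], atol=1e-4)

    def test_context_in_convex_hull(self):
        rng = np.random.default_rng(10)
        p = init_attention(2, 3, rng)
        z = rng.normal(size=(6, 2))
        _, ctx = temporal_attention(z, p)
        assert np.all(ctx.data <= z.max(axis=0) + 1e-12)
        assert np.all(ctx.data >= z.min(axis=0) - 1e-12)
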