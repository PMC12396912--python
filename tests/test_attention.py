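"""Channel attention gate: each step against trivial closed forms and an
independent all-loops float64 oracle, plus the gate's structural
invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cagsnet.attention import (
    CAGParams, make_cag_params, project_features, channel_correlation,
    channel_softmax, gate_signal, attention_response, gate_weights,
    apply_gate_and_merge, cag_forward, CAGGate,
)
from oracle_cag import (
    cag_oracle, loop_project, loop_correlation, loop_mix, loop_response,
)


def identity_params(c, mu=0.0):
    eye = np.eye(c, dtype=np.float32)
    return CAGParams(w_f=eye.copy(), w_g=eye.copy(), w_h=eye.copy(), mu=mu)


def random_params(c, seed, mu=0.01):
    return make_cag_params(c, np.random.default_rng(seed), mu=mu)


class TestProjectFeatures:
    def test_zero_input_gives_zero_features(self):
        p = random_params(3, 0)
        p.b_f[:] = 0; p.b_g[:] = 0
        x = np.zeros((3, 2, 2, 2), np.float32)
        f, g = project_features(x, x, p)
        assert np.all(f == 0) and np.all(g == 0)

    def test_identity_weights_clip_negatives_at_mu_zero(self):
        p = identity_params(2, mu=0.0)
        x = np.zeros((2, 1, 1, 2), np.float32)
        x[0, 0, 0, 0] = -2.0
        x[1, 0, 0, 1] = 3.0
        f, _ = project_features(x, x, p)
        assert f[0, 0, 0, 0] == 0.0          # ReLU clips the negative entry
        assert f[1, 0, 0, 1] == 3.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        p = random_params(2, 1)
        x = rng.normal(size=(2, 1, 2, 2)).astype(np.float32)
        y = rng.normal(size=(2, 1, 2, 2)).astype(np.float32)
        f, g = project_features(x, y, p)
        f_ref = loop_project(x.reshape(2, 4).astype(float), p.w_f, p.b_f, p.mu)
        g_ref = loop_project(y.reshape(2, 4).astype(float), p.w_g, p.b_g, p.mu)
        np.testing.assert_allclose(f.reshape(2, 4), f_ref, atol=1e-5)
        np.testing.assert_allclose(g.reshape(2, 4), g_ref, atol=1e-5)

    def test_shape_mismatch_names_both_shapes(self):
        p = random_params(2, 0)
        with pytest.raises(ValueError, match=r"2, 2, 2.*2, 2, 3"):
            project_features(np.zeros((2, 2, 2, 2), np.float32),
                             np.zeros((2, 2, 2, 3), np.float32), p)


class TestChannelCorrelation:
    def test_single_channel_of_ones_sums_voxels(self):
        f = np.ones((1, 2, 2, 2), np.float32)
        np.testing.assert_allclose(channel_correlation(f, f), [[8.0]])

    def test_orthogonal_channels_give_zero_off_diagonals(self):
        f = np.zeros((2, 1, 1, 4), np.float32)
        f[0, 0, 0, :2] = 1.0
        f[1, 0, 0, 2:] = 1.0
        delta = channel_correlation(f, f)
        assert delta[0, 1] == 0.0 and delta[1, 0] == 0.0
        assert delta[0, 0] == 2.0 and delta[1, 1] == 2.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=(3, 1, 1, 5)).astype(np.float32)
        g = rng.normal(size=(3, 1, 1, 5)).astype(np.float32)
        ref = loop_correlation(f.reshape(3, 5).astype(float),
                               g.reshape(3, 5).astype(float))
        np.testing.assert_allclose(channel_correlation(f, g), ref, atol=1e-5)


class TestChannelSoftmax:
    def test_single_channel_gives_one(self):
        np.testing.assert_allclose(channel_softmax(np.array([[3.0]])), [[1.0]])

    def test_uniform_row_gives_uniform_weights(self):
        alpha = channel_softmax(np.full((4, 4), 2.5))
        np.testing.assert_allclose(alpha, 0.25, atol=1e-6)

    def test_log_ratio_row(self):
        alpha = channel_softmax(np.array([[0.0, np.log(3.0)]]))
        np.testing.assert_allclose(alpha, [[0.25, 0.75]], atol=1e-6)

    def test_survives_large_magnitudes(self):
        alpha = channel_softmax(np.array([[1000.0, 999.0], [-1000.0, -999.0]]))
        assert np.all(np.isfinite(alpha))
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 6), st.integers(0, 10 ** 6))
    def test_rows_always_sum_to_one(self, c, seed):
        delta = np.random.default_rng(seed).normal(0, 10, size=(c, c))
        alpha = channel_softmax(delta)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((alpha >= 0) & (alpha <= 1))


class TestGateSignal:
    def test_opposite_inputs_cancel(self):
        p = random_params(2, 2)
        p.b_h[:] = 0
        f = np.random.default_rng(0).normal(size=(2, 2, 2, 2)).astype(np.float32)
        np.testing.assert_allclose(gate_signal(f, -f, p), 0.0, atol=1e-6)

    def test_identity_projection_passes_f_through(self):
        p = identity_params(3)
        f = np.random.default_rng(1).normal(size=(3, 1, 2, 2)).astype(np.float32)
        np.testing.assert_allclose(gate_signal(f, np.zeros_like(f), p), f,
                                   atol=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        p = random_params(2, 3)
        f = rng.normal(size=(2, 1, 2, 3)).astype(np.float32)
        g = rng.normal(size=(2, 1, 2, 3)).astype(np.float32)
        ref = loop_mix(p.w_h.astype(float), p.b_h.astype(float),
                       (f + g).reshape(2, 6).astype(float))
        np.testing.assert_allclose(gate_signal(f, g, p).reshape(2, 6), ref,
                                   atol=1e-5)


class TestAttentionResponse:
    def test_identity_mixing_returns_h(self):
        h = np.random.default_rng(0).normal(size=(3, 2, 2, 1)).astype(np.float32)
        r = attention_response(np.eye(3), h)
        np.testing.assert_allclose(r, h.reshape(3, -1), atol=1e-6)

    def test_uniform_mixing_averages_channels(self):
        h = np.random.default_rng(1).normal(size=(4, 1, 1, 3)).astype(np.float32)
        r = attention_response(np.full((4, 4), 0.25), h)
        mean = h.reshape(4, -1).mean(axis=0)
        for i in range(4):
            np.testing.assert_allclose(r[i], mean, atol=1e-6)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        alpha = channel_softmax(rng.normal(size=(3, 3)))
        h = rng.normal(size=(3, 1, 2, 2)).astype(np.float32)
        ref = loop_response(alpha.astype(float), h.reshape(3, 4).astype(float))
        np.testing.assert_allclose(attention_response(alpha, h), ref, atol=1e-5)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channels"):
            attention_response(np.eye(2), np.zeros((3, 1, 1, 2), np.float32))


class TestGateWeights:
    def test_closed_forms(self):
        r = np.array([[0.0, np.log(3.0)]])
        np.testing.assert_allclose(gate_weights(r), [[0.5, 0.75]], atol=1e-6)

    def test_strictly_inside_unit_interval_and_monotone(self):
        # +/-15 keeps float32 sigmoid away from exact saturation
        r = np.linspace(-15, 15, 13).reshape(1, -1)
        omega = gate_weights(r)
        assert np.all((omega > 0) & (omega < 1))
        assert np.all(np.diff(omega[0]) > 0)


class TestApplyGateAndMerge:
    def test_unit_gate_is_identity_on_f(self):
        f = np.random.default_rng(0).normal(size=(2, 2, 2, 2)).astype(np.float32)
        y = np.zeros_like(f)
        out = apply_gate_and_merge(f, np.ones((2, 8), np.float32), y)
        np.testing.assert_allclose(out[:2], f)

    def test_half_gate_halves_f(self):
        f = np.random.default_rng(1).normal(size=(2, 1, 2, 2)).astype(np.float32)
        out = apply_gate_and_merge(f, np.full((2, 4), 0.5, np.float32),
                                   np.zeros_like(f))
        np.testing.assert_allclose(out[:2], 0.5 * f, atol=1e-6)

    def test_concat_channel_arithmetic_and_sum_mode(self):
        f = np.ones((3, 2, 2, 2), np.float32)
        y = np.full((3, 2, 2, 2), 2.0, np.float32)
        omega = np.full((3, 8), 0.5, np.float32)
        assert apply_gate_and_merge(f, omega, y).shape[0] == 6
        s = apply_gate_and_merge(f, omega, y, merge_mode="sum")
        np.testing.assert_allclose(s, 2.5)


class TestComposedGate:
    def test_zero_inputs_zero_gated_part(self):
        p = random_params(2, 0)
        p.b_f[:] = 0; p.b_g[:] = 0; p.b_h[:] = 0
        z = np.zeros((2, 2, 2, 2), np.float32)
        out = cag_forward(z, z, p)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("c,shape", [(1, (1, 2, 2)), (2, (2, 2, 2)),
                                         (3, (3, 3, 3)), (4, (1, 3, 3))])
    def test_matches_all_loop_oracle(self, c, shape):
        rng = np.random.default_rng(c)
        p = random_params(c, 10 + c)
        x = rng.normal(size=(c,) + shape).astype(np.float32)
        y = rng.normal(size=(c,) + shape).astype(np.float32)
        out = cag_forward(x, y, p)
        ref = cag_oracle(x, y, p)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_composition_equals_chained_steps(self):
        rng = np.random.default_rng(9)
        p = random_params(2, 11)
        x = rng.normal(size=(2, 2, 2, 2)).astype(np.float32)
        y = rng.normal(size=(2, 2, 2, 2)).astype(np.float32)
        f, g = project_features(x, y, p)
        alpha = channel_softmax(channel_correlation(f, g))
        omega = gate_weights(attention_response(alpha, gate_signal(f, g, p)))
        manual = apply_gate_and_merge(f, omega, y)
        np.testing.assert_allclose(cag_forward(x, y, p), manual, atol=1e-6)

    def test_gating_never_amplifies(self):
        rng = np.random.default_rng(12)
        p = random_params(3, 13)
        x = rng.normal(size=(3, 2, 2, 2)).astype(np.float32)
        y = rng.normal(size=(3, 2, 2, 2)).astype(np.float32)
        f, _ = project_features(x, y, p)
        out = cag_forward(x, y, p)
        assert np.all(np.abs(out[:3]) <= np.abs(f) + 1e-7)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        c = 3
        p = random_params(c, 22)
        x = rng.normal(size=(c, 2, 2, 2)).astype(np.float32)
        y = rng.normal(size=(c, 2, 2, 2)).astype(np.float32)
        perm = np.array([2, 0, 1])
        pp = CAGParams(
            w_f=p.w_f[np.ix_(perm, perm)], w_g=p.w_g[np.ix_(perm, perm)],
            w_h=p.w_h[np.ix_(perm, perm)], b_f=p.b_f[perm], b_g=p.b_g[perm],
            b_h=p.b_h[perm], mu=p.mu)
        out = cag_forward(x, y, p)
        out_p = cag_forward(x[perm], y[perm], pp)
        full_perm = np.concatenate([perm, perm + c])  # gated block then y block
        np.testing.assert_allclose(out_p, out[full_perm], atol=1e-5)


def test_trainable_gate_matches_functional_path():
    rng = np.random.default_rng(30)
    gate = CAGGate(2, np.random.default_rng(31))
    x = rng.normal(size=(2, 2, 2, 2)).astype(np.float32)
    y = rng.normal(size=(2, 2, 2, 2)).astype(np.float32)
    out = gate(x, y)  # numpy in -> numpy out through the Tensor path
    p = CAGParams(w_f=gate.w_f.data, w_g=gate.w_g.data, w_h=gate.w_h.data,
                  b_f=gate.b_f.data, b_g=gate.b_g.data, b_h=gate.b_h.data,
                  mu=gate.mu)
    np.testing.assert_allclose(out, cag_oracle(x, y, p), atol=1e-5)
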