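"""Architecture: LSTM cell equations, blocks, the dual module, and fusion."""

import numpy as np
import pytest

from sleepfusion.network import (
    BiLSTMBlock,
    BiLSTMBlockSpec,
    ConvBlock,
    ConvBlockSpec,
    DualModuleSpec,
    FeatureMap,
    LSTMCellParams,
    bilstm_block_forward,
    bilstm_sequence,
    build_dual_module,
    build_fusion,
    conv_block_forward,
    count_parameters,
    dual_forward,
    load_checkpoint,
    lstm_step,
    save_checkpoint,
)


def lstm_step_oracle(params, x_t, h_prev, c_prev):
    """Element-wise scalar-loop evaluation of the gate recurrence.

    Deliberately loop-based and independent of any vectorized code path.
    """
    u = params.units
    z = list(h_prev) + list(x_t)
    h_t, c_t = np.zeros(u), np.zeros(u)
    for j in range(u):
        af = ai = ao = ac = 0.0
        for m, zm in enumerate(z):
            af += params.w_f[j][m] * zm
            ai += params.w_i[j][m] * zm
            ao += params.w_o[j][m] * zm
            ac += params.w_c[j][m] * zm
        f = 1.0 / (1.0 + np.exp(-(af + params.b_f[j])))
        i = 1.0 / (1.0 + np.exp(-(ai + params.b_i[j])))
        o = 1.0 / (1.0 + np.exp(-(ao + params.b_o[j])))
        c_t[j] = f * c_prev[j] + i * np.tanh(ac + params.b_c[j])
        h_t[j] = o * np.tanh(c_t[j])
    return h_t, c_t


class TestLstmStep:
    def test_zero_fixed_point(self):
        p = LSTMCellParams.zeros(3, 2)
        h, c = lstm_step(p, np.zeros(2), np.zeros(3), np.zeros(3))
        assert np.array_equal(h, np.zeros(3))
        assert np.array_equal(c, np.zeros(3))

    def test_saturated_candidate_bias(self):
        """Zero weights, huge candidate bias: c_t -> 1/2, h_t -> tanh(1/2)/2."""
        p = LSTMCellParams.zeros(1, 1)
        p.b_c[:] = 50.0  # saturates tanh at ~1
        h, c = lstm_step(p, np.zeros(1), np.zeros(1), np.zeros(1))
        assert c[0] == pytest.approx(0.5, abs=1e-9)
        assert h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-9)
        assert h[0] == pytest.approx(0.2311, abs=1e-4)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(100):
            u = int(rng.integers(1, 5))
            d = int(rng.integers(1, 5))
            p = LSTMCellParams.random(u, d, rng, scale=1.5)
            x = rng.normal(size=d)
            h0 = rng.normal(size=u)
            c0 = rng.normal(size=u)
            h, c = lstm_step(p, x, h0, c0)
            h_ref, c_ref = lstm_step_oracle(p, x, h0, c0)
            assert np.max(np.abs(h - h_ref)) <= 1e-6
            assert np.max(np.abs(c - c_ref)) <= 1e-6

    def test_gate_and_state_bounds(self, rng):
        p = LSTMCellParams.random(4, 3, rng, scale=2.0)
        h, c = lstm_step(p, rng.normal(size=3), np.zeros(4), np.zeros(4))
        assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch_rejected(self, rng):
        p = LSTMCellParams.random(2, 3, rng)
        with pytest.raises(ValueError, match="mismatch"):
            lstm_step(p, np.zeros(5), np.zeros(2), np.zeros(2))


class TestBilstmSequence:
    def test_backward_stream_is_forward_on_reversed_input(self, rng):
        fwd = LSTMCellParams.random(3, 2, rng)
        bwd = LSTMCellParams.random(3, 2, rng)
        seq = FeatureMap(rng.normal(size=(9, 2)))
        out = bilstm_sequence(fwd, bwd, seq)
        # independent recomputation: run bwd params forward over reversed input
        h = np.zeros(3)
        c = np.zeros(3)
        states = []
        for x_t in seq.values[::-1]:
            h, c = lstm_step(bwd, x_t, h, c)
            states.append(h)
        assert np.allclose(out.backward.values, np.array(states)[::-1])

    def test_palindromic_input_symmetry(self, rng):
        params = LSTMCellParams.random(2, 1, rng)
        half = rng.normal(size=(4, 1))
        seq = FeatureMap(np.vstack([half, half[::-1]]))
        out = bilstm_sequence(params, params, seq)
        assert np.allclose(out.forward.values, out.backward.values[::-1])

    def test_length_one_sequence(self, rng):
        out = bilstm_sequence(
            LSTMCellParams.random(3, 2, rng),
            LSTMCellParams.random(3, 2, rng),
            FeatureMap(rng.normal(size=(1, 2))),
        )
        assert out.combined.values.shape == (1, 6)

    def test_all_zero_parameters_give_zero_output(self):
        out = bilstm_sequence(
            LSTMCellParams.zeros(2, 3),
            LSTMCellParams.zeros(2, 3),
            FeatureMap(np.ones((5, 3))),
        )
        assert np.allclose(out.combined.values, 0.0)


class TestConvBlock:
    def test_default_shape_3000_to_1500x32(self, rng):
        block = ConvBlock(ConvBlockSpec(filters=32), in_width=1, rng=rng)
        out = conv_block_forward(block, FeatureMap(rng.normal(size=(3000, 1))))
        assert (out.length, out.width) == (1500, 32)

    def test_outputs_nonnegative(self, rng):
        block = ConvBlock(ConvBlockSpec(filters=8), in_width=2, rng=rng)
        out = conv_block_forward(block, FeatureMap(rng.normal(size=(64, 2))))
        assert np.all(out.values >= 0.0)

    def test_delta_kernel_reduces_to_pooled_relu(self, rng):
        """Identity taps and zero bias: block = max-pool of rectified input."""
        block = ConvBlock(ConvBlockSpec(filters=1, kernel_size=3), in_width=1, rng=rng)
        for conv in (block.conv1, block.conv2):
            conv.w.data[:] = 0.0
            conv.w.data[1, 0, 0] = 1.0  # center tap passes the signal through
            conv.b.data[:] = 0.0
        x = rng.normal(size=(10, 1))
        out = conv_block_forward(block, FeatureMap(x))
        expected = np.maximum(x[:, 0], 0.0).reshape(5, 2).max(axis=1)
        assert np.allclose(out.values[:, 0], expected, atol=1e-6)

    def test_inference_deterministic(self, rng):
        block = ConvBlock(ConvBlockSpec(filters=4), in_width=1, rng=rng)
        x = FeatureMap(rng.normal(size=(100, 1)))
        a = conv_block_forward(block, x, inference=True)
        b = conv_block_forward(block, x, inference=True)
        assert np.array_equal(a.values, b.values)

    def test_too_short_input_rejected(self, rng):
        block = ConvBlock(ConvBlockSpec(filters=4), in_width=1, rng=rng)
        with pytest.raises(ValueError):
            conv_block_forward(block, FeatureMap(rng.normal(size=(1, 1))))


class TestBiLstmBlock:
    def test_shape_1500x64_to_750x32(self, rng):
        block = BiLSTMBlock(BiLSTMBlockSpec(units=16), in_width=64, rng=rng)
        out = bilstm_block_forward(block, FeatureMap(rng.normal(size=(1500, 64))))
        assert (out.length, out.width) == (750, 32)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        block = BiLSTMBlock(BiLSTMBlockSpec(units=4), in_width=3, rng=rng)
        for _ in range(20):
            out = bilstm_block_forward(
                block, FeatureMap(rng.normal(scale=3.0, size=(40, 3)))
            )
            assert np.all(np.abs(out.values) < 1.0)


class TestDualModuleSpec:
    def test_coupling_constraint_enforced(self):
        with pytest.raises(ValueError, match="2\\*units"):
            DualModuleSpec(
                channel_pair=("EEG Fpz-Cz", "EOG horizontal"),
                filters=(32, 64), units=(16, 16),
            )

    def test_two_eeg_channels_refused(self):
        with pytest.raises(ValueError, match="EEG"):
            DualModuleSpec(channel_pair=("EEG Fpz-Cz", "EEG Pz-Oz"))

    def test_two_eeg_channels_allowed_with_override(self):
        spec = DualModuleSpec(
            channel_pair=("EEG Fpz-Cz", "EEG Pz-Oz"), allow_same_family=True
        )
        assert spec.channel_pair == ("EEG Fpz-Cz", "EEG Pz-Oz")

    def test_shape_ladder_default(self):
        ladder = DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")).shape_ladder()
        assert ladder["conv"] == [1500, 750, 375, 187]
        assert ladder["bilstm"] == [750, 375, 187, 93]


@pytest.fixture(scope="module")
def reduced():
    spec = DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")).scaled(0.25)
    return build_dual_module(spec, seed=0)


class TestDualModule:

    def test_bilstm_input_widths_follow_coupling(self):
        """Level-k Bi-LSTM consumes both conv streams plus the previous level."""
        module = build_dual_module(
            DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")), seed=0
        )
        widths = [
            blk.bilstm.fwd.w.data.shape[0] - blk.spec.units
            for blk in module.bilstm_blocks
        ]
        assert widths == [64, 160, 320, 640]  # m_k + m_k + 2 u_{k-1}
        assert module.feature_width == 93 * 256

    def test_same_seed_identical_parameters(self):
        spec = DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")).scaled(0.25)
        a = build_dual_module(spec, seed=5).state_dict()
        b = build_dual_module(spec, seed=5).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_probability_simplex(self, reduced, rng):
        proba = dual_forward(reduced, rng.normal(size=(3, 3000, 2)))
        assert proba.shape == (3, 5)
        assert np.all(proba >= 0.0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_permutation_equivariance(self, reduced, rng):
        x = rng.normal(size=(4, 3000, 2))
        perm = np.array([2, 0, 3, 1])
        a = dual_forward(reduced, x)[perm]
        b = dual_forward(reduced, x[perm])
        assert np.allclose(a, b, atol=1e-6)

    def test_wrong_input_shape_rejected(self, reduced):
        with pytest.raises(ValueError, match="expected input"):
            dual_forward(reduced, np.zeros((2, 100, 2)))

    def test_checkpoint_round_trip(self, tmp_path, reduced):
        save_checkpoint(tmp_path / "ckpt", reduced)
        back = load_checkpoint(tmp_path / "ckpt")
        assert back.spec == reduced.spec
        a, b = reduced.state_dict(), back.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)


@pytest.fixture(scope="module")
def modules():
    tiny = dict(filters=(4, 8), units=(2, 4), epoch_samples=64)
    m1 = build_dual_module(
        DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal"), **tiny), seed=0
    )
    m2 = build_dual_module(
        DualModuleSpec(("EEG Fpz-Cz", "EMG submental"), **tiny), seed=1
    )
    return m1, m2


class TestFusion:

    def test_default_fusion_head_width(self):
        spec1 = DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal"))
        spec2 = DualModuleSpec(("EEG Fpz-Cz", "EMG submental"))
        m1 = build_dual_module(spec1, seed=0)
        m2 = build_dual_module(spec2, seed=1)
        fused = build_fusion(m1, m2, freeze=True, seed=2)
        assert fused.head.w.data.shape[0] == 2 * 93 * 256 == 47616

    def test_fused_probabilities_sum_to_one(self, modules, rng):
        fused = build_fusion(*modules, freeze=True, seed=2)
        p = fused.predict_proba(
            rng.normal(size=(2, 64, 2)), rng.normal(size=(2, 64, 2))
        )
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_channel_pairs_warn(self, modules):
        m1, _ = modules
        spec = DualModuleSpec(
            ("EEG Fpz-Cz", "EOG horizontal"), filters=(4, 8), units=(2, 4),
            epoch_samples=64,
        )
        m_dup = build_dual_module(spec, seed=3)
        with pytest.warns(UserWarning, match="same channel pair"):
            build_fusion(m1, m_dup, freeze=True, seed=0)

    def test_frozen_counts_exclude_backbones(self, modules):
        fused = build_fusion(*modules, freeze=True, seed=2)
        head_params = sum(p.data.size for p in fused.head.parameters())
        assert count_parameters(fused, trainable_only=True) == head_params
        assert count_parameters(fused) > head_params


class TestParameterCount:
    def test_analytic_count_for_one_level_spec(self):
        spec = DualModuleSpec(
            ("EEG Fpz-Cz", "EOG horizontal"),
            filters=(4,), units=(2,), kernel_size=3, epoch_samples=8,
        )
        module = build_dual_module(spec, seed=0)
        # two conv streams: (3*1*4+4) + (3*4*4+4) each; Bi-LSTM level 1:
        # two directions of ((2+8)*8 + 8); head: flatten 2*(2*2)=8 -> 5
        per_stream = (3 * 1 * 4 + 4) + (3 * 4 * 4 + 4)
        bilstm = 2 * ((2 + 8) * 8 + 8)
        head = 8 * 5 + 5
        assert count_parameters(module) == 2 * per_stream + bilstm + head

    def test_count_invariant_to_seed(self):
        spec = DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")).scaled(0.25)
        assert (
            count_parameters(build_dual_module(spec, seed=0))
            == count_parameters(build_dual_module(spec, seed=99))
        )


class TestSummary:
    def test_text_summary_reports_ladder_and_counts(self):
        module = build_dual_module(
            DualModuleSpec(("EEG Fpz-Cz", "EOG horizontal")).scaled(0.25), seed=0
        )
        text = module.summary()
        assert "(93, 64)" in text      # final coupled output at 1/4 scale
        assert "dense 5" in text
        assert f"{module.count_parameters():,}" in text
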