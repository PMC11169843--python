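"""Unit tests for the variant-STBP backward pass and training loops."""

import numpy as np
import pytest

import dtscnn as d
from dtscnn.training import _loss_and_grad

from helpers_oracle import scalar_grads, tape_grads


class TestLoss:
    def test_uniform_logits_give_log_n_classes(self):
        assert d.compute_loss(np.zeros((3, 10)), [0, 5, 9]) == pytest.approx(np.log(10))

    def test_two_class_closed_form(self):
        # softmax CE of logits (1, 0) with label 0: ln(1 + e^-1)
        loss = d.compute_loss(np.array([[1.0, 0.0]]), [0])
        assert loss == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-9)

    def test_confident_correct_output_drives_loss_to_zero(self):
        loss = d.compute_loss(np.array([[50.0, 0.0, 0.0]]), [0])
        assert loss < 1e-9

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            d.compute_loss(np.zeros((2, 3)), [0, 3])

    def test_gradient_is_softmax_minus_onehot_over_batch(self):
        vms = np.array([[1.0, 0.0], [0.0, 0.0]])
        _, g = _loss_and_grad(vms, [0, 1])
        p0 = np.exp(1) / (np.exp(1) + 1)
        np.testing.assert_allclose(g[0], [(p0 - 1) / 2, (1 - p0) / 2], atol=1e-12)
        np.testing.assert_allclose(g[1], [0.25, -0.25], atol=1e-12)


class TestBackwardPrimitives:
    def test_spike_gradient_sums_contributions(self):
        g = d.backward_spike(np.ones(3), 2 * np.ones(3), 3 * np.ones(3))
        np.testing.assert_array_equal(g, 6 * np.ones(3))
        np.testing.assert_array_equal(d.backward_spike(np.zeros(3)), np.zeros(3))

    def test_spike_gradient_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d.backward_spike(np.ones(3), np.ones(2))

    def test_membrane_gradient_worked_example(self):
        # v=0.6, vth0=1.0 (u=0.6, in window), vth1=0.5 (u=1.2, in window):
        # unit upstream on both pathways -> 1/1.0 + 1/0.5 = 3
        g = d.backward_membrane(np.ones(1), np.ones(1), np.array([0.6]), (1.0, 0.5))
        assert g[0] == pytest.approx(3.0)
        # upstream only on the secondary pathway -> 2
        g = d.backward_membrane(np.zeros(1), np.ones(1), np.array([0.6]), (1.0, 0.5))
        assert g[0] == pytest.approx(2.0)

    def test_membrane_far_from_both_windows_gets_no_gradient(self):
        g = d.backward_membrane(np.ones(1), np.ones(1), np.array([0.0]), (1.0, 1.0))
        assert g[0] == 0.0

    def test_threshold_gradient_worked_examples(self):
        # u = 0.8/0.5 = 1.6 falls outside the surrogate window -> no gradient
        assert d.threshold_gradient(np.ones(1), np.array([0.8]), 0.5) == 0.0
        # u = 1.2 in window: 1 * 1 * (-0.6/0.25) = -2.4
        assert d.threshold_gradient(np.ones(1), np.array([0.6]), 0.5) == pytest.approx(-2.4)

    def test_threshold_update_direction(self):
        # gradient-descent step: delta = -lr * gradient
        g = d.threshold_gradient(np.ones(1), np.array([0.6]), 0.5)
        assert -0.1 * g == pytest.approx(0.24)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            d.threshold_gradient(np.ones(1), np.ones(1), 0.0)


class TestBackpropAgainstOracles:
    """The vectorised engine against independent scalar references."""

    @pytest.mark.parametrize("arch_text,shape", [
        ("2dtc1-3fc-2fc", (1, 1, 2)),
        ("1dtc3-2fc", (2, 2, 1)),
        ("2c3-1dtc3-2fc", (2, 2, 1)),
    ])
    @pytest.mark.parametrize("timesteps", [1, 2, 3])
    def test_matches_literal_chain_rule_expansion(self, arch_text, shape, timesteps, rng):
        arch = d.parse_arch(arch_text, shape)
        params = d.init_params(arch, seed=3)
        x = rng.random((2, shape[2], shape[0], shape[1]))
        y = rng.integers(0, arch.n_classes, 2)
        _, tr = d.network_forward(arch, params, x, timesteps, trace=True)
        cfg = d.TrainConfig(timesteps=timesteps, dropout=0.0)
        g = d.backprop(arch, params, tr, y, cfg)
        loss_o, gw_o, gth_o = scalar_grads(arch, params, x, y, timesteps)
        assert g.loss == pytest.approx(loss_o, abs=1e-10)
        for li in range(len(arch.layers)):
            if g.weight_grads[li] is not None:
                np.testing.assert_allclose(g.weight_grads[li], gw_o[li], atol=1e-8)
            if g.threshold_grads[li] is not None:
                np.testing.assert_allclose(g.threshold_grads[li], gth_o[li], atol=1e-8)

    def test_standard_temporal_mode_matches_autodiff_tape(self, rng):
        """Full-STBP mode equals exact reverse-mode with surrogate partials."""
        arch = d.parse_arch("2dtc1-3fc-2fc", (1, 1, 2))
        params = d.init_params(arch, seed=5)
        x = rng.random((2, 2, 1, 1))
        y = rng.integers(0, 2, 2)
        for timesteps in (2, 3):
            _, tr = d.network_forward(arch, params, x, timesteps, trace=True)
            cfg = d.TrainConfig(timesteps=timesteps, dropout=0.0,
                                temporal_membrane_path=True)
            g = d.backprop(arch, params, tr, y, cfg)
            _, gw_o, gth_o = tape_grads(arch, params, x, y, timesteps)
            for li in range(len(arch.layers)):
                if g.weight_grads[li] is not None:
                    np.testing.assert_allclose(g.weight_grads[li], gw_o[li], atol=1e-8)
                if g.threshold_grads[li] is not None:
                    np.testing.assert_allclose(g.threshold_grads[li], gth_o[li], atol=1e-8)

    def test_single_timestep_modes_coincide(self, rng):
        """At T=1 no temporal code path runs: both modes give equal gradients."""
        arch = d.parse_arch("1dtc3-p2-2fc", (2, 2, 1))
        params = d.init_params(arch, seed=2)
        x = rng.random((3, 1, 2, 2))
        y = rng.integers(0, 2, 3)
        _, tr = d.network_forward(arch, params, x, 1, trace=True)
        g_var = d.backprop(arch, params, tr, y, d.TrainConfig(dropout=0.0))
        g_std = d.backprop(arch, params, tr, y,
                           d.TrainConfig(dropout=0.0, temporal_membrane_path=True))
        for a, b in zip(g_var.weight_grads, g_std.weight_grads):
            if a is not None:
                np.testing.assert_array_equal(a, b)
        for a, b in zip(g_var.threshold_grads, g_std.threshold_grads):
            if a is not None:
                np.testing.assert_array_equal(a, b)

    def test_degenerate_pair_collapses_to_plain_stbp(self, rng):
        """With vth1 = vth0 the dtc weight gradient equals the summed gradient
        of the matched plain conv layer carrying duplicated kernels."""
        shape = (4, 4, 1)
        arch_dt = d.parse_arch("2dtc3-4fc-2fc", shape)
        p_dt = d.init_params(arch_dt, seed=8, threshold_init=0.5)
        arch_sc = d.parse_arch("4c3-4fc-2fc", shape)
        p_sc = d.init_params(arch_sc, seed=8)
        p_sc.weights[0] = np.concatenate([p_dt.weights[0]] * 2, axis=0)
        p_sc.weights[1] = p_dt.weights[1].copy()
        p_sc.weights[2] = p_dt.weights[2].copy()
        p_sc.thresholds[0] = np.array([0.5])
        p_sc.thresholds[1] = p_dt.thresholds[1].copy()
        x = rng.random((2, 4, 4))
        y = rng.integers(0, 2, 2)
        cfg = d.TrainConfig(timesteps=2, dropout=0.0, temporal_membrane_path=True)
        _, tr_dt = d.network_forward(arch_dt, p_dt, x, 2, trace=True)
        _, tr_sc = d.network_forward(arch_sc, p_sc, x, 2, trace=True)
        g_dt = d.backprop(arch_dt, p_dt, tr_dt, y, cfg)
        g_sc = d.backprop(arch_sc, p_sc, tr_sc, y, cfg)
        np.testing.assert_allclose(
            g_dt.weight_grads[0], g_sc.weight_grads[0][:2] + g_sc.weight_grads[0][2:],
            atol=1e-10,
        )
        np.testing.assert_allclose(g_dt.weight_grads[1], g_sc.weight_grads[1], atol=1e-10)


def _toy_data(rng, n=16, n_classes=2, size=10):
    spec = d.SyntheticSpec(n_classes=n_classes, samples_per_class=n // n_classes,
                           image_size=(size, size), noise_std=0.05, seed=0)
    return d.generate_synthetic_dataset(spec)


class TestTrainStage:
    def test_zero_epochs_is_a_no_op(self, rng):
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=0)
        data = _toy_data(rng)
        out, metrics = d.train_stage(arch, params, data,
                                     d.TrainConfig(epochs=0))
        assert metrics == []
        for a, b in zip(params.weights, out.weights):
            if a is not None:
                np.testing.assert_array_equal(a, b)

    def test_learning_rate_schedule(self, rng):
        # lr 0.1 decaying 10% every 25 epochs: epoch 60 runs at 0.1 * 0.9^2
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=0)
        data = (np.zeros((2, 10, 10)), np.array([0, 1]))
        cfg = d.TrainConfig(epochs=61, lr=0.1, decay_interval=25, batch_size=2,
                            dropout=0.0)
        _, metrics = d.train_stage(arch, params, data, cfg)
        assert metrics[0]["lr"] == pytest.approx(0.1)
        assert metrics[25]["lr"] == pytest.approx(0.09)
        assert metrics[60]["lr"] == pytest.approx(0.081)

    def test_same_seed_reproduces_history_bit_for_bit(self, rng):
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=1)
        data = _toy_data(rng)
        cfg = d.TrainConfig(epochs=3, batch_size=8, seed=42)
        p_a, m_a = d.train_stage(arch, params, data, cfg)
        p_b, m_b = d.train_stage(arch, params, data, cfg)
        assert m_a == m_b
        for a, b in zip(p_a.weights, p_b.weights):
            if a is not None:
                np.testing.assert_array_equal(a, b)
        _, m_c = d.train_stage(arch, params, data,
                               d.TrainConfig(epochs=3, batch_size=8, seed=43))
        assert m_a != m_c

    def test_loss_decreases_on_separable_data(self, rng):
        arch = d.parse_arch("2dtc3-p2-8fc-2fc", (16, 16, 1))
        params = d.init_params(arch, seed=3)
        data = _toy_data(rng, n=32, size=16)
        cfg = d.TrainConfig(timesteps=3, epochs=8, batch_size=8, lr=0.05,
                            dropout=0.0, seed=7)
        _, metrics = d.train_stage(arch, params, data, cfg)
        assert metrics[-1]["loss"] < metrics[0]["loss"]

    def test_thresholds_stay_positive(self, rng):
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=4)
        data = _toy_data(rng)
        cfg = d.TrainConfig(epochs=5, batch_size=8, lr=1.0, seed=0)  # aggressive
        out, _ = d.train_stage(arch, params, data, cfg)
        for th in out.thresholds:
            if th is not None:
                assert np.all(th >= cfg.threshold_floor)

    def test_empty_data_rejected(self):
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=0)
        with pytest.raises(ValueError, match="empty"):
            d.train_stage(arch, params, (np.zeros((0, 10, 10)), np.zeros(0, int)),
                          d.TrainConfig())


class TestTwoStageTrain:
    def test_zero_epoch_retrain_keeps_pretrained_params(self, rng):
        arch = d.parse_arch("2dtc3-p2-4fc-2fc", (10, 10, 1))
        params = d.init_params(arch, seed=0)
        data = _toy_data(rng)
        cfg_pre = d.TrainConfig(timesteps=2, epochs=2, batch_size=8)
        cfg_re = d.TrainConfig(timesteps=1, epochs=0, stage="retrain")
        final, hist = d.two_stage_train(arch, params, data, cfg_pre, cfg_re)
        p1, _ = d.train_stage(arch, params, data, cfg_pre)
        assert hist["retrain"] == []
        for a, b in zip(final.weights, p1.weights):
            if a is not None:
                np.testing.assert_array_equal(a, b)


class TestTrainConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = d.TrainConfig(timesteps=5, lr=0.02, seed=9, stage="retrain",
                            temporal_membrane_path=True)
        path = tmp_path / "cfg.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert d.TrainConfig.from_file(path) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            d.TrainConfig.from_dict({"learning_rate_typo": 0.1})

    @pytest.mark.parametrize("kw", [
        {"timesteps": 0}, {"dropout": 1.0}, {"lr": 0}, {"stage": "warmup"},
        {"pooling": "median"}, {"leak": 1.5},
    ])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            d.TrainConfig(**kw)
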