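"""Tests for the feed-forward SNN: forward pass, loss, BPTT, accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delaysnn.data import generate_lag_task, pad_for_delays
from delaysnn.network import (
    NetworkConfig,
    SigmoidSpike,
    SNNModel,
    TrainingConfig,
    aggregate_readout,
    count_parameters,
    evaluate,
    load_checkpoint,
    loss,
    loss_and_delta,
    save_checkpoint,
    train,
)


def tiny_config(**kw):
    base = dict(n_in=3, hidden_sizes=(4, 4), n_out=2)
    base.update(kw)
    return NetworkConfig(**base)


class TestConfig:
    def test_exactly_two_hidden_layers(self):
        with pytest.raises(ValueError, match="two hidden"):
            NetworkConfig(n_in=3, hidden_sizes=(4, 4, 4), n_out=2)

    def test_dropout_range(self):
        with pytest.raises(ValueError, match="dropout"):
            tiny_config(dropout_rate=1.0)

    def test_delay_mode_validated(self):
        with pytest.raises(ValueError, match="delay_mode"):
            tiny_config(delay_mode="sometimes")


class TestReadoutAndLoss:
    def test_constant_readout_gives_uniform_scores(self):
        scores = aggregate_readout(np.zeros((1, 10, 4)))
        np.testing.assert_allclose(scores, 2.5)

    def test_single_timestep_reduces_to_softmax(self):
        u = np.array([[[1.0, 2.0, 0.5]]])
        e = np.exp(u[0, 0] - u[0, 0].max())
        np.testing.assert_allclose(aggregate_readout(u)[0], e / e.sum())

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10**6), st.integers(1, 20), st.integers(2, 6))
    def test_scores_sum_to_T(self, seed, T, K):
        u = np.random.default_rng(seed).normal(0, 3, (2, T, K))
        np.testing.assert_allclose(aggregate_readout(u).sum(-1), T)

    def test_uniform_scores_loss_is_log_K(self):
        scores = np.full((3, 5), 2.0)
        assert loss(scores, np.array([0, 3, 1])) == pytest.approx(np.log(5))

    def test_true_class_share_near_one_gives_near_zero_loss(self):
        scores = np.array([[1e6, 1e-6, 1e-6]])
        assert loss(scores, np.array([0])) < 1e-5

    def test_two_sample_arithmetic(self):
        # shares 0.5 and 0.25 -> (log 2 + log 4) / 2
        scores = np.array([[2.0, 2.0], [1.0, 3.0]])
        expected = (np.log(2) + np.log(4)) / 2
        assert loss(scores, np.array([0, 0])) == pytest.approx(expected)

    def test_non_finite_scores_surface_an_error(self):
        with pytest.raises(FloatingPointError):
            loss(np.array([[np.inf, 1.0]]), np.array([0]))

    def test_loss_delta_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1, (2, 4, 3))
        y = np.array([1, 2])
        _, delta = loss_and_delta(u, y)
        eps = 1e-6
        for ix in np.ndindex(u.shape):
            u[ix] += eps
            Lp = loss(aggregate_readout(u), y)
            u[ix] -= 2 * eps
            Lm = loss(aggregate_readout(u), y)
            u[ix] += eps
            assert delta[ix] == pytest.approx((Lp - Lm) / (2 * eps), abs=1e-6)


class TestForward:
    def test_silent_input_silent_network(self):
        m = SNNModel(tiny_config(), seed=0)
        u, cache = m.forward(np.zeros((2, 10, 3)))
        assert np.all(u == 0)
        assert all(s.sum() == 0 for s in cache["spikes"])

    def test_zero_delays_match_no_delay_network_bitwise(self):
        cfg_d = tiny_config(delay_mode="learnable", d_max=5)
        cfg_n = tiny_config(delay_mode="none")
        md = SNNModel(cfg_d, seed=3)
        mn = SNNModel(cfg_n, seed=99)
        for ln, ld in zip(mn.layers, md.layers):
            ln.F = ld.F.copy()
            ln.bias = ld.bias.copy()
        mn.neuron_params = [p.copy() for p in md.neuron_params]
        x = (np.random.default_rng(0).random((2, 15, 3)) < 0.5).astype(float)
        np.testing.assert_array_equal(md.forward(x)[0], mn.forward(x)[0])

    def test_input_channel_mismatch_rejected(self):
        m = SNNModel(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="batch"):
            m.forward(np.zeros((1, 10, 5)))

    def test_lif_coincidence_spikes_at_last_input_time(self):
        """Four equidistant sub-threshold inputs: the neuron fires once,
        at the arrival time of the last one (summation crosses theta)."""
        cfg = NetworkConfig(n_in=4, hidden_sizes=(1, 1), n_out=2, variant="LIF")
        m = SNNModel(cfg, seed=0)
        m.layers[0].F[:] = 4.545   # (1 - 0.9) * 4.545 = 0.4545 per spike
        m.layers[0].bias[:] = 0.0
        m.neuron_params[0].alpha[:] = 0.9
        x = np.zeros((1, 20, 4))
        times = [0, 4, 8, 12]
        for ch, t in enumerate(times):
            x[0, t, ch] = 1.0
        _, cache = m.forward(x)
        spikes = np.flatnonzero(cache["spikes"][0][0, :, 0])
        np.testing.assert_array_equal(spikes, [12])


class TestGradients:
    def test_bptt_matches_finite_differences_with_smooth_spikes(self):
        """Analytic gradients vs central differences on a 3-neuron toy net,
        with the threshold replaced by its own smooth stand-in."""
        cfg = NetworkConfig(n_in=3, hidden_sizes=(3, 3), n_out=2,
                            variant="cAdLIF", delay_mode="learnable", d_max=3)
        m = SNNModel(cfg, seed=1, spike_fn=SigmoidSpike(4.0))
        rng = np.random.default_rng(0)
        for layer in m.layers:
            layer.delays.d[:] = rng.uniform(0, 3, layer.delays.d.shape)
        x = (rng.random((2, 5, 3)) < 0.5).astype(float)
        y = np.array([0, 1])

        def total_loss():
            u, _ = m.forward(x)
            return loss(aggregate_readout(u), y)

        u, cache = m.forward(x, training=True)
        _, delta = loss_and_delta(u, y)
        grads = m.backward(delta, cache)
        eps = 1e-6
        checked = 0
        for li in range(3):
            arrays = {"F": m.layers[li].F, "bias": m.layers[li].bias}
            if li < 2:
                p = m.neuron_params[li]
                arrays.update({n: getattr(p, n) for n in p.trainable_names()})
            for name, arr in arrays.items():
                analytic = grads["layers"][li][name]
                for ix in np.ndindex(arr.shape):
                    old = arr[ix]
                    arr[ix] = old + eps
                    Lp = total_loss()
                    arr[ix] = old - eps
                    Lm = total_loss()
                    arr[ix] = old
                    fd = (Lp - Lm) / (2 * eps)
                    denom = max(abs(fd), abs(analytic[ix]), 1e-4)
                    assert abs(fd - analytic[ix]) / denom < 1e-3, (li, name, ix)
                    checked += 1
        assert checked > 50


class TestParameterAccounting:
    @pytest.mark.parametrize(
        "variant,delay_mode,millions",
        [
            ("LIF", "none", 0.30),      # weights + biases + alpha
            ("LIF", "learnable", 0.60),  # every synapse gains a delay
            ("cAdLIF", "learnable", 0.61),
        ],
    )
    def test_speech_commands_architecture_counts(self, variant, delay_mode, millions):
        cfg = NetworkConfig(n_in=40, hidden_sizes=(512, 512), n_out=35,
                            variant=variant, delay_mode=delay_mode)
        assert round(count_parameters(cfg) / 1e6, 2) == millions

    def test_frozen_delays_add_no_trainable_parameters(self):
        base = dict(n_in=40, hidden_sizes=(512, 512), n_out=35, variant="cAdLIF")
        frozen = NetworkConfig(**base, delay_mode="fixed_random")
        plain = NetworkConfig(**base, delay_mode="none")
        assert count_parameters(frozen) == count_parameters(plain)


class TestEvaluate:
    def test_silent_network_zero_spike_rate(self):
        m = SNNModel(tiny_config(), seed=0)
        X = np.zeros((4, 10, 3))
        y = np.zeros(4, dtype=int)
        _, spn = evaluate(m, (X, y))
        assert spn == 0.0

    def test_chance_accuracy_for_uninformative_model(self):
        m = SNNModel(tiny_config(n_out=4), seed=0)
        rng = np.random.default_rng(0)
        X = np.zeros((400, 5, 3))
        y = rng.integers(0, 4, 400)
        acc, _ = evaluate(m, (X, y))
        assert abs(acc - 0.25) < 0.1

    def test_empty_dataset_rejected(self):
        m = SNNModel(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(m, (np.zeros((0, 5, 3)), np.zeros(0, dtype=int)))


class TestTraining:
    def _small_task(self, seed=0):
        task = generate_lag_task(80, n_channels=3, T=20, lags=(None, 4),
                                 noise_rate=0.01, seed=seed)
        return task

    def test_frozen_delays_unchanged_by_training(self):
        task = self._small_task()
        cfg = NetworkConfig(n_in=3, hidden_sizes=(6, 6), n_out=2, variant="cAdLIF",
                            delay_mode="fixed_random", d_max=6, input_gain=5.0)
        m = SNNModel(cfg, seed=0)
        frozen = [layer.delays.d.copy() for layer in m.layers]
        X = pad_for_delays(task.inputs, 6)
        train(m, (X, task.labels), TrainingConfig(epochs=2, seed=0, batch_size=16))
        for layer, before in zip(m.layers, frozen):
            np.testing.assert_array_equal(layer.delays.d, before)

    def test_identical_seeds_identical_histories(self):
        task = self._small_task()
        hists = []
        for _ in range(2):
            cfg = NetworkConfig(n_in=3, hidden_sizes=(6, 6), n_out=2,
                                variant="LIF", delay_mode="learnable", d_max=6,
                                input_gain=5.0, dropout_rate=0.1)
            m = SNNModel(cfg, seed=7)
            X = pad_for_delays(task.inputs, 6)
            _, h = train(m, (X, task.labels),
                         TrainingConfig(epochs=3, seed=7, batch_size=16))
            hists.append(h)
        assert hists[0] == hists[1]

    def test_separable_lag_task_reaches_high_training_accuracy(self):
        """The lag task is separable by construction; 2 classes, short run."""
        task = generate_lag_task(200, n_channels=4, T=40, lags=(0, 6),
                                 noise_rate=0.01, seed=0)
        cfg = NetworkConfig(n_in=4, hidden_sizes=(16, 16), n_out=2,
                            variant="LIF", delay_mode="learnable", d_max=12,
                            input_gain=6.0)
        m = SNNModel(cfg, seed=0)
        X = pad_for_delays(task.inputs, 12)
        _, h = train(m, (X, task.labels),
                     TrainingConfig(lr_weights=5e-3, epochs=30, batch_size=32, seed=0))
        assert h["train_acc"][-1] >= 0.9


class TestCheckpoint:
    def test_round_trip_preserves_forward_pass(self, tmp_path):
        cfg = tiny_config(delay_mode="learnable", d_max=4, variant="cAdLIF")
        m = SNNModel(cfg, seed=5)
        m.layers[0].delays.d[:] = 2.0
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        x = (np.random.default_rng(0).random((2, 12, 3)) < 0.5).astype(float)
        np.testing.assert_array_equal(m.forward(x)[0], back.forward(x)[0])
        assert back.config == cfg
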