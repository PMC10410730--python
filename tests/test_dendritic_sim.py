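import numpy as np
import pytest

from dendrimod import dendritic_sim as dsim


def single_neuron_net(D=4, **kwargs):
    params = dsim.DendriticNeuronParams(n_compartments=D)
    return dsim.DendriticNetwork(params, W_ff=np.array([[1.0]]), n_ctx=1,
                                 seed=0, **kwargs)


class TestSpikeTrainSet:
    def test_sorted_by_time(self):
        s = dsim.SpikeTrainSet(ids=[2, 0, 1], times=[3.0, 1.0, 2.0])
        np.testing.assert_array_equal(s.times, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(s.ids, [0, 1, 2])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            dsim.SpikeTrainSet(ids=[0], times=[-1.0])

    def test_csv_roundtrip(self, tmp_path):
        s = dsim.SpikeTrainSet(ids=[0, 1], times=[1.5, 2.5])
        s.to_csv(tmp_path / "s.csv")
        loaded = dsim.SpikeTrainSet.from_csv(tmp_path / "s.csv")
        np.testing.assert_array_equal(loaded.times, s.times)


class TestEncoders:
    def test_zero_image_empty(self):
        s = dsim.encode_image_burst(np.zeros(10), 25.0, 15.0, seed=0)
        assert len(s) == 0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            dsim.encode_image_burst(np.array([-0.1]), 25.0, 15.0, seed=0)

    def test_count_proportional_to_intensity(self):
        pixels = np.array([0.2, 0.8, 0.5])
        rate = 20.0
        totals = [
            len(dsim.encode_image_burst(pixels, 25.0, rate, seed=s))
            for s in range(1000)
        ]
        ratio = np.mean(totals) / (rate * pixels.sum())
        assert abs(ratio - 1.0) < 0.05

    def test_seed_determinism(self):
        a = dsim.encode_image_burst(np.ones(5), 25.0, 10.0, seed=3)
        b = dsim.encode_image_burst(np.ones(5), 25.0, 10.0, seed=3)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.ids, b.ids)

    def test_context_inactive_empty(self):
        assert len(dsim.encode_context_burst(False, 15.0, seed=0)) == 0

    def test_context_mean_count(self):
        counts = [
            len(dsim.encode_context_burst(True, 50.0, seed=s))
            for s in range(1000)
        ]
        assert abs(np.mean(counts) - 60.0) < 2.0

    def test_context_time_spread(self):
        trains = [dsim.encode_context_burst(True, 100.0, seed=s)
                  for s in range(200)]
        times = np.concatenate([t.times for t in trains])
        expected_sd = 20.0 / (2 * np.sqrt(2 * np.log(2)))
        assert abs(times.std() - expected_sd) / expected_sd < 0.1


class TestSimulation:
    def test_rest_state(self):
        net = single_neuron_net()
        res = net.simulate(dsim.SpikeTrainSet.empty(),
                           dsim.SpikeTrainSet.empty(), 50.0, 0.1, record=True)
        assert np.abs(res.V_soma - net.params.soma.E_L).max() < 1e-9
        assert np.abs(res.V_dend - net.params.dendrite.E_L).max() < 1e-9
        assert len(res.output_spikes) == 0

    def test_dt_convergence(self):
        net = single_neuron_net()
        ctx = dsim.encode_context_burst(True, 15.0, seed=1)
        finals = []
        for dt in (0.1, 0.05):
            res = net.simulate(dsim.SpikeTrainSet.empty(), ctx, 80.0, dt,
                               record=True)
            finals.append(res.V_dend[-1])
        rel = np.abs(finals[0] - finals[1]) / (np.abs(finals[1]) + 1e-12)
        assert rel.max() < 0.01

    def test_modulation_increases_spike_count(self):
        net = single_neuron_net()
        rng = np.random.default_rng(0)
        times = np.clip(rng.normal(55.0, 2.5, 35), 0, None)
        ff = dsim.SpikeTrainSet(ids=np.zeros(35, int), times=times)
        ctx = dsim.encode_context_burst(True, 15.0, seed=2)
        net.w_ctx[:] = 0.0
        low = len(net.simulate(ff, ctx, 130.0, 0.1).hidden_spikes[0])
        net.w_ctx[:] = 0.9
        high = len(net.simulate(ff, ctx, 130.0, 0.1).hidden_spikes[0])
        assert high >= low
        assert high >= 1

    def test_pre_trace_decays_exponentially(self):
        net = single_neuron_net()
        ctx = dsim.SpikeTrainSet(ids=[0], times=[5.0])
        tau = 30.0
        res = net.simulate(dsim.SpikeTrainSet.empty(), ctx, 95.0, 0.05,
                           trace_taus=(tau, 30.0, 50.0))
        # one spike at t=5, trace sampled at t~95: expect exp(-90/tau)
        expected = np.exp(-90.0 / tau)
        assert res.traces["pre"][0] == pytest.approx(expected, rel=0.01)

    def test_integration_error_names_compartment(self):
        net = single_neuron_net()
        net.params.dendrite.E_L = float("nan")  # poisoned parameter
        with pytest.raises(dsim.IntegrationError, match="dendrite"):
            net.simulate(dsim.SpikeTrainSet.empty(),
                         dsim.SpikeTrainSet.empty(), 10.0, 0.1)


class TestClassifyWindow:
    def test_empty_is_target(self):
        assert dsim.classify_window(np.array([]), (10.0, 60.0)) \
            == "target_class"

    def test_edge_spike_counts_inside(self):
        assert dsim.classify_window(np.array([60.0]), (10.0, 60.0)) == "other"

    def test_spike_before_window_ignored(self):
        assert dsim.classify_window(np.array([5.0]), (10.0, 60.0)) \
            == "target_class"


class TestPlasticity:
    def _state(self, **over):
        base = dict(
            pre_trace=np.array([0.2]),
            post_trace=np.array([0.5]),
            v_dend_trace=np.full((1, 3), 0.0),
            eta=0.1,
            error=+1,
        )
        base.update(over)
        return dsim.PlasticityState(**base)

    def test_zero_error_zero_update(self):
        dw = dsim.plasticity_update(self._state(error=0))
        np.testing.assert_array_equal(dw, 0.0)

    def test_zero_pre_trace_zero_update(self):
        dw = dsim.plasticity_update(self._state(pre_trace=np.array([0.0])))
        np.testing.assert_array_equal(dw, 0.0)

    def test_zero_post_trace_zero_update(self):
        dw = dsim.plasticity_update(self._state(post_trace=np.array([0.0])))
        np.testing.assert_array_equal(dw, 0.0)

    def test_hand_product(self):
        # eta=0.1, error=+1, post=0.5, pre=0.2, phi == 1
        dw = dsim.plasticity_update(self._state(), phi=lambda v: np.ones_like(v))
        np.testing.assert_allclose(dw, 0.01)

    def test_sign_follows_error(self):
        plus = dsim.plasticity_update(self._state(error=+1))
        minus = dsim.plasticity_update(self._state(error=-1))
        np.testing.assert_allclose(plus, -minus)

    def test_phi_bounded(self):
        v = np.linspace(-120, 60, 500)
        out = dsim.phi_voltage_modulation(v)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestOnlineLearning:
    def test_eta_zero_keeps_weights(self):
        from dendrimod.experiments import encode_xor_episode
        from dendrimod.synthetic_data import gen_xor_episodes

        net = dsim.build_xor_network(seed=0)
        w_before = net.w_ctx.copy()
        proto = dsim.EpisodeProtocol()
        eps = [encode_xor_episode(e, proto)
               for e in gen_xor_episodes(10, seed=0)]
        dsim.run_online_learning(net, eps, proto,
                                 dsim.PlasticityConfig(eta=0.0))
        np.testing.assert_array_equal(net.w_ctx, w_before)

    def test_weights_clipped_to_bounds(self):
        from dendrimod.experiments import encode_xor_episode
        from dendrimod.synthetic_data import gen_xor_episodes

        net = dsim.build_xor_network(seed=0)
        proto = dsim.EpisodeProtocol()
        eps = [encode_xor_episode(e, proto)
               for e in gen_xor_episodes(30, seed=1)]
        dsim.run_online_learning(net, eps, proto,
                                 dsim.PlasticityConfig(eta=0.5))
        assert net.w_ctx.min() >= 0.0
        assert net.w_ctx.max() <= net.w_max


class TestEffectiveConductance:
    def test_passive_closed_form(self):
        net = single_neuron_net(D=3)
        p = net.params
        t, g = dsim.effective_conductance(
            net, dsim.SpikeTrainSet.empty(), [-80.0, -70.0, -60.0],
            duration=40.0)
        expected = p.soma.g_L + 3 * (
            p.dendrite.g_c * p.dendrite.g_L
            / (p.dendrite.g_L + p.dendrite.g_c))
        np.testing.assert_allclose(g, expected, atol=1e-6)

    def test_added_linear_conductance_shifts_exactly(self):
        net = single_neuron_net(D=3)
        g_s = 7.3
        _, base = dsim.effective_conductance(
            net, dsim.SpikeTrainSet.empty(), [-80.0, -60.0], duration=20.0)
        _, shifted = dsim.effective_conductance(
            net, dsim.SpikeTrainSet.empty(), [-80.0, -60.0], duration=20.0,
            extra_soma_conductance=(g_s, 0.0))
        np.testing.assert_allclose(shifted - base, g_s, atol=1e-9)

    def test_nmda_input_transient(self):
        net = single_neuron_net(D=3)
        net.w_ctx[:] = 0.8
        ctx = dsim.encode_context_burst(True, 30.0, seed=4)
        t, g = dsim.effective_conductance(
            net, ctx, [-80.0, -70.0, -60.0], duration=300.0)
        _, g0 = dsim.effective_conductance(
            net, dsim.SpikeTrainSet.empty(), [-80.0, -70.0, -60.0],
            duration=300.0)
        dev = np.abs(g - g0)
        assert dev[(t > 30) & (t < 90)].max() > 10 * dev[t < 20].max() + 1e-9
        # returns toward baseline after decay
        assert dev[-1] < 0.2 * dev.max()

    def test_needs_two_potentials(self):
        net = single_neuron_net()
        with pytest.raises(ValueError):
            dsim.effective_conductance(net, dsim.SpikeTrainSet.empty(),
                                       [-70.0])


class TestXorExperiment:
    def test_xor_initially_unsolved_then_learned(self):
        from dendrimod.experiments import run_xor_experiment

        acc, curve = run_xor_experiment(seed=1, n_train=200, n_eval=40)
        assert acc > 0.9
        # error rate improves from start to end of training
        assert curve.train_acc_ma.iloc[-1] >= curve.train_acc_ma.iloc[20]
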