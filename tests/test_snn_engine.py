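"""LIF engine: sampling, wiring, exact-integration correctness, and the
dynamical behaviors the architectures rely on."""

import numpy as np
import pytest

from snnhfo.snn_engine import (
    GI_TONIC_RATE_HZ,
    NetworkSpec,
    NeuronParams,
    SynapseParams,
    build_network,
    frequency_response,
    sample_core_params,
    simulate,
)
from snnhfo.spike_codec import SpikeTrain


def _train(times, polarity=1, duration=None):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(times, polarity * np.ones(times.size, dtype=np.int8),
                      duration=duration or (times[-1] + 0.05 if times.size else 1.0))


class TestSampling:
    def test_time_constant_ranges_hold(self):
        pairs = sample_core_params(10_000, seed=0)
        tau_exc = np.array([p[0].tau_syn_ms for p in pairs])
        tau_inh = np.array([p[1].tau_syn_ms for p in pairs])
        assert np.all((tau_exc >= 3.0) & (tau_exc <= 6.0))
        assert np.all(tau_inh > 0)
        gap = tau_exc - tau_inh
        assert np.all((gap >= 0.1) & (gap <= 1.0))

    def test_uniform_mean_of_excitatory_tau(self):
        pairs = sample_core_params(100_000, seed=1)
        mean = np.mean([p[0].tau_syn_ms for p in pairs])
        assert mean == pytest.approx(4.5, abs=0.01)

    def test_weights_signed_unit_magnitudes(self):
        pairs = sample_core_params(2000, seed=2)
        ups = {p[0].weight for p in pairs}
        dns = {p[1].weight for p in pairs}
        assert ups == {1.0, 2.0}
        assert dns == {-1.0, -2.0}

    def test_per_neuron_substreams_stable_under_n(self):
        small = sample_core_params(10, seed=3)
        large = sample_core_params(200, seed=3)
        assert small == large[:10]

    def test_inhibitory_tau_is_exc_minus_gap(self):
        # the documented example: tau_exc 3.5 ms with gap 0.2 -> 3.3 ms
        exc = SynapseParams(1.0, 3.5, "exc")
        inh = SynapseParams(-1.0, 3.5 - 0.2, "inh")
        assert inh.tau_syn_ms == pytest.approx(3.3)


class TestBuild:
    def test_core_connection_count_four_trains(self):
        net = build_network("core", n_second_layer=256, seed=0)
        assert net.n_neurons == 256
        assert len(net.ext_connections) == 4 * 256
        assert len(net.rec_connections) == 0

    def test_inband_adds_two_neurons_and_circuit(self):
        core = build_network("core", ["FR_UP", "FR_DN"], 256, seed=0)
        full = build_network("core+inband", ["FR_UP", "FR_DN"], 256, seed=0)
        assert full.n_neurons - core.n_neurons == 2
        # 2 extra excitatory input taps + (dis->gi) + 256 (gi->layer)
        extra_ext = len(full.ext_connections) - len(core.ext_connections)
        assert extra_ext == 2
        assert len(full.rec_connections) == 1 + 256
        dis = full.populations["dis_inhibitory"][0]
        gi = full.populations["global_inhibitory"][0]
        taps = [c for c in full.ext_connections if c[1] == dis]
        assert all(c[2] == 3.0 and c[3] == 5.0 for c in taps)
        dg = [c for c in full.rec_connections if c[0] == dis and c[1] == gi]
        assert dg[0][2:] == (-2.5, 20.0)
        gl = [c for c in full.rec_connections if c[0] == gi]
        assert len(gl) == 256  # global inhibition reaches every layer neuron
        assert all(c[2] == -2.5 and c[3] == 5.0 for c in gl)

    def test_artifact_subnet_shares_core_sampling_ranges(self):
        net = build_network("core+inband+artifact", ["ripple_UP", "ripple_DN"],
                            64, seed=0)
        sub = net.artifact_subnet
        assert sub is not None and sub.architecture == "core"
        assert sub.input_map == ["artifact_UP", "artifact_DN"]
        exc_taus = [c[3] for c in sub.ext_connections if c[2] > 0]
        assert all(3.0 <= t <= 6.0 for t in exc_taus)

    def test_unknown_architecture(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_network("resnet")

    def test_up_exc_dn_inh_polarity(self):
        net = build_network("core", ["ripple_UP", "ripple_DN"], 32, seed=4)
        for ti, name in enumerate(net.input_map):
            ws = [c[2] for c in net.ext_connections if c[0] == ti]
            assert all(w > 0 for w in ws) if name.endswith("_UP") else \
                all(w < 0 for w in ws)

    def test_yaml_replay_roundtrip(self, tmp_path):
        net = build_network("core+inband+artifact", ["ripple_UP", "ripple_DN"],
                            16, seed=5)
        path = tmp_path / "net.yaml"
        net.to_yaml(path)
        back = NetworkSpec.from_yaml(path)
        assert back.ext_connections == net.ext_connections
        assert back.neurons == net.neurons
        assert back.artifact_subnet.ext_connections == \
            net.artifact_subnet.ext_connections


class TestSimulate:
    def test_silent_inputs_silent_network(self):
        net = build_network("core", ["a_UP", "a_DN"], 16, seed=0)
        res = simulate(net, {"a_UP": _train([]), "a_DN": _train([], -1)},
                       span=0.5)
        assert res.spike_times.size == 0

    def test_shot_noise_mean_current(self):
        """Time-averaged drive of a Poisson-driven exponential synapse is
        weight x rate x tau, read off the membrane of a non-spiking
        neuron (whose time-average equals the mean current)."""
        w, tau_ms, rate = 2.0, 4.5, 500.0
        rng = np.random.default_rng(7)
        times = np.cumsum(rng.exponential(1 / rate, size=int(rate * 25)))
        times = times[times < 20.0]
        assert times.size >= 1e4 / 2  # enough events for 5% accuracy
        net = NetworkSpec("probe", ["p_UP"], 1,
                          [NeuronParams(threshold=1e12)],
                          [(0, 0, w, tau_ms)], [], {"second_layer": [0]}, 0)
        res = simulate(net, {"p_UP": _train(times, duration=20.0)},
                       span=20.0, record=[0])
        trace = res.traces[0]
        mean_m = trace[trace.size // 4:].mean()
        assert mean_m == pytest.approx(w * rate * tau_ms * 1e-3, rel=0.05)

    def test_trajectory_matches_event_driven_closed_form(self):
        """Exact event-driven integration (analytic exponentials between
        spikes) agrees with the engine to ~machine precision."""
        dt_ms = 0.05
        neuron = NeuronParams(tau_mem_ms=15.0, threshold=1e12,
                              tonic_drive=0.3)
        conns = [(0, 0, 1.5, 4.0), (1, 0, -2.0, 3.2)]
        net = NetworkSpec("probe", ["e_UP", "i_DN"], 1, [neuron],
                          conns, [], {"second_layer": [0]}, 0)
        spike_times = {0: [0.0100, 0.0150, 0.0225], 1: [0.0175]}
        res = simulate(net, {"e_UP": _train(spike_times[0], duration=0.06),
                             "i_DN": _train(spike_times[1], -1, duration=0.06)},
                       dt_ms=dt_ms, span=0.06, record=[0])
        trace = res.traces[0]

        # independent oracle: piecewise-analytic propagation
        dt = dt_ms * 1e-3
        tau_m = 0.015
        taus = [0.004, 0.0032]
        T = 0.3
        deliveries = {int(round(t / dt)): (c, w)
                      for c, (src, _, w, _) in enumerate(conns)
                      for t in spike_times[src]}
        m, I = 0.0, [0.0, 0.0]
        expected = np.empty(trace.size)
        for step in range(trace.size):
            if step in deliveries:
                c, w = deliveries[step]
                I[c] += w
            A = [I[c] * taus[c] / (taus[c] - tau_m) for c in range(2)]
            em = np.exp(-dt / tau_m)
            m = T + (m - T - sum(A)) * em + sum(
                A[c] * np.exp(-dt / taus[c]) for c in range(2))
            I = [I[c] * np.exp(-dt / taus[c]) for c in range(2)]
            expected[step] = m
        rel = np.abs(trace - expected).max() / np.abs(expected).max()
        assert rel <= 1e-6

    def test_seed_determinism_of_rasters(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 2.0, 400))
        for _ in range(2):
            net = build_network("core", ["a_UP", "a_DN"], 64, seed=9)
            r = simulate(net, {"a_UP": _train(times, duration=2.0),
                               "a_DN": _train(times + 1e-3, -1, duration=2.0)},
                         span=2.0)
            sig = (r.spike_times.tobytes(), r.spike_neurons.tobytes())
            if _ == 0:
                first = sig
        assert sig == first

    def test_global_inhibitory_tonic_rate(self):
        net = build_network("core+inband", ["a_UP", "a_DN"], 8, seed=0)
        res = simulate(net, {"a_UP": _train([]), "a_DN": _train([], -1)},
                       span=2.0)
        gi = net.populations["global_inhibitory"][0]
        rate = res.spikes_of(gi).size / 2.0
        assert rate == pytest.approx(GI_TONIC_RATE_HZ, rel=0.05)

    def test_dis_inhibition_silences_global_inhibitory(self):
        """A dense UP+DN burst suppresses the tonically firing
        global-inhibitory neuron via the dis-inhibitory path."""
        net = build_network("core+inband", ["a_UP", "a_DN"], 8, seed=0)
        burst = np.arange(1.0, 1.5, 0.5e-3)
        res = simulate(net, {"a_UP": _train(burst, duration=2.0),
                             "a_DN": _train(burst + 0.25e-3, -1, duration=2.0)},
                       span=2.0)
        gi_t = res.spikes_of(net.populations["global_inhibitory"][0])
        before = ((gi_t >= 0.4) & (gi_t < 0.9)).sum() / 0.5
        during = ((gi_t >= 1.05) & (gi_t < 1.5)).sum() / 0.45
        assert before == pytest.approx(GI_TONIC_RATE_HZ, rel=0.1)
        assert during < 0.2 * before

    def test_nan_state_aborts_with_diagnostic(self):
        net = NetworkSpec("probe", ["p_UP"], 1, [NeuronParams(threshold=1e12)],
                          [(0, 0, 1e308, 4.0)], [], {"second_layer": [0]}, 0)
        with pytest.raises(FloatingPointError, match="neuron 0"):
            simulate(net, {"p_UP": _train([0.01, 0.0101, 0.0102],
                                          duration=0.2)}, span=0.2)

    def test_dt_above_limit_rejected(self):
        net = build_network("core", ["a_UP", "a_DN"], 4, seed=0)
        with pytest.raises(ValueError, match="dt"):
            simulate(net, {"a_UP": _train([0.1]), "a_DN": _train([0.2], -1)},
                     dt_ms=0.5, span=1.0)


class TestFrequencyResponse:
    # probe neuron: low threshold so a single band-tuned synapse pair
    # exposes its selectivity; inhibitory tau shorter by the top of the
    # sampled gap range
    EXC = SynapseParams(2.0, 4.5, "exc")
    INH = SynapseParams(-2.0, 3.5, "inh")
    NEURON = NeuronParams(threshold=0.4)

    def test_responds_to_ripple_isi_not_slow(self):
        fast = frequency_response(self.EXC, self.INH,
                                  np.array([2e-3, 4e-3, 6e-3]),
                                  neuron=self.NEURON)
        slow = frequency_response(self.EXC, self.INH, np.array([50e-3]),
                                  neuron=self.NEURON)
        assert np.all(fast >= 1)
        assert slow[0] == 0

    def test_zero_weights_flat_zero(self):
        counts = frequency_response(
            SynapseParams(1e-12, 4.5, "exc"), SynapseParams(-1e-12, 4.0, "inh"),
            np.array([2e-3, 10e-3, 50e-3]))
        assert np.all(counts == 0)

    def test_selectivity_shifts_with_tau(self):
        """Smaller excitatory tau -> tuning concentrated at shorter
        periods: the count-weighted mean response period grows with
        tau."""
        periods = np.linspace(1e-3, 30e-3, 30)
        centroids = []
        for tau in (3.0, 4.5, 6.0):
            counts = frequency_response(
                SynapseParams(2.0, tau, "exc"),
                SynapseParams(-2.0, tau - 1.0, "inh"),
                periods, neuron=self.NEURON)
            assert counts.sum() > 0
            centroids.append(np.average(periods, weights=counts))
        assert centroids[0] <= centroids[1] <= centroids[2]
        assert centroids[0] < centroids[2]
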