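"""Calyx transmission: release statistics, plasticity, AMPA kinetics."""

import numpy as np
import pytest

from magsim.synapse import (AMPAParams, AMPAState, ReleaseParams, ReleaseState,
                            ampa_kernel, epsc_trace, synaptic_conductance)


class TestRelease:
    def test_no_ap_no_release(self):
        g = synaptic_conductance([np.zeros(0)], 50.0)
        assert np.all(g == 0.0)

    def test_single_ap_expected_release_count(self):
        params = ReleaseParams()
        st = ReleaseState(params)
        n, t_rel = st.on_presynaptic_spike(1.0)
        p_hat = params.single_ap_release_probability()
        assert np.isclose(n, 500 * p_hat)
        assert np.isclose(t_rel, 1.0 + params.delay)

    def test_single_ap_stochastic_within_binomial_bounds(self):
        params = ReleaseParams()
        p_hat = params.single_ap_release_probability()
        counts = []
        for seed in range(60):
            st = ReleaseState(params, mode="stochastic",
                              rng=np.random.default_rng(seed))
            counts.append(st.on_presynaptic_spike(1.0)[0])
        mean = np.mean(counts)
        se = np.sqrt(500 * p_hat * (1 - p_hat) / len(counts))
        assert abs(mean - 500 * p_hat) < 3 * se

    def test_paired_pulse_facilitation_then_train_depression(self):
        g = synaptic_conductance([np.array([1.0, 6.0])], 30.0)
        i = epsc_trace(g[:, 0])
        t = np.arange(len(i)) * 0.005
        a1 = -(i[(t >= 1.0) & (t < 6.0)]).min()
        a2 = -(i[(t >= 6.0) & (t < 11.0)]).min()
        assert a2 > a1                                     # facilitation at 5 ms
        aps = np.arange(20) * 10.0 + 1.0                   # 100 Hz train
        g3 = synaptic_conductance([aps], 230.0)
        i3 = epsc_trace(g3[:, 0])
        t3 = np.arange(len(i3)) * 0.005
        peaks = np.array([-(i3[(t3 >= ta) & (t3 < ta + 9.9)]).min() for ta in aps])
        assert peaks[1] > peaks[0]                         # initial facilitation
        assert peaks[-1] < 0.8 * peaks.max()               # late depression

    def test_release_probability_bounded_under_any_history(self):
        rng = np.random.default_rng(4)
        st = ReleaseState(ReleaseParams(ca_scale=2.5))      # elevated calcium
        t = 0.0
        for _ in range(200):
            t += rng.uniform(0.1, 20.0)
            n, _ = st.on_presynaptic_spike(t)
            assert 0.0 <= n <= 500.0
            assert 0.0 <= st.occupancy <= 1.0
            assert 0.0 <= st.slow_gate <= 1.0

    def test_deterministic_matches_stochastic_mean(self):
        gd = synaptic_conductance([np.array([1.0])], 10.0)
        peaks = [synaptic_conductance([np.array([1.0])], 10.0, mode="stochastic",
                                      seed=s).max() for s in range(100)]
        se = np.std(peaks) / np.sqrt(len(peaks))
        assert abs(np.mean(peaks) - gd.max()) < 3 * se


class TestAMPA:
    def test_occupancies_sum_to_one_after_many_random_steps(self):
        rng = np.random.default_rng(0)
        st = AMPAState()
        on = rng.random(10_000) < 0.3
        for k in range(1_000_000):
            st.step(0.005, bool(on[k % len(on)]))
            if k % 100_000 == 0:
                assert abs(st.occ.sum() - 1.0) < 1e-9
        assert abs(st.occ.sum() - 1.0) < 1e-9
        assert np.all(st.occ >= -1e-12)

    def test_transmitter_off_from_rest_is_absorbing(self):
        st = AMPAState()
        for _ in range(1000):
            st.step(0.005, False)
        assert np.allclose(st.occ, [1, 0, 0, 0, 0, 0], atol=1e-12)

    def test_zero_driving_force_zero_current(self):
        st = AMPAState()
        for _ in range(200):
            st.step(0.005, True)
        assert st.open_fraction > 0.0
        assert st.current(0.0) == 0.0

    def test_kernel_shape(self):
        k = ampa_kernel()
        assert k.max() > 0.3
        assert k[-1] < 0.02 * k.max()        # decays back toward rest

    def test_desensitized_state_reached_from_open(self):
        st = AMPAState()
        for _ in range(2000):                # 10 ms transmitter
            st.step(0.005, True)
        assert st.occ[5] > 0.2               # D populated under sustained transmitter


class TestEPSC:
    def test_single_ap_epsc_exceeds_one_nA_at_clamp(self):
        g = synaptic_conductance([np.array([1.0])], 20.0)
        i = epsc_trace(g[:, 0], v_hold=-70.0)
        assert -i.min() > 1.0

    def test_calyx_to_soma_delay(self):
        g = synaptic_conductance([np.array([1.0])], 20.0)
        i = epsc_trace(g[:, 0])
        t = np.arange(len(i)) * 0.005
        delay = t[np.argmin(i)] - 1.0
        assert 0.5 < delay < 0.8
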