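"""Cable solver: resting equilibrium, AP propagation, analytic limits,
charge conservation, spike detection."""

from types import SimpleNamespace

import numpy as np
import pytest

from magsim.cable import (CellTemplate, CurrentPulse, MembraneParams, Stimuli,
                          detect_spikes, run_simulation, _axial_apply)
from magsim.morphology import CompartmentTree


def uniform_passive_cable(n=140, seg=25.0, diam=2.0, g_leak=1e-4, ra=100.0):
    """Sealed-end uniform passive cable along +x (leak only, no myelin)."""
    x = np.arange(n + 1) * seg
    tree = CompartmentTree(
        parent=np.arange(-1, n - 1),
        prox=np.column_stack([x[:-1], np.zeros(n), np.zeros(n)]),
        dist=np.column_stack([x[1:], np.zeros(n), np.zeros(n)]),
        diameter=np.full(n, diam),
        label=np.full(n, "node", dtype="<U20"),
        section_id=np.arange(n),
    )
    mp = MembraneParams(ra=ra, densities={"node": {"leak": g_leak}},
                        q10_cond=1.0, v_init=-65.0)
    return CellTemplate(tree, mp)


class TestRestAndAP:
    def test_resting_equilibrium(self, gbc_template):
        tr = run_simulation(gbc_template, Stimuli(), duration=5.0)
        dv = np.diff(tr.v[:, :, 0], axis=0) / 0.025
        assert np.abs(dv).max() < 0.01        # mV/ms

    def test_ap_conduction_velocity_and_amplitude(self, gbc_template):
        tpl = gbc_template
        stim = Stimuli(current=[CurrentPulse(tpl.indices("soma"), 20.0, 0.5, 0.25)])
        tr = run_simulation(tpl, stim, duration=4.0)
        t1 = detect_spikes(tr, tpl.node_from_is(1))
        t16 = detect_spikes(tr, tpl.node_from_is(16))
        assert len(t1) == len(t16) == 1
        dist_mm = (200.0 * 8 + 180 + 150 + 120 + 95 + 75 + 60 + 50 + 15) * 1e-3
        cv = dist_mm / (t16[0] - t1[0])
        assert 5.0 <= cv <= 10.0
        v = tr.v[:, tpl.node_from_is(8), 0]
        assert v.max() - v[0] > 60.0
        # depolarization width near the 0.1 ms scale
        half = v[0] + 0.5 * (v.max() - v[0])
        width = 0.025 * np.count_nonzero(v >= half)
        assert width < 0.5

    def test_reliable_following_100_and_200_Hz(self, gbc_template):
        tpl = gbc_template
        for hz in (100, 200):
            stim = Stimuli(current=[CurrentPulse(tpl.indices("soma"), 20.0, 1.0,
                                                 0.25, period=1000.0 / hz, n_pulses=5)])
            tr = run_simulation(tpl, stim, duration=1.0 + 5000.0 / hz)
            assert len(detect_spikes(tr, tpl.node_from_is(7))) == 5

    def test_mntb_brief_pulse_following(self, mntb_template):
        tpl = mntb_template
        det = int(tpl.indices("mntb_node")[-1])
        stim = Stimuli(current=[CurrentPulse(tpl.indices("mntb_soma"), 0.5, 1.0,
                                             0.25, period=10.0, n_pulses=5)])
        tr = run_simulation(tpl, stim, duration=51.0)
        assert len(detect_spikes(tr, det)) == 5

    def test_refractory_two_pulses_at_most_two_spikes(self, gbc_template):
        tpl = gbc_template
        soma = tpl.indices("soma")
        # rough single-pulse threshold
        thr = None
        for amp in (1.0, 2.0, 4.0, 8.0, 16.0):
            tr = run_simulation(tpl, Stimuli(current=[CurrentPulse(soma, amp, 0.5, 0.25)]),
                                duration=4.0)
            if len(detect_spikes(tr, tpl.node_from_is(7))):
                thr = amp
                break
        assert thr is not None
        stim = Stimuli(current=[CurrentPulse(soma, 1.2 * thr, 0.5, 0.25,
                                             period=2.0, n_pulses=2)])
        tr = run_simulation(tpl, stim, duration=7.0)
        assert len(detect_spikes(tr, tpl.node_from_is(7))) <= 2

    def test_time_step_convergence(self, gbc_template):
        tpl = gbc_template
        stim = Stimuli(current=[CurrentPulse(tpl.indices("soma"), 20.0, 0.2, 0.25)])
        runs = {dt: run_simulation(tpl, stim, duration=1.2, dt=dt)
                for dt in (0.0025, 0.00125, 0.000625)}
        d_half = np.abs(runs[0.00125].v - runs[0.000625].v).max()
        d_full = np.abs(runs[0.0025].v - runs[0.000625].v).max()
        assert d_half < 0.5
        assert d_full / d_half > 2.5        # at least second-order convergence


class TestPassiveLimits:
    def test_steady_state_attenuation_matches_analytic(self):
        tpl = uniform_passive_cable()
        stim = Stimuli(current=[CurrentPulse(np.array([0]), 0.1, 0.0, 1e9)])
        tr = run_simulation(tpl, stim, duration=80.0, dt=0.025)
        v = tr.v[-1, :, 0] - (-65.0)
        x = tpl.midpoints[:, 0]
        lam = np.sqrt((tpl.tree.diameter[0] * 1e-4) / (4.0 * tpl.membrane.ra * 1e-4))
        lam_um = lam * 1e4
        sel = (x > 150) & (x < 1500)        # away from injection end and far seal
        ratio = v[sel] / v[sel][0]
        expected = np.exp(-(x[sel] - x[sel][0]) / lam_um)
        assert np.max(np.abs(ratio / expected - 1.0)) < 0.01

    def test_charge_conservation_per_step(self):
        """The discrete theta-method balance holds to 1e-6 relative per step."""
        tpl = uniform_passive_cable(n=40)
        stim = Stimuli(current=[CurrentPulse(np.array([0]), 0.5, 0.2, 0.6)])
        dt = 0.025
        tr = run_simulation(tpl, stim, duration=2.0, dt=dt, record_dt=dt)
        g_leak = tpl.g_abs["leak"][:, None]
        e_l = tpl.membrane.e_rev["leak"]
        cm = tpl.cm_nF[:, None]
        worst = 0.0
        for k in range(1, len(tr.t)):
            v0 = tr.v[k - 1].astype(float)
            v1 = tr.v[k].astype(float)
            vm = 0.5 * (v0 + v1)
            i_inj = np.zeros_like(v0)
            tmid = tr.t[k - 1] + dt / 2
            for cp in stim.current:
                if cp.active(tmid):
                    i_inj[cp.comps] += cp.amplitude
            resid = cm * (v1 - v0) / dt + g_leak * (vm - e_l) \
                - _axial_apply(tpl, vm) - i_inj
            worst = max(worst, np.abs(resid).max())
        # relative to the 0.5 nA injected current driving the dynamics
        assert worst / 0.5 < 1e-6

    def test_kirchhoff_sum_of_membrane_currents(self, gbc_template):
        tpl = gbc_template
        stim = Stimuli(current=[CurrentPulse(tpl.indices("soma"), 5.0, 0.2, 0.5)])
        tr = run_simulation(tpl, stim, duration=1.5)
        total = tr.i_m[:, :, 0].sum(axis=1)
        inj = np.array([5.0 if stim.current[0].active(t) else 0.0 for t in tr.t])
        # membrane currents of the whole cell balance the injected current
        assert np.abs(total - inj).max() < 1e-6


class TestDetectSpikes:
    def _trace(self, t, v):
        return SimpleNamespace(t=t, v=v[:, None, None])

    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 10, 0.025)
        tr = self._trace(t, np.full_like(t, -64.0))
        assert len(detect_spikes(tr, 0)) == 0

    def test_triangular_wave_crossings_interpolated(self):
        t = np.arange(0.0, 12.0, 0.025)
        # two triangular depolarizations peaking at t=2 and t=7
        v = np.full_like(t, -60.0)
        for peak in (2.0, 7.0):
            tri = 50.0 * np.maximum(0.0, 1.0 - np.abs(t - peak) / 1.0)
            v = np.maximum(v, -60.0 + tri)
        times = detect_spikes(self._trace(t, v), 0, threshold=-20.0)
        # -60 + 50(1-|t-peak|) = -20  =>  |t-peak| = 0.2
        assert np.allclose(times, [1.8, 6.8], atol=0.013)

    def test_refractory_lockout_merges_close_crossings(self):
        t = np.arange(0.0, 3.0, 0.025)
        v = np.where((t * 10).astype(int) % 2 == 0, 0.0, -50.0)   # 0.1 ms chatter
        times = detect_spikes(self._trace(t, v), 0, refractory=1.0)
        assert len(times) <= 3

    def test_zero_duration_protocol(self, gbc_template):
        tr = run_simulation(gbc_template, Stimuli(), duration=0.0)
        assert tr.v.shape[0] == 0
        assert len(detect_spikes(tr, 0)) == 0

    def test_default_detection_node_is_7th_from_initial_segment(self, gbc_template):
        nodes = gbc_template.node_compartments()
        assert gbc_template.node_from_is(7) == nodes[6]
        assert gbc_template.node_from_calyx(6) == nodes[-6]
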