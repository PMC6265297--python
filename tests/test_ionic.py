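"""Leak subtraction, G-V extraction, Boltzmann fits, ddG and tail kinetics."""

import numpy as np
import pytest

import gatingkit as gk
from gatingkit.constants import InvalidParameterError


def _no_channel_scheme():
    return gk.build_two_state_scheme(z=3.4, Vd=-25.9, N=0.0)


class TestPOverNSubtract:
    def test_noiseless_linear_cell_cancels_to_machine_precision(self, gv_protocol):
        scheme = _no_channel_scheme()
        cell = gk.CellModel(C_lin=0.3, tau_clamp=0.25, g_leak=2.0, E_leak=-10.0, noise_sd=0.0)
        test = gk.simulate_sweeps(scheme, gv_protocol, cell)
        subs = gk.simulate_p_over_n(scheme, gv_protocol, cell, n=8)
        corrected = gk.p_over_n_subtract(test, subs, n=8)
        assert np.abs(corrected.traces).max() < 1e-10

    def test_noisy_linear_cell_residual_at_noise_scale(self, gv_protocol):
        scheme = _no_channel_scheme()
        sd = 0.05
        cell = gk.CellModel(C_lin=0.3, tau_clamp=0.25, g_leak=2.0, E_leak=-10.0,
                            noise_sd=sd, seed=7)
        test = gk.simulate_sweeps(scheme, gv_protocol, cell)
        subs = gk.simulate_p_over_n(scheme, gv_protocol, cell, n=8)
        corrected = gk.p_over_n_subtract(test, subs, n=8)
        # time-mean of each subtracted trace is noise-limited: per-sample sd is
        # sd*sqrt(1+n), plus the shared pre-baseline alignment noise
        n_samp = corrected.traces.shape[1]
        n_pre = int(corrected.segment_mask("pre").sum())
        sd_mean = sd * np.sqrt(9.0 / n_samp + 9.0 / n_pre)
        assert np.abs(corrected.traces.mean(axis=1)).max() < 4 * sd_mean

    def test_channel_current_survives_subtraction(self, wt_scheme, gv_protocol, artifact_cell, clean_cell):
        test = gk.simulate_sweeps(wt_scheme, gv_protocol, artifact_cell)
        # subpulses from a hyperpolarized holding level keep channels shut
        subs = gk.simulate_p_over_n(wt_scheme, gv_protocol, artifact_cell, n=8, subpulse_hold=-120.0)
        corrected = gk.p_over_n_subtract(test, subs, n=8)
        bare = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        # steady-state current at the most depolarized step
        mask = corrected.segment_mask("step")
        i_corr = corrected.traces[-1][mask][-20:].mean()
        i_bare = bare.traces[-1][mask][-20:].mean()
        assert i_corr == pytest.approx(i_bare, rel=0.01)

    def test_mismatched_protocols_rejected(self, wt_scheme, gv_protocol, clean_cell):
        test = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        other = gk.VoltageProtocol(V_hold=-80.0, step_voltages=(0.0,), V_tail=-50.0)
        sub = gk.simulate_sweeps(wt_scheme, other, clean_cell)
        with pytest.raises(InvalidParameterError):
            gk.p_over_n_subtract(test, [sub], n=8)


class TestTailAmplitude:
    def test_zero_trace_gives_zero(self):
        t = np.arange(0, 40, 0.1)
        assert gk.tail_window_amplitude(t, np.zeros_like(t), 10.0) == 0.0

    def test_exponential_window_mean_closed_form(self):
        # mean over [2,4] ms of A exp(-t/tau): (A tau/2)(e^{-2/tau}-e^{-4/tau})
        # = -3.7102 uA for A=-5, tau=10 (independent quadrature cross-check)
        t = np.arange(0.0, 200.0, 0.001)
        trace = -5.0 * np.exp(-t / 10.0)
        got = gk.tail_window_amplitude(t, trace, 0.0, window=(2.0, 4.0), baseline_frac=0.05)
        expected = -5.0 * (10.0 / 2.0) * (np.exp(-0.2) - np.exp(-0.4))
        assert expected == pytest.approx(-3.7102, abs=5e-4)
        assert got == pytest.approx(expected, abs=2e-3)

    def test_non_deactivating_trace_returns_full_amplitude(self):
        t = np.arange(0.0, 40.0, 0.1)
        trace = np.full_like(t, -5.0)
        # constant trace: window mean equals amplitude once baseline is zero
        got = gk.tail_window_amplitude(t, trace + 5.0, 10.0)
        assert got == 0.0
        slow = -5.0 * np.exp(-t / 1e9)
        assert gk.tail_window_amplitude(t, slow, 10.0) == pytest.approx(0.0, abs=1e-6)

    def test_window_beyond_trace_rejected(self):
        t = np.arange(0.0, 5.0, 0.1)
        with pytest.raises(InvalidParameterError):
            gk.tail_window_amplitude(t, np.zeros_like(t), 4.0)


class TestGVConstruction:
    def test_tail_gv_matches_floor_referenced_po(self, wt_scheme, gv_protocol, clean_cell):
        sw = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        curve = gk.gv_from_tails(sw)
        po = wt_scheme.po_eq(np.asarray(curve.voltages))
        floor = wt_scheme.po_eq(gv_protocol.V_tail)
        expected = (po - floor) / (po[-1] - floor)
        assert np.abs(curve.values - expected).max() < 1.5e-3

    def test_most_depolarized_step_normalizes_to_one(self, wt_scheme, gv_protocol, clean_cell):
        sw = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        assert gk.gv_from_tails(sw).values[-1] == pytest.approx(1.0)

    def test_conductance_scale_invariance(self, gv_protocol, clean_cell):
        a = gk.build_two_state_scheme(z=3.4, Vd=-25.9, gamma=1e-13)
        b = gk.build_two_state_scheme(z=3.4, Vd=-25.9, gamma=2e-13)
        ca = gk.gv_from_tails(gk.simulate_sweeps(a, gv_protocol, clean_cell))
        cb = gk.gv_from_tails(gk.simulate_sweeps(b, gv_protocol, clean_cell))
        assert np.allclose(ca.values, cb.values, atol=1e-12)

    def test_chord_and_tail_agree_for_clean_truth(self, wt_scheme, gv_protocol, clean_cell):
        sw = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        tail = gk.gv_from_tails(sw)
        chord = gk.gv_from_chord(sw, Vrev=0.0)
        po = {v: wt_scheme.po_eq(float(v)) for v in chord.voltages}
        top = wt_scheme.po_eq(60.0)
        # chord estimates Po directly (no tail floor referencing)
        for v, y in zip(chord.voltages, chord.values):
            assert y == pytest.approx(po[v] / top, abs=8e-3)

    def test_chord_excludes_near_reversal_steps(self, wt_scheme, gv_protocol, clean_cell):
        sw = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        chord = gk.gv_from_chord(sw, Vrev=0.0, exclude_mV=5.0)
        assert np.all(np.abs(chord.voltages) > 5.0)
        assert np.all(np.isfinite(chord.values))

    def test_no_expression_raises(self, gv_protocol, clean_cell):
        sw = gk.simulate_sweeps(_no_channel_scheme(), gv_protocol, clean_cell)
        with pytest.raises(InvalidParameterError, match="expression"):
            gk.gv_from_tails(sw)

    def test_ohmic_open_channel_chord_is_flat(self, clean_cell):
        always_open = gk.build_two_state_scheme(z=3.0, Vd=-500.0)  # Po ~ 1 everywhere
        # hold at the reversal potential so the standing open-channel current
        # is zero and the pre-pulse baseline is clean
        proto = gk.VoltageProtocol(
            V_hold=0.0, step_voltages=tuple(np.arange(-80.0, 60.1, 10.0)),
            V_tail=0.0, step_duration=20.0, tail_duration=10.0, pre_duration=5.0,
        )
        sw = gk.simulate_sweeps(always_open, proto, clean_cell)
        chord = gk.gv_from_chord(sw, Vrev=0.0)
        assert np.abs(chord.values - 1.0).max() < 1e-6


class TestBoltzmannFit:
    def test_noiseless_recovery_of_synthetic_curve(self, constants):
        V = np.arange(-80.0, 60.1, 5.0)
        y = 1.0 / (1.0 + np.exp(-3.4 * (V + 25.9) / constants.rt_f_mV))
        fit = gk.fit_boltzmann(gk.GVCurve(V, y))
        assert fit.converged
        assert fit.Vd == pytest.approx(-25.9, abs=0.05)
        assert fit.z == pytest.approx(3.4, abs=0.01)

    def test_fitted_curve_half_maximal_at_midpoint(self, constants):
        V = np.arange(-80.0, 60.1, 5.0)
        y = 0.8 / (1.0 + np.exp(-2.0 * (V + 10.0) / constants.rt_f_mV))
        fit = gk.fit_boltzmann(gk.GVCurve(V, y))
        assert fit.predict(fit.Vd) == pytest.approx(0.5 * fit.Gmax, rel=1e-6)

    def test_monte_carlo_recovery_under_noise(self, constants):
        V = np.arange(-80.0, 60.1, 5.0)
        truth = 1.0 / (1.0 + np.exp(-3.4 * (V + 25.9) / constants.rt_f_mV))
        rng = np.random.default_rng(0)
        vds = []
        for _ in range(20):
            y = truth + rng.normal(0.0, 0.01, V.size)
            vds.append(gk.fit_boltzmann(gk.GVCurve(V, y)).Vd)
        assert abs(np.mean(vds) + 25.9) < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            gk.fit_boltzmann(gk.GVCurve(np.array([-20.0, 0.0, 20.0]), np.array([0.1, 0.5, 0.9])))

    def test_flat_curve_flagged_not_raised(self):
        V = np.arange(-50.0, 50.1, 10.0)
        fit = gk.fit_boltzmann(gk.GVCurve(V, np.full(V.size, 0.5)))
        assert not fit.converged


class TestDeltaDeltaG:
    def test_v369_worked_example(self):
        # Boltzmann parameters of the amide control vs ester variant at site 369
        d = gk.delta_delta_g_from_params(3.8, -25.5, 1.9, 33.0)
        assert d.value == pytest.approx(-3.68, abs=0.01)

    def test_l375_worked_example(self):
        d = gk.delta_delta_g_from_params(3.5, -26.0, 3.8, -23.4)
        assert d.value == pytest.approx(-0.05, abs=0.01)

    def test_identical_fits_give_exact_zero(self):
        d = gk.delta_delta_g_from_params(3.4, -25.9, 3.4, -25.9)
        assert d.value == 0.0

    def test_antisymmetry(self):
        a = gk.delta_delta_g_from_params(3.8, -25.5, 1.9, 33.0)
        b = gk.delta_delta_g_from_params(1.9, 33.0, 3.8, -25.5)
        assert a.value == pytest.approx(-b.value, abs=1e-12)

    def test_unconverged_fit_rejected(self):
        bad = gk.BoltzmannFit(1.0, 0.0, 1.0, 0.0, converged=False)
        good = gk.BoltzmannFit(1.0, -20.0, 3.0, 0.0, converged=True)
        with pytest.raises(InvalidParameterError):
            gk.delta_delta_g(good, bad)


class TestExponentialTail:
    def test_synthetic_tau_recovered_noiseless(self):
        t = np.arange(0.0, 80.0, 0.1)
        trace = -4.0 * np.exp(-t / 12.0) + 0.2
        fit = gk.fit_exponential_tail(t, trace, t_start=0.0, blank=0.3)
        assert fit.converged
        assert fit.tau == pytest.approx(12.0, rel=1e-3)
        assert fit.offset == pytest.approx(0.2, abs=1e-6)

    def test_two_state_tail_matches_relaxation_time(self, wt_scheme, gv_protocol, clean_cell, constants):
        sw = gk.simulate_sweeps(wt_scheme, gv_protocol, clean_cell)
        fit = gk.fit_exponential_tail(
            sw.time, sw.traces[-1], t_start=gv_protocol.t_tail_start, blank=0.3
        )
        kf, kb = wt_scheme.transitions[0].rates(gv_protocol.V_tail, constants)
        assert fit.converged
        assert fit.tau == pytest.approx(1.0 / (kf + kb), rel=1e-3)

    def test_constant_trace_flagged(self):
        t = np.arange(0.0, 40.0, 0.1)
        fit = gk.fit_exponential_tail(t, np.full_like(t, 1.5), t_start=5.0)
        assert not fit.converged
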