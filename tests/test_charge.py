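"""OFF-charge integration, linear-capacitance removal and Q-V decomposition."""

import warnings

import numpy as np
import pytest

import gatingkit as gk
from gatingkit.charge import QVCurve
from gatingkit.constants import InvalidParameterError


@pytest.fixture(scope="module")
def chain_sweeps(chain_scheme, qv_protocol):
    cell = gk.CellModel(C_lin=0.2, tau_clamp=0.5, g_leak=0.0, noise_sd=0.0)
    return gk.simulate_sweeps(chain_scheme, qv_protocol, cell)


class TestIntegrateOffCharge:
    def test_zero_trace_integrates_to_zero(self):
        t = np.arange(0.0, 30.0, 0.1)
        assert gk.integrate_off_charge(t, np.zeros_like(t), (5.0, 25.0)) == 0.0

    def test_linear_capacitor_q_equals_c_dv(self):
        # OFF step of dV = -150 mV through a 0.2 nC/mV capacitance
        t = np.arange(0.0, 30.0, 0.002)
        tau = 0.5
        trace = 0.2 * (-150.0) / tau * np.exp(-t / tau)
        q = gk.integrate_off_charge(t, trace, (0.0, 30.0))
        assert q == pytest.approx(0.2 * -150.0, rel=1e-3)

    def test_truncated_transient_warns(self):
        t = np.arange(0.0, 30.0, 0.1)
        trace = -3.0 * np.exp(-t / 40.0)  # far from decayed inside the window
        with pytest.warns(UserWarning, match="truncate"):
            gk.integrate_off_charge(t, trace, (0.0, 10.0))


class TestLinearCapacitance:
    def test_constructed_line_slope_recovered(self):
        V = np.arange(-150.0, 100.1, 5.0)
        q = 0.15 * (V + 100.0) + 3.0  # saturated gating offset of 3 nC
        c = gk.estimate_linear_capacitance(V, q)
        assert c == pytest.approx(0.15, rel=1e-9)

    def test_five_points_at_5mV_spacing_is_exact(self):
        V = np.arange(50.0, 70.1, 5.0)
        q = 0.15 * (V + 100.0) + 3.0
        assert gk.estimate_linear_capacitance(V, q) == pytest.approx(0.15, rel=1e-12)

    def test_zero_capacitance_cell_gives_zero_slope(self):
        V = np.arange(-150.0, 100.1, 5.0)
        q = np.full(V.size, 2.0)
        assert abs(gk.estimate_linear_capacitance(V, q)) < 1e-12

    def test_too_few_points_in_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            gk.estimate_linear_capacitance(np.array([0.0, 55.0, 100.0]), np.zeros(3))

    def test_unsaturated_gating_charge_warns(self, qv_protocol):
        # component 2 at +20 mV is still moving inside the +50..+70 window
        late = gk.build_sequential_scheme(
            [(1.0, -120.0, 0.3), (2.5, 20.0, 0.3)], N=1e10, conducting=False
        )
        cell = gk.CellModel(C_lin=0.2, tau_clamp=0.5, noise_sd=0.0)
        sw = gk.simulate_sweeps(late, qv_protocol, cell)
        q_raw = gk.off_charges(sw)
        with pytest.warns(UserWarning, match="saturated"):
            gk.estimate_linear_capacitance(np.asarray(qv_protocol.step_voltages), q_raw)


class TestSubtractLinear:
    def test_pure_linear_cell_flags_negligible_charge(self, qv_protocol):
        none = gk.build_sequential_scheme([(1.0, -120.0, 0.3)], N=0.0, conducting=False)
        cell = gk.CellModel(C_lin=0.2, tau_clamp=0.5, noise_sd=0.0)
        sw = gk.simulate_sweeps(none, qv_protocol, cell)
        qv = gk.qv_from_sweeps(sw)
        assert "negligible_charge" in qv.flags
        assert np.abs(qv.q).max() < 0.01

    def test_recovered_qv_matches_equilibrium_charge(self, chain_scheme, chain_sweeps, constants):
        qv = gk.qv_from_sweeps(chain_sweeps)
        scale = chain_scheme.N * constants.e0 * 1e9
        ref = chain_scheme.charge_displacement(chain_scheme.equilibrium(-100.0))
        exact = np.array([
            chain_scheme.charge_displacement(chain_scheme.equilibrium(v)) - ref
            for v in qv.voltages
        ]) * scale
        # agreement to ~0.6% of total charge; the residual is trapezoidal
        # quadrature error on the fast component of the OFF transient
        assert np.abs(qv.q - exact).max() / (scale * chain_scheme.total_charge) < 1e-2

    def test_constant_raw_offset_does_not_change_normalized_qv(self, chain_sweeps):
        qv1 = gk.qv_from_sweeps(chain_sweeps)
        fit1 = gk.fit_double_boltzmann(qv1)
        qv2 = gk.subtract_linear(qv1.voltages, qv1.q_raw + 5.0, qv1.c_lin, -100.0)
        fit2 = gk.fit_double_boltzmann(qv2)
        gk.normalize_qv(qv1, fit1)
        gk.normalize_qv(qv2, fit2)
        assert np.allclose(qv1.q_norm, qv2.q_norm, atol=1e-6)


class TestDoubleBoltzmannFit:
    def test_synthetic_two_component_recovery(self, constants):
        rt = constants.rt_f_mV
        V = np.arange(-150.0, 100.1, 5.0)
        truth = dict(Qmax=2.0, f1=0.8, V1=-120.0, z1=1.0, V2=25.0, z2=1.9)
        y = truth["Qmax"] * (
            truth["f1"] / (1 + np.exp(-truth["z1"] * (V - truth["V1"]) / rt))
            + (1 - truth["f1"]) / (1 + np.exp(-truth["z2"] * (V - truth["V2"]) / rt))
        )
        fit = gk.fit_double_boltzmann(QVCurve(V, y, 0.0, y))
        assert fit.converged
        assert fit.f1 == pytest.approx(0.8, rel=0.05)
        assert fit.V1 == pytest.approx(-120.0, rel=0.05)
        assert fit.z1 == pytest.approx(1.0, rel=0.05)
        assert fit.V2 == pytest.approx(25.0, rel=0.05)
        assert fit.z2 == pytest.approx(1.9, rel=0.05)

    def test_single_component_truth_collapses_with_flag(self, constants):
        rt = constants.rt_f_mV
        V = np.arange(-150.0, 100.1, 5.0)
        y = 2.0 / (1 + np.exp(-2.0 * (V + 40.0) / rt))
        fit = gk.fit_double_boltzmann(QVCurve(V, y, 0.0, y))
        assert fit.f1 == 1.0
        assert "single_component" in fit.flags
        assert fit.V1 == pytest.approx(-40.0, abs=1.0)
        assert fit.z1 == pytest.approx(2.0, rel=0.02)

    def test_midpoint_identity_single_component(self, constants):
        rt = constants.rt_f_mV
        V = np.arange(-150.0, 100.1, 5.0)
        y = 2.0 / (1 + np.exp(-2.0 * (V + 40.0) / rt))
        fit = gk.fit_double_boltzmann(QVCurve(V, y, 0.0, y))
        mid = fit.predict(fit.V1, constants) - fit.offset
        assert mid == pytest.approx(fit.Qmax / 2, rel=1e-3)

    def test_too_few_points_rejected(self):
        V = np.arange(-60.0, 0.1, 10.0)
        with pytest.raises(InvalidParameterError):
            gk.fit_double_boltzmann(QVCurve(V, np.zeros(V.size), 0.0, np.zeros(V.size)))


class TestEndToEndChargePipeline:
    def test_noiseless_recovery_of_all_gating_parameters(self, chain_scheme, chain_sweeps, constants):
        """integrate -> regress +50..+70 -> subtract -> double Boltzmann."""
        qv = gk.qv_from_sweeps(chain_sweeps)
        fit = gk.fit_double_boltzmann(qv)
        assert qv.c_lin == pytest.approx(0.2, rel=0.02)
        assert fit.converged
        f1_true = 1.0 / 3.5
        assert fit.f1 == pytest.approx(f1_true, rel=0.05)
        assert fit.V1 == pytest.approx(-120.0, rel=0.05)
        assert fit.z1 == pytest.approx(1.0, rel=0.05)
        assert fit.V2 == pytest.approx(-20.0, rel=0.05)
        assert fit.z2 == pytest.approx(2.5, rel=0.05)
        qmax_true = chain_scheme.N * constants.e0 * 1e9 * chain_scheme.total_charge
        assert fit.Qmax == pytest.approx(qmax_true, rel=0.02)

    def test_noisy_recovery_from_seed_averaged_qv(self, chain_scheme, qv_protocol):
        """2% noise (of the filtered peak gating current), 20 seeds."""
        bare = gk.simulate_sweeps(
            chain_scheme, qv_protocol,
            gk.CellModel(C_lin=0.0, noise_sd=0.0, tau_clamp=0.5, filter_kHz=1.0),
        )
        sd = 0.02 * np.abs(bare.traces).max()
        qs, cs = [], []
        for seed in range(20):
            cell = gk.CellModel(C_lin=0.2, tau_clamp=0.5, noise_sd=sd, seed=seed)
            qv = gk.qv_from_sweeps(gk.simulate_sweeps(chain_scheme, qv_protocol, cell))
            qs.append(qv.q)
            cs.append(qv.c_lin)
        mean_q = np.mean(qs, axis=0)
        qv_mean = QVCurve(qv.voltages, mean_q, float(np.mean(cs)), mean_q)
        fit = gk.fit_double_boltzmann(qv_mean)
        assert fit.converged
        assert fit.f1 == pytest.approx(1.0 / 3.5, rel=0.15)
        assert fit.V1 == pytest.approx(-120.0, rel=0.15)
        assert fit.z1 == pytest.approx(1.0, rel=0.15)
        assert fit.V2 == pytest.approx(-20.0, rel=0.15)
        assert fit.z2 == pytest.approx(2.5, rel=0.15)
        assert np.mean(cs) == pytest.approx(0.2, rel=0.02)

    def test_capacitance_estimate_invariant_to_gating_parameters(self, qv_protocol):
        cell = gk.CellModel(C_lin=0.2, tau_clamp=0.5, noise_sd=0.0)
        chains = [
            gk.build_sequential_scheme([(1.0, -120.0, 0.3), (2.5, -20.0, 0.3)], N=1e10, conducting=False),
            gk.build_sequential_scheme([(2.0, -90.0, 0.3), (1.5, -40.0, 0.3)], N=5e9, conducting=False),
        ]
        cs = []
        for ch in chains:
            sw = gk.simulate_sweeps(ch, qv_protocol, cell)
            cs.append(gk.qv_from_sweeps(sw).c_lin)
        assert cs[0] == pytest.approx(cs[1], rel=5e-3)
        assert cs[0] == pytest.approx(0.2, rel=0.02)


class TestChargeConservation:
    def test_on_off_ratio_unity_noiseless(self, chain_scheme):
        proto = gk.VoltageProtocol(
            V_hold=-100.0, step_voltages=tuple(np.arange(-150.0, 100.1, 25.0)),
            V_tail=-100.0, step_duration=30.0, tail_duration=30.0, pre_duration=2.0,
            sample_rate=2000.0,
        )
        sw = gk.simulate_sweeps(
            chain_scheme, proto, gk.CellModel(C_lin=0.0, noise_sd=0.0, tau_clamp=0.25)
        )
        report = gk.charge_conservation_report(sw)
        ratios = report["ratio"].dropna()
        assert len(ratios) >= 9
        assert np.abs(ratios - 1.0).max() < 1e-3

    def test_truncated_off_window_flags_deviation(self, chain_scheme):
        proto = gk.VoltageProtocol(
            V_hold=-100.0, step_voltages=(0.0,), V_tail=-100.0,
            step_duration=30.0, tail_duration=1.0,  # OFF cut far too short
            pre_duration=2.0, sample_rate=500.0,
        )
        slow = gk.build_sequential_scheme(
            [(1.0, -120.0, 0.05), (2.5, -20.0, 0.05)], N=1e10, conducting=False
        )
        sw = gk.simulate_sweeps(slow, proto, gk.CellModel(C_lin=0.0, noise_sd=0.0, tau_clamp=0.25))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = gk.charge_conservation_report(sw)
        assert report["flag"].iloc[0] in ("deviation", "n/a") or report["ratio"].iloc[0] > 1.05

    def test_zero_charge_scheme_reported_not_applicable(self, qv_protocol):
        none = gk.build_sequential_scheme([(1.0, -120.0, 0.3)], N=0.0, conducting=False)
        sw = gk.simulate_sweeps(none, qv_protocol, gk.CellModel(C_lin=0.0, noise_sd=0.0, tau_clamp=0.25))
        report = gk.charge_conservation_report(sw)
        assert (report["flag"] == "n/a").all()
        assert report["ratio"].isna().all()
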