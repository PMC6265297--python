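"""Shared fixtures: schemes, protocols, cells and ideal-helix structures."""

import numpy as np
import pytest

import gatingkit as gk


@pytest.fixture(scope="session")
def constants():
    return gk.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def wt_scheme():
    """WT-like two-state channel: z = 3.4 e0, Vd = -25.9 mV."""
    return gk.build_two_state_scheme(z=3.4, Vd=-25.9, k0=0.1)


@pytest.fixture(scope="session")
def chain_scheme():
    """Two-step activation chain with well-separated charge components."""
    return gk.build_sequential_scheme(
        [(1.0, -120.0, 0.3), (2.5, -20.0, 0.3)], N=1e10, conducting=False
    )


@pytest.fixture(scope="session")
def gv_protocol():
    """Ionic activation family: hold -80, steps -80..+60 (5 mV), tail -50."""
    return gk.VoltageProtocol(
        V_hold=-80.0, step_voltages=tuple(np.arange(-80.0, 60.1, 5.0)),
        step_duration=30.0, V_tail=-50.0, tail_duration=30.0, pre_duration=5.0,
        sample_rate=10.0,
    )


@pytest.fixture(scope="session")
def qv_protocol():
    """Gating-current family: hold -100, steps -150..+100 (5 mV), back to hold."""
    return gk.VoltageProtocol(
        V_hold=-100.0, step_voltages=tuple(np.arange(-150.0, 100.1, 5.0)),
        step_duration=30.0, V_tail=-100.0, tail_duration=30.0, pre_duration=5.0,
        sample_rate=500.0,
    )


@pytest.fixture
def clean_cell():
    """No artifacts, no noise; tau_clamp long enough to avoid the
    undersampling warning at 10 kHz."""
    return gk.CellModel(C_lin=0.0, tau_clamp=0.25, g_leak=0.0, noise_sd=0.0)


@pytest.fixture
def artifact_cell():
    """Realistic linear artifacts, still noiseless."""
    return gk.CellModel(C_lin=0.2, tau_clamp=0.25, g_leak=1.0, E_leak=-20.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def alpha_helix():
    return gk.build_ideal_helix(12, -57.0, -47.0)


@pytest.fixture(scope="session")
def three_ten_helix():
    return gk.build_ideal_helix(12, -49.0, -26.0)
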