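"""Deactivation kinetics: single-exponential tail fits vs the closed form.

For a two-state channel the tail current at the repolarization potential
relaxes with tau = 1/(k_f + k_b) evaluated there; the fitted tau from the
simulated sweep should match that closed form.  Faster deactivation in an
ester variant is the kinetic signature of a destabilized open state.
"""

import numpy as np

import gatingkit as gk

protocol = gk.VoltageProtocol(
    V_hold=-80.0, step_voltages=(60.0,), step_duration=30.0,
    V_tail=-50.0, tail_duration=30.0, pre_duration=5.0, sample_rate=10.0,
)
cell = gk.CellModel(C_lin=0.0, noise_sd=0.0, tau_clamp=0.25)

print(f"{'construct':<12} {'tau_fit (ms)':>12} {'tau_theory (ms)':>16}")
for label, z, vd in [("wt-like", 3.4, -25.9), ("ester-like", 1.9, 33.0)]:
    scheme = gk.build_two_state_scheme(z=z, Vd=vd, k0=0.1)
    sw = gk.simulate_sweeps(scheme, protocol, cell)
    fit = gk.fit_exponential_tail(sw.time, sw.traces[0], protocol.t_tail_start, blank=0.3)
    kf, kb = scheme.transitions[0].rates(protocol.V_tail)
    print(f"{label:<12} {fit.tau:>12.3f} {1.0/(kf+kb):>16.3f}")

print()
print("The right-shifted, shallow ester-like variant deactivates much faster")
print("at -50 mV: its closing rate there is far from its midpoint, exactly the")
print("behaviour seen when a backbone H-bond stabilizing the open state is lost.")
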