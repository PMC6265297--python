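"""Deterministic macroscopic voltage-clamp sweep simulation.

The state of the channel population evolves by the master equation
dp/dt = A(V) p with the command potential piecewise constant, so each protocol
segment is propagated exactly through the eigendecomposition of its generator
(with a matrix-exponential fallback for ill-conditioned cases).  The recorded
current is a sum of physically distinct terms:

* ionic current      N * Po(t) * gamma * (V - Vrev)            (conducting only)
* gating current     N * e0 * sum_t z_t * (net forward flux)
* capacitive current C_lin * dV_clamp/dt, with the clamp potential settling
  exponentially (tau_clamp) after each commanded jump -- the familiar
  oocyte capacitive spike
* linear leak        g_leak * (V - E_leak)
* Gaussian noise     iid per sample, sd ``noise_sd``

Sign conventions: depolarization positive, outward current positive; the ON
gating transient at a depolarizing step is upward.

Units: time ms, voltage mV, current uA.  Charge obtained by integrating uA
over ms is in nC, and the linear capacitance is carried in nC/mV so that
Q = C * dV holds numerically (1 nC/mV = 1 uF; a whole oocyte is ~0.2 uF).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .constants import InvalidParameterError
from .protocol import VoltageProtocol, p_over_n_subpulses
from .scheme import GatingScheme


@dataclass(frozen=True)
class CellModel:
    """Recording-cell artifact model.

    C_lin: linear membrane capacitance, nC/mV.  tau_clamp: clamp settling time
    constant, ms.  g_leak: linear leak conductance, uS (E_leak its reversal,
    mV).  noise_sd: Gaussian noise sd, uA.  seed: RNG seed for the noise.
    """

    C_lin: float = 0.2
    tau_clamp: float = 0.1
    g_leak: float = 0.0
    E_leak: float = -80.0
    noise_sd: float = 0.0
    seed: int = 0
    filter_kHz: float = 0.0  # one-pole low-pass cutoff; 0 disables

    def __post_init__(self) -> None:
        if self.C_lin < 0 or self.g_leak < 0 or self.noise_sd < 0 or self.filter_kHz < 0:
            raise InvalidParameterError("C_lin, g_leak, noise_sd and filter_kHz must be >= 0")
        if not self.tau_clamp > 0:
            raise InvalidParameterError("tau_clamp must be > 0")


@dataclass
class SweepSet:
    """Time-aligned current traces for one voltage-step protocol.

    ``traces`` has shape (n_steps, n_samples) in uA on the shared ``time``
    base (ms).  ``meta`` carries provenance (scheme/cell parameters, seed).
    """

    time: np.ndarray
    traces: np.ndarray
    protocol: VoltageProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape != (len(self.protocol.step_voltages), self.time.size):
            raise InvalidParameterError(
                "traces must be (n_steps, n_samples) matching protocol and time base"
            )

    @property
    def n_steps(self) -> int:
        return self.traces.shape[0]

    def segment_mask(self, segment: str) -> np.ndarray:
        """Boolean sample mask for 'pre', 'step' or 'tail'."""
        t, p = self.time, self.protocol
        if segment == "pre":
            return t < p.t_step_start
        if segment == "step":
            return (t >= p.t_step_start) & (t < p.t_tail_start)
        if segment == "tail":
            return t >= p.t_tail_start
        raise ValueError(f"unknown segment {segment!r}")

    # ----- serialization: TSV trace table + JSON sidecar ------------------

    def to_tsv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` (time_ms + one current column per step) and
        ``<prefix>.json`` (protocol / provenance sidecar)."""
        prefix = Path(prefix)
        data = {"time_ms": self.time}
        for v, trace in zip(self.protocol.step_voltages, self.traces):
            data[f"I_step_{v:g}"] = trace
        tsv = prefix.with_suffix(".tsv")
        pd.DataFrame(data).to_csv(tsv, sep="\t", index=False, float_format="%.10g")
        sidecar = {"protocol": asdict(self.protocol), "meta": self.meta}
        js = prefix.with_suffix(".json")
        js.write_text(json.dumps(sidecar, indent=2, default=str))
        return tsv, js

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "SweepSet":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        pspec = sidecar["protocol"]
        pspec["step_voltages"] = tuple(pspec["step_voltages"])
        protocol = VoltageProtocol(**pspec)
        traces = df[[c for c in df.columns if c.startswith("I_step_")]].to_numpy().T
        return cls(df["time_ms"].to_numpy(), traces, protocol, sidecar.get("meta", {}))


def one_pole_lowpass(signal: np.ndarray, dt: float, cutoff_kHz: float) -> np.ndarray:
    """Single-pole RC low-pass (unit DC gain), the acquisition-filter stage.

    ``cutoff_kHz`` is the -3 dB frequency; the filter time constant is
    1/(2 pi f_c).  Total charge (the time integral) is preserved.
    """
    import scipy.signal

    tau_f = 1.0 / (2.0 * np.pi * cutoff_kHz)
    a = float(np.exp(-dt / tau_f))
    return scipy.signal.lfilter([1.0 - a], [1.0, -a], signal, axis=-1)


def _propagate_segment(A: np.ndarray, p0: np.ndarray, t_local: np.ndarray) -> np.ndarray:
    """Solve dp/dt = A p exactly at the requested local times."""
    try:
        w, U = scipy.linalg.eig(A)
        c = scipy.linalg.solve(U, p0.astype(complex))
        E = np.exp(np.outer(t_local, w))
        P = np.real(E * c[None, :] @ U.T)
    except scipy.linalg.LinAlgError:  # defective generator: step with expm
        P = np.empty((t_local.size, p0.size))
        for k, t in enumerate(t_local):
            P[k] = scipy.linalg.expm(A * t) @ p0
    # clean tiny negative round-off without disturbing normalization
    return P


def occupancies(scheme: GatingScheme, protocol: VoltageProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Master-equation state probabilities for every sweep of a protocol.

    Returns ``(time, P)`` with ``P`` of shape (n_steps, n_samples, n_states).
    The initial condition is the equilibrium at the holding potential; within
    each constant-voltage segment the solution is exact.
    """
    t = protocol.times()
    n_states = scheme.n_states
    P = np.empty((len(protocol.step_voltages), t.size, n_states))
    p_hold = scheme.equilibrium(protocol.V_hold)
    for i, Vs in enumerate(protocol.step_voltages):
        p0 = p_hold
        t_seg_start = 0.0
        for V, dur in protocol.segments(Vs):
            mask = (t >= t_seg_start - 1e-12) & (t < t_seg_start + dur - 1e-12)
            A = scheme.rate_matrix(V)
            t_local = t[mask] - t_seg_start
            if t_local.size:
                P[i, mask] = _propagate_segment(A, p0, t_local)
            # exact boundary value seeds the next segment
            p0 = _propagate_segment(A, p0, np.array([dur]))[0]
            t_seg_start += dur
    return t, P


def simulate_sweeps(scheme: GatingScheme, protocol: VoltageProtocol, cell: CellModel) -> SweepSet:
    """Simulate a full sweep family with recording artifacts.

    Deterministic for a fixed ``cell.seed``; running twice with identical
    inputs yields bitwise-identical traces.
    """
    if protocol.dt > cell.tau_clamp / 2:
        warnings.warn(
            "sample interval exceeds tau_clamp/2: capacitance transient is undersampled",
            UserWarning,
            stacklevel=2,
        )
    t = protocol.times()
    time_, P = occupancies(scheme, protocol)
    rng = np.random.default_rng(cell.seed)
    open_idx = [scheme.state_index(s) for s in scheme.open_states]
    traces = np.empty((len(protocol.step_voltages), t.size))
    for i, Vs in enumerate(protocol.step_voltages):
        V_cmd = protocol.command_voltage(Vs)
        I = np.zeros(t.size)
        # ionic current, uA = N * gamma[S] * Po * (mV driving force) * 1e3
        if scheme.conducting and open_idx:
            Po = P[i][:, open_idx].sum(axis=1)
            I += scheme.N * scheme.gamma * Po * (V_cmd - scheme.Vrev) * 1e3
        # gating current, uA = N * e0[C] * flux[ms^-1] * 1e9
        flux = np.zeros(t.size)
        t_seg_start = 0.0
        for V, dur in protocol.segments(Vs):
            mask = (t >= t_seg_start - 1e-12) & (t < t_seg_start + dur - 1e-12)
            for tr in scheme.transitions:
                kf, kb = tr.rates(V, scheme.constants)
                si, ti = scheme.state_index(tr.source), scheme.state_index(tr.target)
                flux[mask] += tr.z * (P[i, mask, si] * kf - P[i, mask, ti] * kb)
            t_seg_start += dur
        I += scheme.N * scheme.constants.e0 * flux * 1e9
        # clamp-smoothed capacitive transient: uA = (nC/mV) * mV/ms
        if cell.C_lin > 0:
            t_seg_start = 0.0
            V_prev = protocol.V_hold
            for V, dur in protocol.segments(Vs):
                mask = (t >= t_seg_start - 1e-12) & (t < t_seg_start + dur - 1e-12)
                dV = V - V_prev
                I[mask] += cell.C_lin * dV / cell.tau_clamp * np.exp(-(t[mask] - t_seg_start) / cell.tau_clamp)
                # clamp has effectively settled by segment end for tau << dur
                V_prev = V - dV * float(np.exp(-dur / cell.tau_clamp))
                t_seg_start += dur
        # linear leak, uA = uS * mV * 1e-3
        if cell.g_leak > 0:
            I += cell.g_leak * (V_cmd - cell.E_leak) * 1e-3
        if cell.filter_kHz > 0:
            I = one_pole_lowpass(I, protocol.dt, cell.filter_kHz)
        if cell.noise_sd > 0:
            I = I + rng.normal(0.0, cell.noise_sd, size=I.shape)
        traces[i] = I
    meta = {
        "scheme": {
            "states": list(scheme.states),
            "transitions": [asdict(tr) for tr in scheme.transitions],
            "open_states": sorted(scheme.open_states),
            "N": scheme.N, "gamma": scheme.gamma, "Vrev": scheme.Vrev,
            "conducting": scheme.conducting,
            "temperature_K": scheme.constants.temperature_K,
        },
        "cell": asdict(cell),
        "seed": cell.seed,
    }
    return SweepSet(t, traces, protocol, meta)


def simulate_p_over_n(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    cell: CellModel,
    n: int = 8,
    scale_sign: float = 1.0,
    subpulse_hold: float | None = None,
) -> list[SweepSet]:
    """Simulate ``n`` repeats of the P/N companion protocol.

    Each repeat gets an independent noise stream (seeds derived from
    ``cell.seed``) so that averaging the repeats reduces subtraction noise as
    in the real acquisition.
    """
    sub_protocol = p_over_n_subpulses(protocol, n, scale_sign, subpulse_hold)
    return [
        simulate_sweeps(scheme, sub_protocol, replace(cell, seed=(cell.seed * 65537 + 1000 + k) % 2**31))
        for k in range(n)
    ]
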