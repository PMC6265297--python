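"""Ionic-current analysis: leak subtraction, G-V curves, Boltzmann fits,
gating free-energy perturbations, and deactivation kinetics.

The analysis chain mirrors standard two-electrode voltage-clamp practice:
P/8-subtract the raw sweeps, read channel activation either from tail-current
amplitudes (2-4 ms window after repolarization) or from chord conductance
I/(V - Vrev), fit the normalized curve with a single Boltzmann

    G(V) = Gmax / (1 + exp(-zF(V - Vd)/RT))

and summarize a backbone perturbation as the gating free-energy difference

    ddG = (z F Vd)_aa - (z F Vd)_ah        [kcal/mol, F = 23.061 kcal/mol/V]

between the amino-acid (aa) control and the alpha-hydroxy (ah, ester)
variant fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .constants import DEFAULT_CONSTANTS, InvalidParameterError, PhysicalConstants
from .simulate import SweepSet


@dataclass
class GVCurve:
    """Normalized conductance vs step voltage, with per-point scatter."""

    voltages: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    n: int = 1
    method: str = "tail"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise InvalidParameterError("voltages must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("conductance values must be finite")


@dataclass
class BoltzmannFit:
    """Single-Boltzmann fit result (Gmax, midpoint Vd in mV, valence z in e0)."""

    Gmax: float
    Vd: float
    z: float
    residual_norm: float
    converged: bool
    offset: float = 0.0
    sd_Vd: float = float("nan")
    sd_z: float = float("nan")
    label: str = ""

    def predict(self, V, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        rt = constants.rt_f_mV
        return self.offset + self.Gmax / (1.0 + np.exp(-self.z * (V - self.Vd) / rt))


@dataclass
class DeltaDeltaG:
    """Gating perturbation energy (kcal/mol) between two Boltzmann fits."""

    value: float
    term_aa: float
    term_ah: float
    label_aa: str = "aa"
    label_ah: str = "ah"
    sd: float = float("nan")


@dataclass
class ExpFit:
    """Single-exponential tail fit A*exp(-(t-t0)/tau) + b."""

    amplitude: float
    tau: float
    offset: float
    window: tuple[float, float]
    converged: bool


# --------------------------------------------------------------------------
# P/N subtraction
# --------------------------------------------------------------------------

def _pre_baseline(sweeps: SweepSet) -> np.ndarray:
    mask = sweeps.segment_mask("pre")
    return sweeps.traces[:, mask].mean(axis=1, keepdims=True)


def p_over_n_subtract(
    test: SweepSet,
    sub: SweepSet | Sequence[SweepSet],
    n: int | None = None,
    scale_sign: float = 1.0,
) -> SweepSet:
    """Remove linear leak and capacitance using scaled subpulse sweeps.

    Each sweep (test and companion) is first aligned to its own pre-pulse
    baseline, then ``scale_sign * n`` times the repeat-averaged companion is
    subtracted from the test sweep.  Because every linear current component
    scales with the 1/n voltage excursion, the linear artifacts cancel exactly
    (to machine precision for noiseless input); nonlinear channel currents
    survive essentially untouched (their subpulse response is negligible).
    """
    subs = [sub] if isinstance(sub, SweepSet) else list(sub)
    if n is None:
        n = len(subs)
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    for s in subs:
        if s.time.size != test.time.size or s.n_steps != test.n_steps:
            raise InvalidParameterError("subpulse sweeps do not match the test protocol")
        if abs(s.protocol.total_duration - test.protocol.total_duration) > 1e-9:
            raise InvalidParameterError("subpulse sweeps do not match the test protocol")
    test_bc = test.traces - _pre_baseline(test)
    sub_bc = np.mean([s.traces - _pre_baseline(s) for s in subs], axis=0)
    corrected = test_bc - float(scale_sign) * n * sub_bc
    meta = dict(test.meta)
    meta["p_over_n"] = {"n": n, "repeats": len(subs), "scale_sign": float(scale_sign)}
    return SweepSet(test.time.copy(), corrected, test.protocol, meta)


# --------------------------------------------------------------------------
# Tail amplitudes and G-V construction
# --------------------------------------------------------------------------

def tail_window_amplitude(
    time: np.ndarray,
    trace: np.ndarray,
    t_switch: float,
    window: tuple[float, float] = (2.0, 4.0),
    baseline_frac: float = 0.1,
) -> float:
    """Mean tail current over ``[t_switch+w0, t_switch+w1]`` ms, minus the
    fully-deactivated baseline (mean of the final ``baseline_frac`` of the
    tail).  This is the 'tail amplitude a few ms after switching' readout."""
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise InvalidParameterError("window must satisfy w1 > w0")
    if t_switch + w1 > time[-1] + 1e-9:
        raise InvalidParameterError("tail window exceeds the recorded trace")
    wmask = (time >= t_switch + w0) & (time <= t_switch + w1)
    tail_mask = time >= t_switch
    t_tail = time[tail_mask]
    t_base = t_tail[-1] - baseline_frac * (t_tail[-1] - t_tail[0])
    bmask = time >= t_base
    return float(trace[wmask].mean() - trace[bmask].mean())


def gv_from_tails(
    sweeps: SweepSet,
    window: tuple[float, float] = (2.0, 4.0),
    baseline_frac: float = 0.1,
    min_amplitude: float = 1e-12,
) -> GVCurve:
    """G-V from normalized tail-current amplitudes at the fixed tail potential.

    The unitary conductance and driving force are common to all steps, so the
    amplitude is proportional to the open probability at the end of each test
    step; normalizing by the largest magnitude yields the activation curve.
    """
    p = sweeps.protocol
    amps = np.array([
        tail_window_amplitude(sweeps.time, tr, p.t_tail_start, window, baseline_frac)
        for tr in sweeps.traces
    ])
    peak = np.abs(amps).max()
    if peak <= min_amplitude:
        raise InvalidParameterError("all tail amplitudes are zero: no channel expression")
    values = amps / amps[np.argmax(np.abs(amps))]
    return GVCurve(np.asarray(p.step_voltages), values, n=1, method="tail")


def gv_from_chord(
    sweeps: SweepSet,
    Vrev: float = 0.0,
    exclude_mV: float = 5.0,
    ss_frac: float = 0.1,
    min_amplitude: float = 1e-12,
) -> GVCurve:
    """G-V from chord conductance G = I_ss / (V - Vrev).

    Steady-state current is the mean over the final ``ss_frac`` of the test
    step (minus the pre-pulse baseline).  Steps within ``exclude_mV`` of the
    reversal potential are dropped rather than divided by a vanishing driving
    force.  Intended for constructs whose tails deactivate too fast for the
    tail-window readout.
    """
    p = sweeps.protocol
    t = sweeps.time
    step_mask = sweeps.segment_mask("step")
    t_step = t[step_mask]
    ss_mask = step_mask & (t >= t_step[-1] - ss_frac * (t_step[-1] - t_step[0]))
    base = sweeps.traces[:, sweeps.segment_mask("pre")].mean(axis=1)
    I_ss = sweeps.traces[:, ss_mask].mean(axis=1) - base
    V = np.asarray(p.step_voltages)
    keep = np.abs(V - Vrev) > exclude_mV
    if not keep.any():
        raise InvalidParameterError("all steps are within exclude_mV of Vrev")
    G = I_ss[keep] / (V[keep] - Vrev)
    peak = np.abs(G).max()
    if peak <= min_amplitude:
        raise InvalidParameterError("all chord conductances are zero: no channel expression")
    values = G / G[np.argmax(np.abs(G))]
    return GVCurve(V[keep], values, n=1, method="chord")


# --------------------------------------------------------------------------
# Boltzmann fitting and ddG
# --------------------------------------------------------------------------

def _boltzmann(V, Gmax, Vd, z, rt):
    return Gmax / (1.0 + np.exp(-z * (V - Vd) / rt))


def fit_boltzmann(
    curve: GVCurve,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    with_offset: bool = False,
    weights: np.ndarray | None = None,
    label: str = "",
) -> BoltzmannFit:
    """Least-squares single-Boltzmann fit of a (normalized) G-V curve.

    Initialization: Vd from the interpolated half-maximum crossing, z from the
    maximum slope of the normalized curve (z = 4 (RT/F) max dG/dV for a unit-
    amplitude Boltzmann).  ``with_offset`` adds a constant term b, useful when
    the tail baseline sits on a nonzero equilibrium conductance.  Failure to
    converge is reported through the ``converged`` flag, not an exception.
    """
    V = curve.voltages
    y = curve.values
    if V.size < 5:
        raise InvalidParameterError("need at least 5 points spanning the transition")
    rt = constants.rt_f_mV
    span = y.max() - y.min()
    if span <= 0:
        return BoltzmannFit(0.0, float(np.median(V)), 1.0, float(np.linalg.norm(y)), False, label=label)
    yn = (y - y.min()) / span
    # half-max crossing by linear interpolation
    above = np.nonzero(yn >= 0.5)[0]
    if above.size and above[0] > 0:
        i = above[0]
        f = (0.5 - yn[i - 1]) / (yn[i] - yn[i - 1])
        Vd0 = V[i - 1] + f * (V[i] - V[i - 1])
    else:
        Vd0 = float(np.median(V))
    slope = np.gradient(yn, V)
    z0 = float(np.clip(rt * 4.0 * slope.max(), 0.2, 15.0))
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights))
    lo_V, hi_V = V.min() - 50.0, V.max() + 50.0

    if with_offset:
        def model(V, Gmax, Vd, z, b):
            return b + _boltzmann(V, Gmax, Vd, z, rt)
        p0 = [span, Vd0, z0, float(y.min())]
        bounds = ([1e-9, lo_V, 0.05, -2.0], [10 * max(span, 1e-9), hi_V, 30.0, 2.0])
    else:
        def model(V, Gmax, Vd, z):
            return _boltzmann(V, Gmax, Vd, z, rt)
        p0 = [max(y.max(), 1e-9), Vd0, z0]
        bounds = ([1e-9, lo_V, 0.05], [10 * max(y.max(), 1e-9), hi_V, 30.0])

    try:
        popt, pcov = scipy.optimize.curve_fit(
            model, V, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return BoltzmannFit(float(span), float(Vd0), float(z0), float("inf"), False, label=label)
    resid = float(np.linalg.norm(model(V, *popt) - y))
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    b = float(popt[3]) if with_offset else 0.0
    # a midpoint pinned to the parameter bound means the transition was not spanned
    converged = bool(lo_V + 1e-6 < popt[1] < hi_V - 1e-6)
    return BoltzmannFit(
        Gmax=float(popt[0]), Vd=float(popt[1]), z=float(popt[2]),
        residual_norm=resid, converged=converged, offset=b,
        sd_Vd=float(perr[1]), sd_z=float(perr[2]), label=label,
    )


def delta_delta_g(
    fit_aa: BoltzmannFit,
    fit_ah: BoltzmannFit,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DeltaDeltaG:
    """Gating perturbation energy (zFVd)_aa - (zFVd)_ah in kcal/mol.

    Vd is converted from mV to volts; F = 23.061 kcal/mol/V.  When both fits
    carry parameter uncertainties, a first-order (delta-method) sd is
    propagated: var(zFVd) = F^2 (Vd^2 var z + z^2 var Vd), summed in
    quadrature over the two constructs.
    """
    if not (fit_aa.converged and fit_ah.converged):
        raise InvalidParameterError("delta_delta_g requires two converged Boltzmann fits")
    F = constants.F_kcal
    term_aa = fit_aa.z * F * (fit_aa.Vd / 1000.0)
    term_ah = fit_ah.z * F * (fit_ah.Vd / 1000.0)
    sd = float("nan")
    if np.isfinite(fit_aa.sd_Vd) and np.isfinite(fit_ah.sd_Vd):
        var = 0.0
        for f in (fit_aa, fit_ah):
            var += F**2 * ((f.Vd / 1000.0) ** 2 * f.sd_z**2 + f.z**2 * (f.sd_Vd / 1000.0) ** 2)
        sd = float(np.sqrt(var))
    return DeltaDeltaG(
        value=term_aa - term_ah, term_aa=term_aa, term_ah=term_ah,
        label_aa=fit_aa.label or "aa", label_ah=fit_ah.label or "ah", sd=sd,
    )


def delta_delta_g_from_params(
    z_aa: float, Vd_aa: float, z_ah: float, Vd_ah: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DeltaDeltaG:
    """ddG straight from printed fit parameters (z in e0, Vd in mV)."""
    mk = lambda z, Vd, lab: BoltzmannFit(1.0, Vd, z, 0.0, True, label=lab)
    return delta_delta_g(mk(z_aa, Vd_aa, "aa"), mk(z_ah, Vd_ah, "ah"), constants)


# --------------------------------------------------------------------------
# Deactivation kinetics
# --------------------------------------------------------------------------

def fit_exponential_tail(
    time: np.ndarray,
    trace: np.ndarray,
    t_start: float,
    blank: float = 0.3,
    t_end: float | None = None,
) -> ExpFit:
    """Single-exponential fit of a deactivating tail current.

    The first ``blank`` ms after the voltage switch are excluded (clamp
    settling).  A non-decaying or flat trace is reported with
    ``converged=False`` rather than raising.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0 = t_start + blank
    t1 = time[-1] if t_end is None else t_end
    mask = (time >= t0) & (time <= t1)
    tt, yy = time[mask], trace[mask]
    if tt.size < 5:
        raise InvalidParameterError("fit window contains fewer than 5 samples")
    b0 = float(yy[int(0.9 * yy.size):].mean())
    A0 = float(yy[0] - b0)
    if abs(A0) < 1e-14:
        return ExpFit(0.0, float("nan"), b0, (t0, t1), False)
    # time to decay to A0/e gives the tau scale
    dec = np.nonzero(np.abs(yy - b0) <= abs(A0) / np.e)[0]
    tau0 = float(tt[dec[0]] - tt[0]) if dec.size else (t1 - t0) / 5.0
    tau0 = max(tau0, (tt[1] - tt[0]))

    def model(t, A, tau, b):
        return A * np.exp(-(t - t0) / tau) + b

    try:
        popt, _ = scipy.optimize.curve_fit(
            model, tt, yy, p0=[A0, tau0, b0],
            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 1e6, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return ExpFit(A0, tau0, b0, (t0, t1), False)
    resid = float(np.std(model(tt, *popt) - yy))
    decaying = abs(popt[0]) > 3 * resid + 1e-12
    return ExpFit(float(popt[0]), float(popt[1]), float(popt[2]), (t0, t1), bool(decaying))
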