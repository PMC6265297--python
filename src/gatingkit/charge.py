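"""Gating-charge (Q-V) analysis from capacitive current sweeps.

Nonconducting (W434F-like) channels still move their voltage sensors, so each
voltage step produces transient capacitive currents that are a mix of linear
membrane charging and nonlinear gating charge.  Following standard practice,
the OFF transient (repolarization to the tail potential) is integrated for
every step; the linear capacitance is then estimated by ordinary least-squares
regression of the integrated charge against step voltage over a range where
gating charge has saturated (+50..+70 mV by default), and subtracted:

    Q(V) = Q_raw(V) - C_lin * (V - V_tail)

The isolated nonlinear Q-V is fit with a double Boltzmann

    Q(V) = Q0 + Qmax * [ f1/(1+exp(-z1 F(V-V1)/RT)) + (1-f1)/(1+exp(-z2 F(V-V2)/RT)) ]

whose two components describe the hyperpolarized (Q1) and depolarized (Q2)
phases of sensor movement.  The additive offset Q0 accounts for the fact that
OFF charge is measured relative to the holding-potential equilibrium, at which
a shallow hyperpolarized component may already be partially activated.

Units as elsewhere: integrating uA over ms yields nC; C_lin is in nC/mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .constants import DEFAULT_CONSTANTS, InvalidParameterError, PhysicalConstants
from .simulate import SweepSet


@dataclass
class QVCurve:
    """Voltage-indexed gating charge before/after linear-capacitance removal."""

    voltages: np.ndarray
    q_raw: np.ndarray          # integrated OFF charge returned per step, nC
    c_lin: float               # linear capacitance used for the subtraction, nC/mV
    q: np.ndarray              # nonlinear gating charge, nC
    q_norm: np.ndarray | None = None
    sd: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.q_raw = np.asarray(self.q_raw, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise InvalidParameterError("voltages must be strictly increasing")


@dataclass
class DoubleBoltzmannFit:
    """Two-component Boltzmann decomposition of a Q-V curve.

    Components are ordered V1 < V2; ``f1`` is the fraction of total charge in
    the hyperpolarized component.  ``offset`` (Q0) references the curve to the
    holding equilibrium.  A degenerate fit (all charge in one component) is
    reported with ``f1 = 1`` and NaN second-component parameters plus a flag.
    """

    Qmax: float
    f1: float
    V1: float
    z1: float
    V2: float
    z2: float
    offset: float
    residual_norm: float
    converged: bool
    flags: list = field(default_factory=list)

    def predict(self, V, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        rt = constants.rt_f_mV
        q = self.f1 / (1.0 + np.exp(-self.z1 * (V - self.V1) / rt))
        if self.f1 < 1.0 and np.isfinite(self.V2):
            q = q + (1.0 - self.f1) / (1.0 + np.exp(-self.z2 * (V - self.V2) / rt))
        return self.offset + self.Qmax * q


# --------------------------------------------------------------------------
# Charge integration
# --------------------------------------------------------------------------

def integrate_off_charge(
    time: np.ndarray,
    trace: np.ndarray,
    off_window: tuple[float, float],
    baseline_frac: float = 0.2,
    noise_sd: float = 0.0,
) -> float:
    """Trapezoidal integral (nC) of the baseline-subtracted OFF transient.

    The baseline is the mean current over the final ``baseline_frac`` of the
    window, where the transient should have decayed.  If the current at the
    window end still deviates from baseline by more than 3x the noise sd, the
    transient was truncated and a warning is issued.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0, t1 = off_window
    mask = (time >= t0) & (time <= t1)
    if mask.sum() < 4:
        raise InvalidParameterError("off_window contains too few samples")
    tt, yy = time[mask], trace[mask]
    bmask = tt >= tt[-1] - baseline_frac * (tt[-1] - tt[0])
    baseline = yy[bmask].mean()
    if abs(yy[-1] - baseline) > 3.0 * noise_sd + 1e-6:  # 1 pA floor
        warnings.warn("OFF window may truncate a non-decayed transient", UserWarning, stacklevel=2)
    return float(np.trapezoid(yy - baseline, tt))


def off_charges(sweeps: SweepSet, blank: float = 0.0, baseline_frac: float = 0.2) -> np.ndarray:
    """Charge returned during the OFF transient of every step, nC.

    Sign convention: the OFF current after a depolarizing step is inward
    (negative); its negated integral -- the charge *returned* -- is positive,
    so raw Q-V curves rise with depolarization.  ``blank`` ms after the switch
    can be excluded (default 0: the linear spike is removed later by the
    regression, and blanking would discard genuine gating charge).
    """
    p = sweeps.protocol
    noise = float(sweeps.meta.get("cell", {}).get("noise_sd", 0.0))
    t0 = p.t_tail_start + blank
    return np.array([
        -integrate_off_charge(sweeps.time, tr, (t0, sweeps.time[-1]), baseline_frac, noise)
        for tr in sweeps.traces
    ])


def estimate_linear_capacitance(
    voltages: np.ndarray,
    q_raw: np.ndarray,
    fit_range: tuple[float, float] = (50.0, 70.0),
) -> float:
    """Linear membrane capacitance (nC/mV) from the saturated limb of Q_raw(V).

    Ordinary least-squares slope of integrated OFF charge vs step voltage over
    ``fit_range``, where sensor charge movement must have saturated.  A
    detectable curvature of the points in the range (gating charge still
    moving) triggers a warning.
    """
    voltages = np.asarray(voltages, dtype=float)
    q_raw = np.asarray(q_raw, dtype=float)
    mask = (voltages >= fit_range[0]) & (voltages <= fit_range[1])
    if mask.sum() < 3:
        raise InvalidParameterError("need at least 3 points inside the capacitance fit range")
    V, Q = voltages[mask], q_raw[mask]
    slope, intercept = np.polyfit(V, Q, 1)
    # saturation check: for a purely linear (capacitive) limb the local slope
    # is constant; residual gating movement bends it.  Warn when the fitted
    # quadratic implies the slope drifts by >1% of itself across the range.
    # (Meaningful for low-noise data; at high noise the curvature estimate
    # from a handful of points is itself noisy.)
    if mask.sum() >= 4 and abs(slope) > 1e-12:
        c2 = np.polyfit(V, Q, 2)[0]
        slope_drift = abs(2.0 * c2 * (V.max() - V.min()))
        if slope_drift > 0.01 * abs(slope):
            warnings.warn(
                "gating charge does not appear saturated in the capacitance fit range",
                UserWarning, stacklevel=2,
            )
    return float(slope)


def subtract_linear(
    voltages: np.ndarray,
    q_raw: np.ndarray,
    C_lin: float,
    V_tail: float,
    negligible_q: float = 0.01,
) -> QVCurve:
    """Isolate nonlinear gating charge: Q(V) = Q_raw - C_lin*(V - V_tail).

    If the residual nonlinear charge never exceeds ``negligible_q`` (nC), the
    curve is flagged ``negligible_charge`` -- the behaviour expected of a
    negative-control cell with no expressed sensors.
    """
    voltages = np.asarray(voltages, dtype=float)
    q_raw = np.asarray(q_raw, dtype=float)
    q = q_raw - C_lin * (voltages - V_tail)
    flags = []
    if np.ptp(q) < negligible_q:
        flags.append("negligible_charge")
    return QVCurve(voltages, q_raw, float(C_lin), q, flags=flags)


def qv_from_sweeps(
    sweeps: SweepSet,
    fit_range: tuple[float, float] = (50.0, 70.0),
    blank: float = 0.0,
    baseline_frac: float = 0.2,
    negligible_q: float = 0.01,
) -> QVCurve:
    """Full OFF-integration pipeline: integrate, estimate C_lin, subtract."""
    q_raw = off_charges(sweeps, blank=blank, baseline_frac=baseline_frac)
    V = np.asarray(sweeps.protocol.step_voltages)
    C = estimate_linear_capacitance(V, q_raw, fit_range)
    return subtract_linear(V, q_raw, C, sweeps.protocol.V_tail, negligible_q)


# --------------------------------------------------------------------------
# Double-Boltzmann fitting
# --------------------------------------------------------------------------

def _double_boltzmann(V, Qmax, f1, V1, z1, V2, z2, Q0, rt):
    b1 = 1.0 / (1.0 + np.exp(-z1 * (V - V1) / rt))
    b2 = 1.0 / (1.0 + np.exp(-z2 * (V - V2) / rt))
    return Q0 + Qmax * (f1 * b1 + (1.0 - f1) * b2)


def fit_double_boltzmann(
    qv: QVCurve,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_starts: int = 7,
) -> DoubleBoltzmannFit:
    """Multi-start least-squares double-Boltzmann fit of a Q-V curve.

    The starts place the two midpoints at quantile-spaced voltage pairs; the
    best residual wins and components are reported with V1 < V2.  All-starts
    failure is reported through ``converged=False``.  If the winning fit puts
    essentially all charge in one component (f1 > 0.99 or < 0.01), the second
    component is unidentifiable: the result collapses to a single-component
    fit with ``f1=1`` and a ``single_component`` flag.
    """
    V = qv.voltages
    y = qv.q
    if V.size < 8:
        raise InvalidParameterError("need at least 8 points for a double-Boltzmann fit")
    rt = constants.rt_f_mV
    span = float(np.ptp(y))
    if span <= 0:
        return DoubleBoltzmannFit(0, 1, np.nan, np.nan, np.nan, np.nan, float(y.mean()),
                                  float("inf"), False, ["flat_curve"])
    # valences above ~8 e0 per component are unphysical for a voltage sensor;
    # the bound keeps noisy shallow components from collapsing into steps
    z_max = 8.0
    lo = [1e-9, 0.0, V.min() - 60, 0.05, V.min() - 60, 0.05, float(y.min()) - 2 * span]
    hi = [10 * span, 1.0, V.max() + 60, z_max, V.max() + 60, z_max, float(y.max()) + 2 * span]
    quantile_pairs = [
        (0.2, 0.7), (0.1, 0.6), (0.3, 0.8), (0.25, 0.5), (0.5, 0.85), (0.05, 0.45), (0.15, 0.9),
    ][:n_starts]
    best = None
    for qa, qb in quantile_pairs:
        Va = V.min() + qa * np.ptp(V)
        Vb = V.min() + qb * np.ptp(V)
        p0 = [span, 0.5, Va, 1.5, Vb, 1.5, float(y.min())]

        def model(V, *p):
            return _double_boltzmann(V, *p, rt)

        try:
            popt, _ = scipy.optimize.curve_fit(model, V, y, p0=p0, bounds=(lo, hi), maxfev=40000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(model(V, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return DoubleBoltzmannFit(span, 0.5, np.nan, np.nan, np.nan, np.nan, float(y.min()),
                                  float("inf"), False, ["no_start_converged"])
    popt, resid = best
    Qmax, f1, V1, z1, V2, z2, Q0 = (float(x) for x in popt)
    flags = list(qv.flags)
    if f1 < 0.5 or (V1 > V2):
        # order components: component 1 is the hyperpolarized one
        if V1 > V2:
            V1, V2 = V2, V1
            z1, z2 = z2, z1
            f1 = 1.0 - f1
    if f1 > 0.99 or f1 < 0.01:
        if f1 < 0.01:
            f1, V1, z1 = 1.0 - f1, V2, z2
        fit = DoubleBoltzmannFit(Qmax, 1.0, V1, z1, float("nan"), float("nan"), Q0,
                                 resid, True, flags + ["single_component"])
    else:
        fit = DoubleBoltzmannFit(Qmax, f1, V1, z1, V2, z2, Q0, resid, True, flags)
    return fit


def normalize_qv(qv: QVCurve, fit: DoubleBoltzmannFit) -> QVCurve:
    """Attach Q/Qmax normalization (referenced to the fitted offset)."""
    if fit.Qmax <= 0:
        raise InvalidParameterError("cannot normalize by a non-positive Qmax")
    qv.q_norm = (qv.q - fit.offset) / fit.Qmax
    return qv


# --------------------------------------------------------------------------
# ON/OFF conservation QC
# --------------------------------------------------------------------------

def charge_conservation_report(
    sweeps: SweepSet,
    baseline_frac: float = 0.2,
    tolerance: float = 0.10,
    min_charge: float = 1e-9,
) -> pd.DataFrame:
    """Per-step |Q_on/Q_off| table; the master equation demands ratio 1.

    ON charge is integrated over the test step (baseline from the final
    ``baseline_frac`` of the step, where the transient has decayed), OFF
    charge over the tail.  Ratios deviating from 1 by more than ``tolerance``
    are flagged; steps moving less than ``min_charge`` nC are reported as not
    applicable (NaN ratio).
    """
    p = sweeps.protocol
    noise = float(sweeps.meta.get("cell", {}).get("noise_sd", 0.0))
    rows = []
    for Vs, tr in zip(p.step_voltages, sweeps.traces):
        # the sample exactly at the switch already carries tail-segment current
        q_on = integrate_off_charge(
            sweeps.time, tr, (p.t_step_start, p.t_tail_start - 1e-9), baseline_frac, noise
        )
        q_off = integrate_off_charge(
            sweeps.time, tr, (p.t_tail_start, float(sweeps.time[-1])), baseline_frac, noise
        )
        if min(abs(q_on), abs(q_off)) < min_charge:
            rows.append((Vs, q_on, q_off, np.nan, "n/a"))
            continue
        ratio = abs(q_on / q_off)
        flag = "" if abs(ratio - 1.0) <= tolerance else "deviation"
        rows.append((Vs, q_on, q_off, ratio, flag))
    return pd.DataFrame(rows, columns=["V_mV", "Q_on_nC", "Q_off_nC", "ratio", "flag"])
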