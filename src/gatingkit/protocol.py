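"""Voltage-step protocols and P/N leak-subtraction companions.

A protocol is a family of sweeps sharing a holding potential, a set of test
step voltages, and a fixed tail (repolarization) potential:

    hold (pre_duration) -> step V_s (step_duration) -> tail V_tail (tail_duration)

sampled uniformly at ``sample_rate`` kHz.  The standard acquisition protocol
in this package follows oocyte practice: holding at -80 or -100 mV, test steps
spanning -150..+100 mV, 30 ms pulses, 10 kHz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import InvalidParameterError


@dataclass(frozen=True)
class VoltageProtocol:
    """A pre/step/tail voltage-step family.  Voltages mV, durations ms."""

    V_hold: float
    step_voltages: tuple[float, ...]
    step_duration: float = 30.0
    V_tail: float = -50.0
    tail_duration: float = 30.0
    pre_duration: float = 5.0
    sample_rate: float = 10.0  # kHz

    def __post_init__(self) -> None:
        for name in ("step_duration", "tail_duration", "pre_duration"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be > 0")
        steps = np.asarray(self.step_voltages, dtype=float)
        if steps.size == 0:
            raise InvalidParameterError("step_voltages must not be empty")
        if steps.size > 1:
            d = np.diff(steps)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise InvalidParameterError("step_voltages must be strictly monotone")
        object.__setattr__(self, "step_voltages", tuple(float(v) for v in steps))

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sample_rate

    @property
    def t_step_start(self) -> float:
        return self.pre_duration

    @property
    def t_tail_start(self) -> float:
        """Time of the step->tail switch, ms from sweep start."""
        return self.pre_duration + self.step_duration

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.step_duration + self.tail_duration

    def times(self) -> np.ndarray:
        """Uniform time base (ms); samples at t=0, dt, ..., < total_duration."""
        n = int(round(self.total_duration / self.dt))
        return np.arange(n) * self.dt

    def segments(self, V_step: float) -> list[tuple[float, float]]:
        """(voltage, duration) pieces of one sweep."""
        return [
            (self.V_hold, self.pre_duration),
            (float(V_step), self.step_duration),
            (self.V_tail, self.tail_duration),
        ]

    def command_voltage(self, V_step: float) -> np.ndarray:
        """Piecewise-constant command voltage on the sample grid."""
        t = self.times()
        V = np.full(t.shape, self.V_hold)
        V[t >= self.t_step_start] = float(V_step)
        V[t >= self.t_tail_start] = self.V_tail
        return V


def p_over_n_subpulses(
    protocol: VoltageProtocol,
    n: int,
    scale_sign: float = 1.0,
    subpulse_hold: float | None = None,
) -> VoltageProtocol:
    """Companion protocol for P/N leak subtraction.

    Each test step's excursion from holding is scaled by ``scale_sign / n``
    and delivered from ``subpulse_hold`` (defaults to the test holding
    potential).  The tail excursion is scaled identically so every voltage
    jump of the test sweep has a 1/n image in the companion.  The classic P/8
    protocol is ``n=8, scale_sign=+1``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError("n must be an integer >= 1")
    if scale_sign not in (1.0, -1.0, 1, -1):
        raise InvalidParameterError("scale_sign must be +1 or -1")
    hold = protocol.V_hold if subpulse_hold is None else float(subpulse_hold)
    s = float(scale_sign) / n
    return replace(
        protocol,
        V_hold=hold,
        step_voltages=tuple(hold + s * (v - protocol.V_hold) for v in protocol.step_voltages),
        V_tail=hold + s * (protocol.V_tail - protocol.V_hold),
    )
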