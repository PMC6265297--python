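"""Markov gating schemes with voltage-dependent Eyring rates.

A channel is modeled as a continuous-time Markov chain over conformational
states.  Each transition carries a gating charge ``z`` (in units of e0) across
the membrane field, so its rates are voltage dependent:

    k_f(V) = k0f * exp( z * delta * V / (RT/F))
    k_b(V) = k0b * exp(-z * (1 - delta) * V / (RT/F))

with V in mV, rates in ms^-1 and ``delta`` the fraction of the charge moved
before the transition barrier (0.5 by default, a symmetric barrier).  The
per-transition equilibrium midpoint is Vd = (RT/zF) ln(k0b/k0f): at V = Vd
forward and backward rates balance.

Two builders cover the schemes used in practice: a two-state C<->O channel
whose equilibrium open probability is exactly a Boltzmann function of voltage,
and a sequential chain (default R<->I<->A) that moves its gating charge in
discrete steps, producing a multi-component Q-V curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, InvalidParameterError, PhysicalConstants


@dataclass(frozen=True)
class Transition:
    """A reversible transition between two states.

    ``z`` is the charge (e0 units) moved going source -> target; ``k0f`` and
    ``k0b`` are the zero-voltage forward/backward rates in ms^-1; ``delta`` is
    the forward charge-split fraction.
    """

    source: str
    target: str
    z: float
    k0f: float
    k0b: float
    delta: float = 0.5

    def rates(self, V: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> tuple[float, float]:
        """Forward and backward rate (ms^-1) at membrane potential V (mV)."""
        rt = constants.rt_f_mV
        kf = self.k0f * np.exp(self.z * self.delta * V / rt)
        kb = self.k0b * np.exp(-self.z * (1.0 - self.delta) * V / rt)
        return float(kf), float(kb)

    def midpoint(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Equilibrium midpoint Vd (mV) of this transition."""
        return constants.rt_f_mV / self.z * float(np.log(self.k0b / self.k0f))


@dataclass(frozen=True)
class GatingScheme:
    """A Markov gating model plus the macroscopic scaling needed for currents.

    Attributes
    ----------
    states:
        Ordered state labels.
    transitions:
        Reversible transitions; together they must connect all states.
    open_states:
        States that conduct when ``conducting`` is true.
    N:
        Number of channels folded into the macroscopic amplitude.
    gamma:
        Unitary conductance in siemens.
    Vrev:
        Reversal potential of the ionic current, mV.
    conducting:
        False emulates a W434F-like nonconducting channel: voltage-sensor
        movement (gating current) is intact but the ionic term is absent.
    """

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    open_states: frozenset
    N: float = 1e9
    gamma: float = 1e-13
    Vrev: float = 0.0
    conducting: bool = True
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        known = set(self.states)
        for t in self.transitions:
            if t.source not in known or t.target not in known:
                raise InvalidParameterError(f"transition {t.source}->{t.target} references unknown state")
        if not self._is_connected():
            raise InvalidParameterError("transition graph does not connect all states")
        if not self.open_states <= known:
            raise InvalidParameterError("open_states must be a subset of states")

    def _is_connected(self) -> bool:
        if len(self.states) == 1:
            return True
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for t in self.transitions:
            adj[t.source].add(t.target)
            adj[t.target].add(t.source)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    @property
    def total_charge(self) -> float:
        """Total gating charge per channel (e0), summed over transitions."""
        return float(sum(t.z for t in self.transitions))

    def rate_matrix(self, V: float) -> np.ndarray:
        """Generator matrix A with dp/dt = A @ p; columns sum to zero."""
        n = self.n_states
        A = np.zeros((n, n))
        for t in self.transitions:
            i, j = self.state_index(t.source), self.state_index(t.target)
            kf, kb = t.rates(V, self.constants)
            if not (np.isfinite(kf) and np.isfinite(kb)):
                raise InvalidParameterError(f"non-finite rate at V={V} mV for {t.source}->{t.target}")
            A[j, i] += kf
            A[i, i] -= kf
            A[i, j] += kb
            A[j, j] -= kb
        return A

    def equilibrium(self, V: float) -> np.ndarray:
        """Stationary state distribution at potential V (mV)."""
        A = self.rate_matrix(V)
        M = np.vstack([A, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(M, b, rcond=None)
        p = np.clip(p, 0.0, None)
        return p / p.sum()

    def po_eq(self, V) -> np.ndarray | float:
        """Equilibrium open probability at V (mV); accepts scalars or arrays."""
        Vs = np.atleast_1d(np.asarray(V, dtype=float))
        idx = [self.state_index(s) for s in self.open_states]
        po = np.array([self.equilibrium(v)[idx].sum() for v in Vs])
        return po if np.ndim(V) else float(po[0])

    def state_charges(self) -> np.ndarray:
        """Cumulative charge coordinate q_s (e0) per state, relative to states[0].

        Walks the transition graph from the first state, adding z along forward
        edges.  Well defined for trees/chains (the schemes built here).
        """
        q = {self.states[0]: 0.0}
        frontier = [self.states[0]]
        edges = list(self.transitions)
        while frontier:
            s = frontier.pop()
            for t in edges:
                if t.source == s and t.target not in q:
                    q[t.target] = q[s] + t.z
                    frontier.append(t.target)
                elif t.target == s and t.source not in q:
                    q[t.source] = q[s] - t.z
                    frontier.append(t.source)
        return np.array([q[s] for s in self.states])

    def charge_displacement(self, p: np.ndarray) -> np.ndarray:
        """z-weighted mean charge coordinate (e0 per channel) of occupancy p."""
        return np.asarray(p) @ self.state_charges()


def build_two_state_scheme(
    z: float,
    Vd: float,
    k0: float = 0.1,
    N: float = 1e9,
    gamma: float = 1e-13,
    Vrev: float = 0.0,
    conducting: bool = True,
    delta: float = 0.5,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> GatingScheme:
    """Two-state closed<->open scheme with an exact Boltzmann equilibrium.

    The equilibrium open probability is 1/(1 + exp(-zF(V-Vd)/RT)) by
    construction: rates are chosen so that k_f = k_b = ``k0`` (ms^-1) at
    V = ``Vd`` (mV) and their ratio carries the full valence ``z`` (e0).
    """
    if not z > 0:
        raise InvalidParameterError("z must be > 0")
    if not k0 > 0:
        raise InvalidParameterError("k0 must be > 0")
    rt = constants.rt_f_mV
    t = Transition(
        "C", "O", z=z,
        k0f=k0 * float(np.exp(-z * delta * Vd / rt)),
        k0b=k0 * float(np.exp(z * (1.0 - delta) * Vd / rt)),
        delta=delta,
    )
    return GatingScheme(
        states=("C", "O"), transitions=(t,), open_states=frozenset({"O"}),
        N=N, gamma=gamma, Vrev=Vrev, conducting=conducting, constants=constants,
    )


def build_sequential_scheme(
    steps: Sequence[tuple[float, float, float]],
    N: float = 1e9,
    gamma: float = 1e-13,
    Vrev: float = 0.0,
    conducting: bool = False,
    delta: float = 0.5,
    state_labels: Sequence[str] | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> GatingScheme:
    """Linear activation chain; each step is a (z, Vd, k0) triple.

    The default two-step chain R<->I<->A mimics a voltage sensor that moves in
    two discrete charge-carrying steps; the final state is the open/active
    one.  A single step reduces exactly to :func:`build_two_state_scheme`.
    """
    steps = list(steps)
    if not steps:
        raise InvalidParameterError("at least one transition is required")
    total_z = sum(s[0] for s in steps)
    if not total_z > 0:
        raise InvalidParameterError("total charge must be > 0")
    n = len(steps) + 1
    if state_labels is None:
        state_labels = ["R", "I", "A"][:n] if n <= 3 else [f"S{i}" for i in range(n)]
    if len(state_labels) != n:
        raise InvalidParameterError("need one more state label than transitions")
    rt = constants.rt_f_mV
    transitions = []
    for (zt, Vd, k0), src, tgt in zip(steps, state_labels[:-1], state_labels[1:]):
        if not (zt > 0 and k0 > 0):
            raise InvalidParameterError("each step needs z > 0 and k0 > 0")
        transitions.append(Transition(
            src, tgt, z=zt,
            k0f=k0 * float(np.exp(-zt * delta * Vd / rt)),
            k0b=k0 * float(np.exp(zt * (1.0 - delta) * Vd / rt)),
            delta=delta,
        ))
    return GatingScheme(
        states=tuple(state_labels), transitions=tuple(transitions),
        open_states=frozenset({state_labels[-1]}),
        N=N, gamma=gamma, Vrev=Vrev, conducting=conducting, constants=constants,
    )


def with_constants(scheme: GatingScheme, constants: PhysicalConstants) -> GatingScheme:
    """Return a copy of ``scheme`` using different physical constants."""
    return replace(scheme, constants=constants)
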