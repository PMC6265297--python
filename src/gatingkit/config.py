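"""Validated run configuration: schemes, protocols, cell and analysis options.

A single YAML file is the source of truth for an end-to-end run.  Validation
is strict -- unknown keys are rejected and errors name the offending key --
and a round trip through :func:`save_config` / :func:`load_config` is
lossless (defaults filled in).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .constants import PhysicalConstants
from .protocol import VoltageProtocol
from .scheme import GatingScheme, build_sequential_scheme, build_two_state_scheme
from .simulate import CellModel


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TwoStateSchemeSpec(_Strict):
    kind: Literal["two_state"] = "two_state"
    z: float = Field(gt=0, description="gating valence, e0")
    Vd: float = Field(description="equilibrium midpoint, mV")
    k0: float = Field(default=0.1, gt=0, description="rate at Vd, ms^-1")
    N: float = Field(default=1e9, ge=0)
    gamma: float = Field(default=1e-13, gt=0, description="effective unitary conductance, S")
    Vrev: float = 0.0
    conducting: bool = True


class ChainStepSpec(_Strict):
    z: float = Field(gt=0)
    Vd: float
    k0: float = Field(default=0.3, gt=0)


class SequentialSchemeSpec(_Strict):
    kind: Literal["sequential"] = "sequential"
    steps: list[ChainStepSpec] = Field(min_length=1)
    N: float = Field(default=1e9, ge=0)
    gamma: float = Field(default=1e-13, gt=0)
    Vrev: float = 0.0
    conducting: bool = False


SchemeSpec = Union[TwoStateSchemeSpec, SequentialSchemeSpec]


class ProtocolSpec(_Strict):
    V_hold: float = -80.0
    V_start: float = -80.0
    V_stop: float = 60.0
    V_increment: float = Field(default=5.0, gt=0)
    step_duration: float = Field(default=30.0, gt=0)
    V_tail: float = -50.0
    tail_duration: float = Field(default=30.0, gt=0)
    pre_duration: float = Field(default=5.0, gt=0)
    sample_rate: float = Field(default=10.0, gt=0, description="kHz")

    @field_validator("V_stop")
    @classmethod
    def _ordered(cls, v, info):
        if "V_start" in info.data and v < info.data["V_start"]:
            raise ValueError("V_stop must be >= V_start")
        return v


class CellSpec(_Strict):
    C_lin: float = Field(default=0.2, ge=0, description="nC/mV")
    tau_clamp: float = Field(default=0.1, gt=0, description="ms")
    g_leak: float = Field(default=0.0, ge=0, description="uS")
    E_leak: float = -80.0
    noise_sd: float = Field(default=0.0, ge=0, description="uA")
    filter_kHz: float = Field(default=0.0, ge=0, description="acquisition low-pass; 0 = off")


class AnalysisSpec(_Strict):
    method: Literal["tail", "chord"] = "tail"
    tail_window: tuple[float, float] = (2.0, 4.0)
    Vrev: float = 0.0
    cap_fit_range: tuple[float, float] = (50.0, 70.0)
    blank: float = Field(default=0.3, ge=0, description="post-switch blank for kinetics, ms")
    temperature_K: float = Field(default=295.15, gt=0)


class ConstructSpec(_Strict):
    scheme: SchemeSpec = Field(discriminator="kind")
    mode: Literal["ionic", "gating"] = "ionic"


class RunConfig(_Strict):
    """Full configuration of a simulate-and-analyze run."""

    constructs: dict[str, ConstructSpec]
    pairs: list[tuple[str, str]] = Field(default_factory=list, description="(aa, ah) construct names")
    protocol: ProtocolSpec = Field(default_factory=ProtocolSpec)
    gating_protocol: Optional[ProtocolSpec] = None
    cell: CellSpec = Field(default_factory=CellSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)
    p_over_n: int = Field(default=8, ge=1)
    seed: int = Field(default=0, ge=0)
    output_prefix: str = "run"

    @field_validator("pairs")
    @classmethod
    def _pairs_known(cls, v, info):
        names = set(info.data.get("constructs", {}))
        for aa, ah in v:
            if aa not in names or ah not in names:
                raise ValueError(f"pairs references unknown construct in ({aa}, {ah})")
        return v


# gating-current acquisition: hold -100, steps -150..+100, return to holding;
# fast sampling so the OFF transient is resolved for trapezoidal integration
DEFAULT_GATING_PROTOCOL = ProtocolSpec(
    V_hold=-100.0, V_start=-150.0, V_stop=100.0, V_increment=5.0,
    V_tail=-100.0, step_duration=30.0, tail_duration=30.0, sample_rate=500.0,
)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ValueError("empty configuration file")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    """Serialize a configuration (with defaults filled) back to YAML."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


# ---- spec -> domain-object builders --------------------------------------

def build_scheme(spec: SchemeSpec, constants: PhysicalConstants) -> GatingScheme:
    if spec.kind == "two_state":
        return build_two_state_scheme(
            z=spec.z, Vd=spec.Vd, k0=spec.k0, N=spec.N, gamma=spec.gamma,
            Vrev=spec.Vrev, conducting=spec.conducting, constants=constants,
        )
    return build_sequential_scheme(
        [(s.z, s.Vd, s.k0) for s in spec.steps], N=spec.N, gamma=spec.gamma,
        Vrev=spec.Vrev, conducting=spec.conducting, constants=constants,
    )


def build_protocol(spec: ProtocolSpec) -> VoltageProtocol:
    steps = tuple(np.arange(spec.V_start, spec.V_stop + spec.V_increment / 2, spec.V_increment))
    return VoltageProtocol(
        V_hold=spec.V_hold, step_voltages=steps, step_duration=spec.step_duration,
        V_tail=spec.V_tail, tail_duration=spec.tail_duration,
        pre_duration=spec.pre_duration, sample_rate=spec.sample_rate,
    )
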