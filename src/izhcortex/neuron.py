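"""Izhikevich two-variable neuron: dynamics, reset rule, and cortical phenotypes.

The model couples a fast membrane potential ``v`` (mV) with a slow recovery
variable ``u``::

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the algebraic reset: if v > 30 mV then v <- c, u <- u + d.  The four
parameters (a, b, c, d) select the firing phenotype; the five cortical
phenotypes used here are regular spiking (RS), intrinsically bursting (IB),
chattering (CH), fast spiking (FS) and low-threshold spiking (LTS).

Scalar operations here are the reference semantics; the simulation engine
re-implements the same update vectorised over the whole population.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPIKE_CUTOFF_MV",
    "SpikingType",
    "NeuronParameters",
    "NeuronState",
    "UnknownPhenotypeError",
    "phenotype_parameters",
    "derivatives",
    "step",
]

#: Spike detection threshold (mV); the reset fires when v exceeds this.
SPIKE_CUTOFF_MV = 30.0


class SpikingType(enum.Enum):
    """The five cortical firing phenotypes."""

    RS = "RS"   # regular spiking
    IB = "IB"   # intrinsically bursting
    CH = "CH"   # chattering
    FS = "FS"   # fast spiking
    LTS = "LTS"  # low-threshold spiking


class UnknownPhenotypeError(KeyError):
    """Raised when a spiking-type label does not name one of the five phenotypes."""


@dataclass(frozen=True)
class NeuronParameters:
    """Izhikevich parameter quadruple for one phenotype.

    a : recovery rate (1/ms)
    b : sensitivity of u to subthreshold v (1/ms)
    c : post-spike reset potential (mV)
    d : post-spike increment of u
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.d >= 0):
            raise ValueError(f"require a > 0, b > 0, d >= 0, got {self}")
        if not self.c < SPIKE_CUTOFF_MV:
            raise ValueError(f"reset potential c={self.c} must lie below {SPIKE_CUTOFF_MV} mV")


@dataclass
class NeuronState:
    """Instantaneous state of one neuron: membrane potential v (mV), recovery u."""

    v: float
    u: float


# Phenotype parameter sets (a, b, c, d).  Note FS uses a=0.05 and LTS a=0.1,
# b=0.25 in this parameterisation.
_PHENOTYPES: dict[SpikingType, NeuronParameters] = {
    SpikingType.RS: NeuronParameters(a=0.02, b=0.2, c=-65.0, d=8.0),
    SpikingType.IB: NeuronParameters(a=0.02, b=0.2, c=-55.0, d=4.0),
    SpikingType.CH: NeuronParameters(a=0.02, b=0.2, c=-50.0, d=2.0),
    SpikingType.FS: NeuronParameters(a=0.05, b=0.2, c=-50.0, d=2.0),
    SpikingType.LTS: NeuronParameters(a=0.1, b=0.25, c=-50.0, d=2.0),
}


def phenotype_parameters(spiking_type: SpikingType | str) -> NeuronParameters:
    """Return the (a, b, c, d) quadruple for a firing phenotype.

    Accepts either a :class:`SpikingType` member or its string label.
    Raises :class:`UnknownPhenotypeError` for anything else.
    """
    if isinstance(spiking_type, str):
        try:
            spiking_type = SpikingType(spiking_type)
        except ValueError as exc:
            raise UnknownPhenotypeError(f"unknown spiking type {spiking_type!r}") from exc
    if not isinstance(spiking_type, SpikingType):
        raise UnknownPhenotypeError(f"unknown spiking type {spiking_type!r}")
    return _PHENOTYPES[spiking_type]


def derivatives(
    state: NeuronState, current: float, params: NeuronParameters
) -> tuple[float, float]:
    """Right-hand side (dv/dt, du/dt) of the Izhikevich equations.

    ``current`` is the total input I (synaptic + noise + external) in the
    model's current units.  Non-finite state or input is rejected.
    """
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(current)):
        raise ValueError(f"non-finite state/input: v={state.v}, u={state.u}, I={current}")
    dv = 0.04 * state.v * state.v + 5.0 * state.v + 140.0 - state.u + current
    du = params.a * (params.b * state.v - state.u)
    return dv, du


def step(
    state: NeuronState,
    current: float,
    params: NeuronParameters,
    dt: float = 0.5,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt`` ms (forward Euler) and apply the reset.

    Returns the new state and whether a spike occurred.  After the reset the
    returned ``v`` equals ``c`` exactly and ``u`` has grown by ``d``; the
    returned ``v`` therefore never exceeds the 30 mV cutoff.

    dt must be positive and at most 1 ms (forward Euler is the conventional
    scheme for this model family; 0.5 ms keeps it stable and accurate while
    two substeps fill each 1 ms recording interval).
    """
    if not 0.0 < dt <= 1.0:
        raise ValueError(f"dt must lie in (0, 1] ms, got {dt}")
    dv, du = derivatives(state, current, params)
    v = state.v + dt * dv
    u = state.u + dt * du
    spiked = v > SPIKE_CUTOFF_MV
    if spiked:
        v = params.c
        u = u + params.d
    return NeuronState(v=v, u=u), bool(spiked)


def simulate_single(
    params: NeuronParameters,
    current: float,
    duration_ms: float,
    dt: float = 0.5,
    v0: float | None = None,
    u0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one isolated neuron under constant drive.

    Returns ``(t, v, spike_times)``: the time grid, the recorded membrane
    trace (clamped at 30 mV on spike steps, so spikes have uniform height),
    and the spike times in ms.  Starts from the phenotype's rest convention
    (v = c, u = b*v) unless overridden.
    """
    v = params.c if v0 is None else v0
    u = params.b * v if u0 is None else u0
    state = NeuronState(v=v, u=u)
    n_steps = int(round(duration_ms / dt))
    t = np.arange(1, n_steps + 1) * dt
    trace = np.empty(n_steps)
    spikes: list[float] = []
    for k in range(n_steps):
        state, spiked = step(state, current, params, dt)
        trace[k] = SPIKE_CUTOFF_MV if spiked else state.v
        if spiked:
            spikes.append(t[k])
    return t, trace, np.asarray(spikes)
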