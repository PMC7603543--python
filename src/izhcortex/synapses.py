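"""Receptor conductance dynamics.

Each neuron carries one conductance-like drive variable g per receptor class
(AMPA, NMDA, GABA).  Between spikes g relaxes exponentially,
dg/dt = -g/tau, integrated exactly (g <- g * exp(-dt/tau), unconditionally
stable for any dt); each presynaptic spike arriving on an edge of weight W
increments the target's g for the edge's receptor by W, convergent spikes
summing.  The default coupling into the membrane equation is current-based,

    I_syn = g_AMPA + g_NMDA - g_GABA,

so excitatory receptors depolarise and GABA hyperpolarises; a
conductance-based alternative I_syn = sum_r g_r * (E_r - v) is available as
a configuration switch.

Defaults: tau_AMPA = 5 ms, tau_NMDA = 150 ms, tau_GABA = 10 ms — standard
literature values for these receptor classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RECEPTORS, Adjacency, SynapseSpec

__all__ = [
    "ReceptorParams",
    "SynapticState",
    "REVERSAL_POTENTIALS_MV",
    "decay_step",
    "apply_spikes",
    "synaptic_current",
]

#: Reversal potentials (mV) for the optional conductance-based coupling.
REVERSAL_POTENTIALS_MV = {"AMPA": 0.0, "NMDA": 0.0, "GABA": -70.0}


@dataclass(frozen=True)
class ReceptorParams:
    """Decay time constant of one receptor class."""

    receptor: str
    tau: float  # ms

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass
class SynapticState:
    """Per-neuron, per-receptor conductances: array of shape (n_neurons, 3)
    with columns ordered (AMPA, NMDA, GABA).  Entries stay non-negative under
    decay and non-negative weight increments."""

    g: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int) -> "SynapticState":
        return cls(g=np.zeros((n_neurons, len(RECEPTORS))))

    @classmethod
    def random_initial(cls, n_neurons: int, rng: np.random.Generator) -> "SynapticState":
        """Initial conductances drawn uniformly on [0, 1) per neuron per receptor."""
        return cls(g=rng.random((n_neurons, len(RECEPTORS))))

    def column(self, receptor: str) -> np.ndarray:
        return self.g[:, RECEPTORS.index(receptor)]


def decay_factors(spec: SynapseSpec, dt: float) -> np.ndarray:
    """exp(-dt/tau) per receptor column, the exact one-step decay."""
    taus = np.array([spec.tau_ampa_ms, spec.tau_nmda_ms, spec.tau_gaba_ms])
    return np.exp(-dt / taus)


def decay_step(state: SynapticState, spec: SynapseSpec, dt: float) -> SynapticState:
    """Relax every conductance over one step: g <- g * exp(-dt/tau)."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return SynapticState(g=state.g * decay_factors(spec, dt))


def apply_spikes(
    state: SynapticState, adjacency: Adjacency, spiked
) -> SynapticState:
    """Deliver one step's spikes: every edge (s, t, W) whose source s spiked
    increments the target's g for the edge's receptor by W; convergent spikes
    sum.  Unknown neuron indices are rejected."""
    spiked = np.asarray(sorted(set(int(i) for i in spiked)), dtype=np.int64)
    if spiked.size and (spiked.min() < 0 or spiked.max() >= adjacency.n_neurons):
        raise IndexError(
            f"spiked neuron indices out of range [0, {adjacency.n_neurons})"
        )
    g = state.g.copy()
    if spiked.size:
        for es in adjacency.edge_sets:
            if es.n_edges == 0:
                continue
            hit = np.isin(es.src, spiked)
            if hit.any():
                col = RECEPTORS.index(es.receptor)
                np.add.at(g[:, col], es.tgt[hit], es.weight)
    return SynapticState(g=g)


def synaptic_current(
    state: SynapticState, spec: SynapseSpec = SynapseSpec(), v: np.ndarray | None = None
) -> np.ndarray:
    """Per-neuron synaptic drive entering the membrane equation's I term.

    Current coupling (default): I = g_AMPA + g_NMDA - g_GABA.
    Conductance coupling: I = sum_r g_r * (E_r - v) (requires v).
    """
    if spec.coupling == "current":
        return state.column("AMPA") + state.column("NMDA") - state.column("GABA")
    if spec.coupling == "conductance":
        if v is None:
            raise ValueError("conductance coupling requires the membrane potentials v")
        i_syn = np.zeros(state.g.shape[0])
        for receptor, e_rev in REVERSAL_POTENTIALS_MV.items():
            i_syn += state.column(receptor) * (e_rev - v)
        return i_syn
    raise ValueError(f"unknown coupling {spec.coupling!r}")
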