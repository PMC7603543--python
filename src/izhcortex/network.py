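"""Construction of the layered cortical circuit.

The default circuit has 17 neuronal groups — 8 excitatory (pyramidal and
spiny stellate cells, 8000 neurons) and 9 inhibitory (non-basket and basket
GABAergic cells, 2000 neurons) — distributed over cortical layers L1-L6.
Every ordered pair of groups (including a group with itself) is wired by an
independent Bernoulli draw per neuron pair ("sparse" connectivity), all
edges of a pair carrying one scalar weight.  An excitatory source drives its
targets through the AMPA or NMDA conductance of the target, an inhibitory
source through the GABA conductance; which receptor a group drives is a
property of the source group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neuron import SpikingType, phenotype_parameters

__all__ = [
    "CELL_CLASSES",
    "LAYERS",
    "RECEPTORS",
    "GroupSpec",
    "ConnectionSpec",
    "NoiseSpec",
    "RunSpec",
    "SynapseSpec",
    "PlasticitySpec",
    "NetworkConfig",
    "EdgeSet",
    "Adjacency",
    "InvalidConfigError",
    "default_cortex_config",
    "scaled_config",
    "validate",
    "build_adjacency",
]

CELL_CLASSES = ("pyramidal", "spiny", "GABA_nb", "GABA_b")
EXCITATORY_CLASSES = ("pyramidal", "spiny")
LAYERS = ("L1", "L2", "L2/3", "L3", "L4", "L5", "L5/6", "L6")
RECEPTORS = ("AMPA", "NMDA", "GABA")


class InvalidConfigError(ValueError):
    """Raised when an operation receives a configuration that fails validation."""


@dataclass(frozen=True)
class GroupSpec:
    """One neuronal population: cell class, layer, size, phenotype, receptor.

    ``receptor`` names the conductance this group drives in its *targets*
    (AMPA/NMDA for excitatory sources, GABA for inhibitory ones).
    """

    name: str
    cell_class: str
    layer: str
    count: int
    spiking_type: SpikingType
    receptor: str

    @property
    def polarity(self) -> str:
        return "excitatory" if self.cell_class in EXCITATORY_CLASSES else "inhibitory"


@dataclass(frozen=True)
class ConnectionSpec:
    """Sparse block connection between two groups.

    ``sparseness`` is the independent probability that any (source, target)
    neuron pair is connected; ``weight`` (mV-equivalent drive units) is added
    to the target's receptor conductance per presynaptic spike.  Weights are
    non-negative; the sign of the effect is carried by the receptor.
    """

    source: str
    target: str
    sparseness: float = 0.1
    weight: float = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic thalamic drive: i.i.d. Gaussian current into selected layers.

    The thalamocortical afferents are abstracted as a zero-mean Gaussian
    current, redrawn each time step, delivered to layers L2/3, L4 and L6 with
    standard deviation ``sigma_exc`` for excitatory and ``sigma_inh`` for
    inhibitory target neurons.
    """

    target_layers: tuple[str, ...] = ("L2/3", "L4", "L6")
    sigma_exc: float = 5.0
    sigma_inh: float = 2.0


@dataclass(frozen=True)
class RunSpec:
    """Run settings: duration and integration step in ms, RNG seed, and an
    optional constant external current applied to every neuron."""

    duration_ms: float = 150.0
    dt_ms: float = 0.5
    seed: int = 0
    i_ext: float = 0.0


@dataclass(frozen=True)
class SynapseSpec:
    """Receptor decay time constants (ms) and the conductance-to-current rule.

    ``coupling`` is "current" (I_syn = g_AMPA + g_NMDA - g_GABA) or
    "conductance" (each receptor contributes g*(E_rev - v)).
    """

    tau_ampa_ms: float = 5.0
    tau_nmda_ms: float = 150.0
    tau_gaba_ms: float = 10.0
    coupling: str = "current"


@dataclass(frozen=True)
class PlasticitySpec:
    """Rate-based Hebbian updating of connection weights (off by default)."""

    enabled: bool = False
    eta: float = 0.0
    epoch_ms: float = 50.0


@dataclass(frozen=True)
class NetworkConfig:
    """Complete declarative description of a circuit and how to run it."""

    groups: tuple[GroupSpec, ...]
    connections: tuple[ConnectionSpec, ...]
    noise: NoiseSpec = NoiseSpec()
    run: RunSpec = RunSpec()
    synapses: SynapseSpec = SynapseSpec()
    plasticity: PlasticitySpec = PlasticitySpec()

    @property
    def n_neurons(self) -> int:
        return sum(g.count for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def group_offsets(self) -> dict[str, tuple[int, int]]:
        """Global neuron index range [start, stop) of each group, in config order."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        for g in self.groups:
            out[g.name] = (start, start + g.count)
            start += g.count
        return out

    @property
    def excitatory_fraction(self) -> float:
        n_exc = sum(g.count for g in self.groups if g.polarity == "excitatory")
        return n_exc / self.n_neurons


# Tables of the default circuit.  Excitatory rows: (name, cell class, layer,
# count, phenotype); receptor follows the source class/layer (pyramidal and
# spiny cells in L2/3 and L4 drive AMPA, deep pyramidal cells drive NMDA).
_EXCITATORY_ROWS = [
    ("RS_p23",   "pyramidal", "L2/3", 2500, "RS", "AMPA"),
    ("RS_p4",    "pyramidal", "L4",   1000, "RS", "AMPA"),
    ("CH_p23",   "pyramidal", "L2/3",  500, "CH", "AMPA"),
    ("IB_p56_1", "pyramidal", "L5/6",  100, "IB", "NMDA"),
    ("CH_p4",    "pyramidal", "L4",   1400, "CH", "AMPA"),
    ("IB_p56_2", "pyramidal", "L5/6",  500, "IB", "NMDA"),
    ("RS_ss4",   "spiny",     "L4",   1000, "RS", "AMPA"),
    ("RS_ss23",  "spiny",     "L2/3", 1000, "RS", "AMPA"),
]
_INHIBITORY_ROWS = [
    ("LTS_nb1", "GABA_nb", "L1", 200, "LTS", "GABA"),
    ("LTS_nb2", "GABA_nb", "L2", 400, "LTS", "GABA"),
    ("LTS_nb4", "GABA_nb", "L4", 200, "LTS", "GABA"),
    ("LTS_nb5", "GABA_nb", "L5", 100, "LTS", "GABA"),
    ("LTS_nb6", "GABA_nb", "L6", 200, "LTS", "GABA"),
    ("FS_b2",   "GABA_b",  "L2", 200, "FS",  "GABA"),
    ("FS_b4",   "GABA_b",  "L4", 400, "FS",  "GABA"),
    ("FS_b5",   "GABA_b",  "L5", 100, "FS",  "GABA"),
    ("FS_b6",   "GABA_b",  "L6", 200, "FS",  "GABA"),
]


def default_cortex_config(sparseness: float = 0.1, weight: float = 10.0) -> NetworkConfig:
    """The full 10,000-neuron cortical circuit.

    8 excitatory groups (8000 neurons) and 9 inhibitory groups (2000
    neurons), all ordered group pairs (including recurrent self-connections)
    wired at the given sparseness and weight.
    """
    groups = tuple(
        GroupSpec(name, cls, layer, count, SpikingType(st), rec)
        for name, cls, layer, count, st, rec in _EXCITATORY_ROWS + _INHIBITORY_ROWS
    )
    names = [g.name for g in groups]
    connections = tuple(
        ConnectionSpec(src, tgt, sparseness=sparseness, weight=weight)
        for src in names
        for tgt in names
    )
    return NetworkConfig(groups=groups, connections=connections)


def scaled_config(config: NetworkConfig, factor: float) -> NetworkConfig:
    """Scale every group's neuron count by ``factor`` (rounded, floor 1),
    preserving composition ratios, connectivity and all other settings."""
    groups = tuple(
        replace(g, count=max(1, int(round(g.count * factor)))) for g in config.groups
    )
    return replace(config, groups=groups)


def validate(
    config: NetworkConfig, expected_excitatory_fraction: float | None = None
) -> list[str]:
    """Check all structural invariants; returns a list of violations (empty = valid).

    ``expected_excitatory_fraction`` additionally enforces the circuit-level
    excitatory/inhibitory split (0.8 for the default cortex).
    """
    violations: list[str] = []
    names = [g.name for g in config.groups]
    if len(set(names)) != len(names):
        violations.append("group names are not unique")
    if not config.groups:
        violations.append("config has no groups")
    for g in config.groups:
        prefix = f"group {g.name!r}:"
        if g.count <= 0:
            violations.append(f"{prefix} count must be positive, got {g.count}")
        if g.cell_class not in CELL_CLASSES:
            violations.append(f"{prefix} unknown cell class {g.cell_class!r}")
        if g.layer not in LAYERS:
            violations.append(f"{prefix} unknown layer {g.layer!r}")
        if g.receptor not in RECEPTORS:
            violations.append(f"{prefix} unknown receptor {g.receptor!r}")
        else:
            if g.polarity == "inhibitory" and g.receptor != "GABA":
                violations.append(f"{prefix} inhibitory group must drive GABA, got {g.receptor}")
            if g.polarity == "excitatory" and g.receptor == "GABA":
                violations.append(f"{prefix} excitatory group cannot drive GABA")
        try:
            phenotype_parameters(g.spiking_type)
        except Exception:
            violations.append(f"{prefix} unknown spiking type {g.spiking_type!r}")
    known = set(names)
    for c in config.connections:
        prefix = f"connection {c.source}->{c.target}:"
        if c.source not in known:
            violations.append(f"{prefix} unknown source group {c.source!r}")
        if c.target not in known:
            violations.append(f"{prefix} unknown target group {c.target!r}")
        if not 0.0 <= c.sparseness <= 1.0:
            violations.append(f"{prefix} sparseness must lie in [0, 1], got {c.sparseness}")
        if c.weight < 0:
            violations.append(f"{prefix} weight must be non-negative, got {c.weight}")
    if config.noise.sigma_exc < 0 or config.noise.sigma_inh < 0:
        violations.append("noise sigma values must be non-negative")
    for layer in config.noise.target_layers:
        if layer not in LAYERS:
            violations.append(f"noise: unknown target layer {layer!r}")
    if config.run.duration_ms <= 0:
        violations.append(f"run: duration must be positive, got {config.run.duration_ms}")
    if not 0.0 < config.run.dt_ms <= 1.0:
        violations.append(f"run: dt must lie in (0, 1] ms, got {config.run.dt_ms}")
    for tau_name in ("tau_ampa_ms", "tau_nmda_ms", "tau_gaba_ms"):
        if getattr(config.synapses, tau_name) <= 0:
            violations.append(f"synapses: {tau_name} must be positive")
    if config.synapses.coupling not in ("current", "conductance"):
        violations.append(f"synapses: unknown coupling {config.synapses.coupling!r}")
    if config.plasticity.eta < 0:
        violations.append("plasticity: eta must be non-negative")
    if config.plasticity.epoch_ms <= 0:
        violations.append("plasticity: epoch_ms must be positive")
    if expected_excitatory_fraction is not None and config.groups and not violations:
        frac = config.excitatory_fraction
        if abs(frac - expected_excitatory_fraction) > 1e-12:
            violations.append(
                f"excitatory fraction {frac:.4f} != expected {expected_excitatory_fraction}"
            )
    return violations


@dataclass
class EdgeSet:
    """Realised edges of one ConnectionSpec, in global neuron indices."""

    source: str
    target: str
    receptor: str
    weight: float
    src: np.ndarray  # int64 global source indices
    tgt: np.ndarray  # int64 global target indices

    @property
    def n_edges(self) -> int:
        return int(self.src.size)


@dataclass
class Adjacency:
    """All realised edges of a circuit.

    Edges are grouped per ConnectionSpec (preserving config order); the
    receptor of an edge set is the receptor its *source* group drives.
    """

    n_neurons: int
    edge_sets: list[EdgeSet] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return sum(es.n_edges for es in self.edge_sets)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.edge_sets:
            return pd.DataFrame(
                {"source_id": np.array([], dtype=np.int64),
                 "target_id": np.array([], dtype=np.int64),
                 "weight_mV": np.array([], dtype=float),
                 "receptor": np.array([], dtype=object)}
            )
        frames = [
            pd.DataFrame(
                {"source_id": es.src, "target_id": es.tgt,
                 "weight_mV": np.full(es.n_edges, es.weight),
                 "receptor": np.full(es.n_edges, es.receptor, dtype=object)}
            )
            for es in self.edge_sets
        ]
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def receptor_matrices(self):
        """Per-receptor sparse weight matrices W with W[target, source] = weight.

        Returns a dict {receptor: csr_matrix of shape (n, n)}; delivering the
        spikes of a boolean source vector ``s`` adds ``W @ s`` to the
        corresponding conductance array.
        """
        from scipy import sparse

        out = {}
        n = self.n_neurons
        for receptor in RECEPTORS:
            sets = [es for es in self.edge_sets if es.receptor == receptor]
            if not sets:
                out[receptor] = sparse.csr_matrix((n, n))
                continue
            rows = np.concatenate([es.tgt for es in sets])
            cols = np.concatenate([es.src for es in sets])
            vals = np.concatenate([np.full(es.n_edges, es.weight) for es in sets])
            out[receptor] = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, n)
            )
        return out


def build_adjacency(config: NetworkConfig, seed: int) -> Adjacency:
    """Realise the sparse connectivity: each neuron pair of each connection is
    wired independently with probability ``sparseness``.

    Self-edges (a neuron onto itself) are excluded in recurrent within-group
    connections.  Deterministic given the seed (edge lists are reproduced bit
    for bit).
    """
    problems = validate(config)
    if problems:
        raise InvalidConfigError("; ".join(problems))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    offsets = config.group_offsets()
    adjacency = Adjacency(n_neurons=config.n_neurons)
    for conn in config.connections:
        src_group = config.group(conn.source)
        off_s, _ = offsets[conn.source]
        off_t, _ = offsets[conn.target]
        n_s = src_group.count
        n_t = config.group(conn.target).count
        recurrent = conn.source == conn.target
        if conn.sparseness <= 0.0:
            flat = np.array([], dtype=np.int64)
        elif conn.sparseness >= 1.0:
            flat = np.arange(n_s * n_t, dtype=np.int64)
        else:
            flat = np.flatnonzero(rng.random(n_s * n_t) < conn.sparseness)
        src = flat // n_t
        tgt = flat % n_t
        if recurrent and flat.size:
            keep = src != tgt
            src, tgt = src[keep], tgt[keep]
        adjacency.edge_sets.append(
            EdgeSet(
                source=conn.source,
                target=conn.target,
                receptor=src_group.receptor,
                weight=float(conn.weight),
                src=src + off_s,
                tgt=tgt + off_t,
            )
        )
    return adjacency
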