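"""Time-stepping engine for the full circuit, with the standard recorders.

One step of size dt (default 0.5 ms) does, in order:

1. assemble the input current I = synaptic drive + thalamic noise + any
   constant external current;
2. advance all membranes by forward Euler and apply the spike reset;
3. relax all receptor conductances (exact exponential decay);
4. deliver this step's spikes to their targets (so a spike influences its
   targets from the next step on — an implicit one-step synaptic delay).

Observables are recorded on a fixed 1 ms grid regardless of dt: the spike
raster, per-group spike counts per 1 ms bin (the population firing rate),
(v, u, g) traces for one probe neuron per group, and optionally the full
membrane-potential matrix used by the synchrony measure.  In recorded traces
v is clamped to 30 mV on the step a spike occurs, so plotted spikes have
uniform height; the reset value is what enters the next step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .neuron import SPIKE_CUTOFF_MV, phenotype_parameters
from .network import RECEPTORS, Adjacency, NetworkConfig, build_adjacency, validate
from .network import InvalidConfigError
from .noise import noise_current, noise_sigma_per_neuron
from .plasticity import hebbian_update
from .synapses import SynapticState, decay_factors, synaptic_current

__all__ = [
    "NetworkState",
    "RecordingSet",
    "SimulationError",
    "run",
    "write_recordings",
    "read_recordings",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("t_ms", "v_mV", "u", "g_ampa", "g_nmda", "g_gaba")


class SimulationError(RuntimeError):
    """Raised when the network state becomes non-finite (numerical explosion)."""


@dataclass
class NetworkState:
    """Complete simulation state at time t."""

    v: np.ndarray
    u: np.ndarray
    syn: SynapticState
    adjacency: Adjacency
    t: float = 0.0


@dataclass
class RecordingSet:
    """Recorded observables of one run, all on the 1 ms grid.

    raster      : DataFrame (t_ms, neuron_id, group), one row per spike event
                  (t_ms is the dt-resolution step end time).
    traces      : {group name: DataFrame with TRACE_COLUMNS} for probe neurons.
    rates       : DataFrame (t_ms, group, count): spikes per group per 1 ms bin,
                  bins labelled by their start time.
    v_matrix    : optional (n_neurons, n_samples) clamped membrane potentials.
    sample_times: times (ms) of the trace/v_matrix samples (0, 1, ..., duration).
    """

    raster: pd.DataFrame
    traces: dict[str, pd.DataFrame]
    rates: pd.DataFrame
    group_names: tuple[str, ...]
    group_slices: dict[str, tuple[int, int]]
    sample_times: np.ndarray
    v_matrix: np.ndarray | None = None
    probe_ids: dict[str, int] = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.raster)

    def group_trace_matrix(self, group: str) -> np.ndarray:
        """Membrane-potential rows of one group (requires v_matrix recording)."""
        if self.v_matrix is None:
            raise ValueError("run was executed without record_v_matrix=True")
        start, stop = self.group_slices[group]
        return self.v_matrix[start:stop]


def _rates_from_raster(
    raster: pd.DataFrame, group_names, duration_ms: float
) -> pd.DataFrame:
    """Bin raster events per group on the 1 ms grid; bin k covers (k, k+1]."""
    n_bins = int(round(duration_ms))
    t_bins = np.arange(n_bins, dtype=float)
    frames = []
    for name in group_names:
        counts = np.zeros(n_bins, dtype=np.int64)
        events = raster.loc[raster["group"] == name, "t_ms"].to_numpy()
        if events.size:
            bins = np.ceil(events - 1e-9).astype(np.int64) - 1
            np.clip(bins, 0, n_bins - 1, out=bins)
            np.add.at(counts, bins, 1)
        frames.append(pd.DataFrame({"t_ms": t_bins, "group": name, "count": counts}))
    return pd.concat(frames, ignore_index=True)


def run(
    config: NetworkConfig,
    seed: int | None = None,
    record_v_matrix: bool = True,
    adjacency: Adjacency | None = None,
) -> RecordingSet:
    """Simulate the circuit and return its recordings.

    All randomness (connectivity, initial conditions, noise) derives from one
    seed (``config.run.seed`` unless overridden here) through named
    substreams, so identical config + seed gives identical output bit for bit.
    """
    problems = validate(config)
    if problems:
        raise InvalidConfigError("; ".join(problems))
    if seed is None:
        seed = config.run.seed
    dt = config.run.dt_ms
    duration = config.run.duration_ms
    n = config.n_neurons
    offsets = config.group_offsets()

    root = np.random.SeedSequence(seed)
    ss_conn, ss_init, ss_noise = root.spawn(3)
    if adjacency is None:
        adjacency = build_adjacency(config, int(ss_conn.generate_state(1)[0] & 0x7FFFFFFF))
    init_rng = np.random.default_rng(ss_init)
    noise_seed = int(ss_noise.generate_state(1)[0] & 0x7FFFFFFF)

    # Per-neuron phenotype parameter arrays.
    a = np.empty(n); b = np.empty(n); c = np.empty(n); d = np.empty(n)
    group_of = np.empty(n, dtype=object)
    for g in config.groups:
        start, stop = offsets[g.name]
        p = phenotype_parameters(g.spiking_type)
        a[start:stop], b[start:stop], c[start:stop], d[start:stop] = p.a, p.b, p.c, p.d
        group_of[start:stop] = g.name

    # Initial conditions: rest at the reset potential with a small jitter to
    # break symmetry; u on its nullcline; conductances random on [0, 1).
    v = c + 5.0 * init_rng.random(n)
    u = b * v
    syn = SynapticState.random_initial(n, init_rng)

    sigma = noise_sigma_per_neuron(config)
    decay = decay_factors(config.synapses, dt)
    weights = adjacency.receptor_matrices()
    plasticity = config.plasticity

    n_steps = int(round(duration / dt))
    steps_per_ms = int(round(1.0 / dt))
    if abs(steps_per_ms * dt - 1.0) > 1e-9:
        raise InvalidConfigError(f"dt={dt} must divide the 1 ms recording grid")
    n_samples = int(round(duration)) + 1
    sample_times = np.arange(n_samples, dtype=float)

    probe_ids = {g.name: offsets[g.name][0] for g in config.groups}
    probe_idx = np.array(list(probe_ids.values()))
    trace_buf = np.empty((n_samples, probe_idx.size, 5))
    v_matrix = np.empty((n, n_samples)) if record_v_matrix else None

    def take_sample(m: int, v_rec: np.ndarray) -> None:
        trace_buf[m, :, 0] = v_rec[probe_idx]
        trace_buf[m, :, 1] = u[probe_idx]
        trace_buf[m, :, 2:] = syn.g[probe_idx]
        if v_matrix is not None:
            v_matrix[:, m] = v_rec

    take_sample(0, v)

    spike_times: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    epoch_counts = np.zeros(n)
    next_epoch = plasticity.epoch_ms if plasticity.enabled else np.inf
    next_log = 10.0

    for k in range(n_steps):
        t_now = k * dt
        t_end = (k + 1) * dt
        i_syn = synaptic_current(syn, config.synapses, v=v)
        i_total = i_syn + config.run.i_ext
        if sigma.any():
            i_total = i_total + noise_current(config.noise, sigma, t_now, noise_seed)
        # Forward Euler on the Izhikevich equations, then the reset rule.
        # Overflow is tolerated here and caught by the finiteness check below.
        with np.errstate(over="ignore", invalid="ignore"):
            dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
            du = a * (b * v - u)
            v = v + dt * dv
            u = u + dt * du
        spiked = v > SPIKE_CUTOFF_MV
        if not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationError(
                f"non-finite membrane potential in neuron {bad} "
                f"(group {group_of[bad]}) at t = {t_end:.2f} ms"
            )
        v_rec = np.where(spiked, SPIKE_CUTOFF_MV, v)
        if spiked.any():
            ids = np.flatnonzero(spiked)
            spike_ids.append(ids)
            spike_times.append(np.full(ids.size, t_end))
            v[ids] = c[ids]
            u[ids] = u[ids] + d[ids]
            epoch_counts[ids] += 1
        syn = SynapticState(g=syn.g * decay)
        if spiked.any():
            s = spiked.astype(float)
            for col, receptor in enumerate(RECEPTORS):
                w = weights[receptor]
                if w.nnz:
                    syn.g[:, col] += w @ s
        if t_end >= next_epoch - 1e-9:
            # Rate-based Hebbian step: per-edge dW = eta * x_pre * y_post,
            # with x, y the spike counts of the epoch just ended.
            for receptor in RECEPTORS:
                w = weights[receptor]
                if w.nnz:
                    y = np.repeat(epoch_counts, np.diff(w.indptr))
                    x = epoch_counts[w.indices]
                    w.data = hebbian_update(w.data, x, y, plasticity.eta)
            epoch_counts[:] = 0.0
            next_epoch += plasticity.epoch_ms
        if (k + 1) % steps_per_ms == 0:
            take_sample((k + 1) // steps_per_ms, v_rec)
        if t_end >= next_log - 1e-9:
            logger.info("simulated %.0f / %.0f ms", t_end, duration)
            next_log += 10.0

    if spike_ids:
        all_ids = np.concatenate(spike_ids)
        all_t = np.concatenate(spike_times)
    else:
        all_ids = np.array([], dtype=np.int64)
        all_t = np.array([], dtype=float)
    raster = pd.DataFrame(
        {"t_ms": all_t, "neuron_id": all_ids, "group": group_of[all_ids]}
    )
    traces = {
        name: pd.DataFrame(
            {
                "t_ms": sample_times,
                "v_mV": trace_buf[:, j, 0],
                "u": trace_buf[:, j, 1],
                "g_ampa": trace_buf[:, j, 2],
                "g_nmda": trace_buf[:, j, 3],
                "g_gaba": trace_buf[:, j, 4],
            }
        )
        for j, name in enumerate(probe_ids)
    }
    rates = _rates_from_raster(raster, config.group_names, duration)
    return RecordingSet(
        raster=raster,
        traces=traces,
        rates=rates,
        group_names=config.group_names,
        group_slices=offsets,
        sample_times=sample_times,
        v_matrix=v_matrix,
        probe_ids=probe_ids,
    )


def write_recordings(rec: RecordingSet, out_dir) -> list[Path]:
    """Write raster, per-probe trace and rate CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    raster_path = out / "raster.csv"
    rec.raster.to_csv(raster_path, index=False)
    paths.append(raster_path)
    for name, df in rec.traces.items():
        p = out / f"trace_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    rates_path = out / "rates.csv"
    rec.rates.to_csv(rates_path, index=False)
    paths.append(rates_path)
    return paths


def read_recordings(out_dir) -> RecordingSet:
    """Read back the CSVs written by :func:`write_recordings` (lossless for
    raster, traces and rates; the bulk v_matrix is not persisted)."""
    out = Path(out_dir)
    raster = pd.read_csv(out / "raster.csv")
    if raster.empty:
        raster = raster.astype({"t_ms": float, "neuron_id": np.int64, "group": object})
    rates = pd.read_csv(out / "rates.csv")
    traces = {}
    for p in sorted(out.glob("trace_*.csv")):
        traces[p.stem[len("trace_"):]] = pd.read_csv(p)
    group_names = tuple(rates["group"].unique()) if len(rates) else tuple(traces)
    n_bins = rates["t_ms"].nunique() if len(rates) else 0
    sample_times = np.arange(n_bins + 1, dtype=float) if n_bins else np.array([])
    return RecordingSet(
        raster=raster,
        traces=traces,
        rates=rates,
        group_names=group_names,
        group_slices={},
        sample_times=sample_times,
    )
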