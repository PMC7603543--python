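"""Variance-ratio population synchrony and the weight-sweep experiment.

For N membrane-potential traces v_i(t) sampled on the 1 ms grid, the
synchrony of the population is

    chi^2(N) = sigma_V^2 / ( (1/N) sum_i sigma_{V_i}^2 ),

where V(t) = (1/N) sum_i v_i(t) is the population-mean trace and sigma^2
denotes the temporal (population-style) variance, <x^2>_t - <x>_t^2.  By
Cauchy-Schwarz 0 <= chi^2 <= 1: chi^2 = 1 for perfectly synchronized
(identical) traces, and for independent traces chi^2 -> 1/N as the sample
length grows.  Both chi^2 and its square root chi are reported.

The headline experiment sweeps a single global connection weight (default
grid 1, 11, ..., 91) and evaluates chi^2 per neuronal group from each run's
membrane traces, after discarding an initial transient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import engine
from .network import NetworkConfig
from .neuron import SPIKE_CUTOFF_MV

__all__ = [
    "DEFAULT_WEIGHT_GRID",
    "SynchronyResult",
    "population_mean_trace",
    "temporal_variance",
    "chi_squared",
    "weight_sweep",
    "results_to_dataframe",
]

#: The swept connection weights: 1 to 100 in steps of 10.
DEFAULT_WEIGHT_GRID = tuple(range(1, 100, 10))

#: Transient discarded before computing variances (ms of samples), configurable.
DEFAULT_DISCARD_MS = 50.0

# Mean per-trace variance (mV^2) below which traces count as constant:
# fluctuations under a micro-volt are far below any physical signal here.
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class SynchronyResult:
    """chi^2 synchrony of one group at one connection weight.

    ``degenerate`` flags the all-constant-traces case, where the measure's
    denominator vanishes.  There chi^2 is defined as 0 (a quiescent
    population shows no synchrony) unless every trace is pinned at the spike
    clamp level — a population firing in lockstep at the recording ceiling —
    in which case the measure's limiting value is 1 and ``saturated`` is set
    (see :func:`chi_squared`).
    """

    group: str
    weight: float
    chi_squared: float
    degenerate: bool = False
    saturated: bool = False

    @property
    def chi(self) -> float:
        return float(np.sqrt(self.chi_squared))


def _as_trace_matrix(traces) -> np.ndarray:
    m = np.asarray(traces, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError(f"trace matrix must be non-empty 2-D (N x T), got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("trace matrix contains non-finite entries")
    return m


def population_mean_trace(traces) -> np.ndarray:
    """V(t) = (1/N) sum_i v_i(t): the mean over neurons at each sample."""
    return _as_trace_matrix(traces).mean(axis=0)


def temporal_variance(series) -> float:
    """<x^2>_t - <x>_t^2 over the samples of one series (>= 2 samples)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"need a 1-D series of >= 2 samples, got shape {x.shape}")
    return float(np.mean(x * x) - np.mean(x) ** 2)


def chi_squared(
    traces,
    group: str = "",
    weight: float = float("nan"),
    clamp_mv: float | None = None,
) -> SynchronyResult:
    """The variance-ratio synchrony of an N x T trace matrix (N >= 2).

    Returns chi^2 = var_t(mean trace) / mean_i(var_t(trace_i)).  If every
    trace is constant the denominator vanishes and the ratio is undefined;
    the result is then chi^2 = 0 with the degenerate flag set, so sweeps
    over quiescent circuits complete.

    ``clamp_mv`` gives the recorder's spike-clamp level (30 mV in this
    package) as context for that degenerate case: traces constant *at the
    clamp* mean every neuron spiked in every sampling interval — a
    population in perfect lockstep at the recording ceiling, for which the
    measure's limiting value under finer sampling is 1, not 0.  Such groups
    report chi^2 = 1 with both the degenerate and saturated flags set.
    Without ``clamp_mv`` the bare quiescent convention (0) applies.
    """
    m = _as_trace_matrix(traces)
    if m.shape[0] < 2:
        raise ValueError("synchrony needs at least 2 neurons")
    if m.shape[1] < 2:
        raise ValueError("synchrony needs at least 2 time samples")
    saturated = clamp_mv is not None and bool(np.all(m == clamp_mv))
    # chi^2 is invariant under a global additive shift; centring on the grand
    # mean removes the cancellation the <x^2> - <x>^2 form suffers for
    # membrane potentials sitting far from zero.
    m = m - m.mean()
    per_neuron_var = (m * m).mean(axis=1) - m.mean(axis=1) ** 2
    denominator = float(per_neuron_var.mean())
    if denominator <= _DEGENERATE_TOL:
        if saturated:
            return SynchronyResult(
                group=group, weight=weight, chi_squared=1.0,
                degenerate=True, saturated=True,
            )
        return SynchronyResult(group=group, weight=weight, chi_squared=0.0, degenerate=True)
    if np.all(m == m[0]):
        # identical non-constant traces: total synchronization, exactly 1
        return SynchronyResult(group=group, weight=weight, chi_squared=1.0)
    mean_trace = m.mean(axis=0)
    numerator = float((mean_trace * mean_trace).mean() - mean_trace.mean() ** 2)
    value = numerator / denominator
    # Guard against round-off nudging the ratio just past the analytic bounds.
    value = min(max(value, 0.0), 1.0)
    return SynchronyResult(group=group, weight=weight, chi_squared=value)


def weight_sweep(
    config: NetworkConfig,
    weights=DEFAULT_WEIGHT_GRID,
    groups=None,
    seed: int = 0,
    discard_ms: float = DEFAULT_DISCARD_MS,
) -> list[SynchronyResult]:
    """Run the circuit once per weight and measure chi^2 per group.

    Every connection's weight is overridden by the swept value (the
    experiment uses one global weight).  Each weight runs with its own seed,
    the base seed plus the weight index, so runs are independent yet the
    whole sweep is reproducible.  The first ``discard_ms`` of samples are
    dropped before computing variances.
    """
    weights = list(weights)
    if not weights:
        raise ValueError("weights must be non-empty")
    if groups is None:
        groups = list(config.group_names)
    unknown = [g for g in groups if g not in config.group_names]
    if unknown:
        raise KeyError(f"unknown groups: {unknown}")
    results: list[SynchronyResult] = []
    for idx, w in enumerate(weights):
        cfg = replace(
            config,
            connections=tuple(replace(c, weight=float(w)) for c in config.connections),
        )
        rec = engine.run(cfg, seed=(seed + idx) & 0x7FFFFFFF, record_v_matrix=True)
        keep = rec.sample_times >= discard_ms
        for name in groups:
            m = rec.group_trace_matrix(name)[:, keep]
            r = chi_squared(m, group=name, weight=float(w), clamp_mv=SPIKE_CUTOFF_MV)
            results.append(r)
    return results


def results_to_dataframe(results) -> pd.DataFrame:
    """Tabulate sweep results: group, weight_mV, chi_squared, chi, degenerate_flag."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "weight_mV": [r.weight for r in results],
            "chi_squared": [r.chi_squared for r in results],
            "chi": [r.chi for r in results],
            "degenerate_flag": [r.degenerate for r in results],
            "saturated_flag": [r.saturated for r in results],
        }
    )
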