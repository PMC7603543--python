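"""Thalamic drive as stochastic current injection.

The thalamus (regular-spiking and bursting excitatory relay groups plus
GABAergic reticular cells) is not simulated explicitly; its effect on the
cortex is introduced as a noise input targeted at layers L2/3, L4 and L6.
Each targeted neuron receives an i.i.d. zero-mean Gaussian current, redrawn
every time step, with standard deviation sigma_exc (excitatory targets) or
sigma_inh (inhibitory targets); neurons outside the targeted layers receive
exactly zero.

The stream is counter-based (Philox keyed on the seed and the step index),
so the current of neuron i at time t depends only on (seed, t, i) — it is
reproducible regardless of what else is recorded or simulated.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkConfig, NoiseSpec

__all__ = ["NoiseSpec", "layer_is_targeted", "noise_sigma_per_neuron", "noise_current"]

# Tables mix single-layer (L2, L3) and merged (L2/3, L5/6) labels; group a
# layer label with every noise target label it overlaps anatomically.
_LAYER_ALIASES = {
    "L1": {"L1"},
    "L2": {"L2", "L2/3"},
    "L3": {"L3", "L2/3"},
    "L2/3": {"L2", "L3", "L2/3"},
    "L4": {"L4"},
    "L5": {"L5", "L5/6"},
    "L5/6": {"L5", "L6", "L5/6"},
    "L6": {"L6", "L5/6"},
}


def layer_is_targeted(layer: str, target_layers) -> bool:
    """Whether a group in ``layer`` receives drive aimed at ``target_layers``,
    honouring the overlap between merged (L2/3, L5/6) and single labels."""
    aliases = _LAYER_ALIASES.get(layer, {layer})
    for target in target_layers:
        if target in aliases or layer in _LAYER_ALIASES.get(target, {target}):
            return True
    return False


def noise_sigma_per_neuron(config: NetworkConfig) -> np.ndarray:
    """Per-neuron noise standard deviation: sigma_exc/sigma_inh inside the
    targeted layers, 0 elsewhere."""
    spec = config.noise
    sigma = np.zeros(config.n_neurons)
    for group, (start, stop) in zip(config.groups, config.group_offsets().values()):
        if layer_is_targeted(group.layer, spec.target_layers):
            sigma[start:stop] = (
                spec.sigma_exc if group.polarity == "excitatory" else spec.sigma_inh
            )
    return sigma


def _step_rng(seed: int, t_ms: float) -> np.random.Generator:
    # Key on (seed, time in units of 2^-16 ms) so the stream is a pure
    # function of seed and time, independent of call history.
    t_key = int(round(t_ms * 65536)) & 0xFFFFFFFFFFFFFFFF
    return np.random.Generator(np.random.Philox(key=np.array([seed, t_key], dtype=np.uint64)))


def noise_current(
    spec: NoiseSpec,
    sigma: np.ndarray,
    t_ms: float,
    seed: int,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Noise current for one time step.

    ``sigma`` is the precomputed per-neuron standard deviation (see
    :func:`noise_sigma_per_neuron`).  Returns a current per neuron (or per
    requested index); zeros wherever sigma is zero.  Deterministic given
    (seed, t_ms, neuron index).
    """
    rng = _step_rng(seed, t_ms)
    draws = rng.standard_normal(sigma.shape[0]) * sigma
    if indices is not None:
        return draws[np.asarray(indices, dtype=np.int64)]
    return draws
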