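"""Configuration files, the miniature test fixture, and run manifests.

A circuit is described by a YAML document with six blocks — ``groups``,
``connections``, ``noise``, ``run``, ``synapses``, ``plasticity`` — mirroring
:class:`~izhcortex.network.NetworkConfig`.  Unknown keys anywhere in the
document are rejected, and the loaded config must pass structural
validation.  The packaged ``data/default_cortex.yaml`` reproduces the full
17-group cortical circuit.

Every CLI run writes a ``manifest.json`` next to its outputs with the config
hash (stable under key reordering), seed, package version, timestamp and
output file list — enough to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .network import (
    ConnectionSpec,
    GroupSpec,
    NetworkConfig,
    NoiseSpec,
    PlasticitySpec,
    RunSpec,
    SynapseSpec,
    validate,
)
from .neuron import SpikingType

__all__ = [
    "ConfigError",
    "load_config",
    "loads_config",
    "save_config",
    "config_to_dict",
    "config_hash",
    "packaged_default_path",
    "make_fixture",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


_GROUP_KEYS = {"name", "cell_class", "layer", "count", "spiking_type", "receptor"}
_CONN_KEYS = {"source", "target", "sparseness", "weight"}
_TOP_KEYS = {"groups", "connections", "noise", "run", "synapses", "plasticity"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def _build_block(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(data, fields, where)
    try:
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()})
    except TypeError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def loads_config(text: str) -> NetworkConfig:
    """Parse and validate a YAML configuration document."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"YAML parse error: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping at top level")
    _check_keys(data, _TOP_KEYS, "top level")
    for required in ("groups", "connections"):
        if required not in data:
            raise ConfigError(f"top level: missing required block {required!r}")
    groups = []
    for i, g in enumerate(data["groups"]):
        where = f"groups[{i}]"
        if not isinstance(g, dict):
            raise ConfigError(f"{where}: must be a mapping")
        _check_keys(g, _GROUP_KEYS, where)
        missing = _GROUP_KEYS - set(g)
        if missing:
            raise ConfigError(f"{where}: missing keys {sorted(missing)}")
        try:
            spiking = SpikingType(g["spiking_type"])
        except ValueError as exc:
            raise ConfigError(f"{where}: unknown spiking_type {g['spiking_type']!r}") from exc
        groups.append(
            GroupSpec(
                name=str(g["name"]),
                cell_class=g["cell_class"],
                layer=g["layer"],
                count=int(g["count"]),
                spiking_type=spiking,
                receptor=g["receptor"],
            )
        )
    connections = []
    for i, c in enumerate(data["connections"]):
        where = f"connections[{i}]"
        if not isinstance(c, dict):
            raise ConfigError(f"{where}: must be a mapping")
        _check_keys(c, _CONN_KEYS, where)
        if "source" not in c or "target" not in c:
            raise ConfigError(f"{where}: source and target are required")
        connections.append(
            ConnectionSpec(
                source=str(c["source"]),
                target=str(c["target"]),
                sparseness=float(c.get("sparseness", 0.1)),
                weight=float(c.get("weight", 10.0)),
            )
        )
    config = NetworkConfig(
        groups=tuple(groups),
        connections=tuple(connections),
        noise=_build_block(NoiseSpec, data.get("noise", {}) or {}, "noise"),
        run=_build_block(RunSpec, data.get("run", {}) or {}, "run"),
        synapses=_build_block(SynapseSpec, data.get("synapses", {}) or {}, "synapses"),
        plasticity=_build_block(PlasticitySpec, data.get("plasticity", {}) or {}, "plasticity"),
    )
    problems = validate(config)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return config


def load_config(path) -> NetworkConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    try:
        return loads_config(text)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_to_dict(config: NetworkConfig) -> dict:
    """Plain-dict form of a config (the YAML document structure)."""
    return {
        "groups": [
            {
                "name": g.name,
                "cell_class": g.cell_class,
                "layer": g.layer,
                "count": g.count,
                "spiking_type": g.spiking_type.value,
                "receptor": g.receptor,
            }
            for g in config.groups
        ],
        "connections": [
            {
                "source": c.source,
                "target": c.target,
                "sparseness": c.sparseness,
                "weight": c.weight,
            }
            for c in config.connections
        ],
        "noise": {
            "target_layers": list(config.noise.target_layers),
            "sigma_exc": config.noise.sigma_exc,
            "sigma_inh": config.noise.sigma_inh,
        },
        "run": {
            "duration_ms": config.run.duration_ms,
            "dt_ms": config.run.dt_ms,
            "seed": config.run.seed,
            "i_ext": config.run.i_ext,
        },
        "synapses": {
            "tau_ampa_ms": config.synapses.tau_ampa_ms,
            "tau_nmda_ms": config.synapses.tau_nmda_ms,
            "tau_gaba_ms": config.synapses.tau_gaba_ms,
            "coupling": config.synapses.coupling,
        },
        "plasticity": {
            "enabled": config.plasticity.enabled,
            "eta": config.plasticity.eta,
            "epoch_ms": config.plasticity.epoch_ms,
        },
    }


def save_config(config: NetworkConfig, path) -> None:
    """Write a config as YAML (round-trips through load_config)."""
    doc = config_to_dict(config)
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None, width=120)
    Path(path).write_text(text)


def config_hash(config: NetworkConfig) -> str:
    """SHA-256 of the canonical JSON form; stable under YAML key reordering."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def packaged_default_path() -> Path:
    """Path of the packaged default cortex configuration file."""
    return Path(resources.files("izhcortex") / "data" / "default_cortex.yaml")


def make_fixture(n_groups: int, neurons_per_group: int, seed: int = 0) -> NetworkConfig:
    """A miniature circuit for fast tests: ``n_groups`` groups of
    ``neurons_per_group`` neurons, alternating an excitatory RS pyramidal
    L2/3 phenotype and an inhibitory FS basket L4 phenotype, fully pairwise
    connected at sparseness 0.1, weight 10."""
    if n_groups < 2 or neurons_per_group < 2:
        raise ValueError("need n_groups >= 2 and neurons_per_group >= 2")
    groups = []
    for i in range(n_groups):
        if i % 2 == 0:
            groups.append(
                GroupSpec(f"RS_fix{i}", "pyramidal", "L2/3", neurons_per_group,
                          SpikingType.RS, "AMPA")
            )
        else:
            groups.append(
                GroupSpec(f"FS_fix{i}", "GABA_b", "L4", neurons_per_group,
                          SpikingType.FS, "GABA")
            )
    connections = tuple(
        ConnectionSpec(a.name, b.name, sparseness=0.1, weight=10.0)
        for a in groups
        for b in groups
    )
    return NetworkConfig(
        groups=tuple(groups), connections=connections, run=RunSpec(seed=seed)
    )


def write_manifest(out_dir, config: NetworkConfig, seed: int, outputs) -> Path:
    """Write manifest.json describing a run (hash, seed, version, outputs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
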