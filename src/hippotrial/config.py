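"""Plain-text (TOML) run configuration and the run manifest.

Sections map one-to-one onto the module configuration dataclasses:

    [network]    -> NetworkConfig
    [receptors]  -> NMDAGatingParams
    [pathology]  -> severity / pruning seed
    [stimulus]   -> DriveConfig
    [engine]     -> SimulationConfig
    [trial]      -> TrialDesign
    [stats]      -> (reserved; no tunables yet)

Unknown sections or keys are rejected with the offending names, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field

from .engine import SimulationConfig
from .network import NetworkConfig
from .receptors import NMDAGatingParams
from .stimulus import DriveConfig
from .trial import TrialDesign

_SECTION_TYPES = {
    "network": NetworkConfig,
    "receptors": NMDAGatingParams,
    "stimulus": DriveConfig,
    "engine": SimulationConfig,
    "trial": TrialDesign,
}
_PATHOLOGY_KEYS = {"severity", "seed"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    receptors: NMDAGatingParams = field(default_factory=NMDAGatingParams)
    pathology: dict = field(default_factory=lambda: {"severity": "control",
                                                     "seed": 0})
    stimulus: DriveConfig = field(default_factory=DriveConfig)
    engine: SimulationConfig = field(default_factory=SimulationConfig)
    trial: TrialDesign = field(default_factory=TrialDesign)

    def to_dict(self) -> dict:
        out = {}
        for name in _SECTION_TYPES:
            value = getattr(self, name)
            d = dataclasses.asdict(value)
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in d.items()}
        out["pathology"] = dict(self.pathology)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_section(cls, section: str, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {unknown}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and fully resolve a TOML run configuration.

    Missing sections and keys take their documented defaults; unknown
    sections or keys raise a ConfigError naming them.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(_SECTION_TYPES) | {"pathology", "stats"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config sections: {unknown}")

    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        kwargs[section] = _build_section(cls, section, raw.get(section, {}))
    path_data = raw.get("pathology", {})
    unknown = sorted(set(path_data) - _PATHOLOGY_KEYS)
    if unknown:
        raise ConfigError(f"unknown keys in [pathology]: {unknown}")
    pathology = {"severity": path_data.get("severity", "control"),
                 "seed": path_data.get("seed", 0)}
    if pathology["severity"] not in ("control", "moderate", "severe"):
        raise ConfigError(f"invalid severity {pathology['severity']!r}")
    return RunConfig(pathology=pathology, **kwargs)


def dump_config(cfg: RunConfig) -> str:
    """Normalized TOML text for a resolved configuration."""
    lines = []
    for section, data in cfg.to_dict().items():
        lines.append(f"[{section}]")
        for k, v in data.items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            elif isinstance(v, list):
                lines.append(f"{k} = {json.dumps(v)}")
            else:
                lines.append(f"{k} = {v}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit-for-bit."""

    config_hash: str
    master_seed: int
    component_seeds: dict
    version: str
    file_index: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
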