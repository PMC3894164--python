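"""Structured configuration, seed derivation and run manifests.

Configuration is a YAML document with three optional sections --
``forcefield``, ``integrator`` and ``protocol`` -- whose defaults are the
published parameterization.  Unknown keys are rejected.  A run manifest
snapshots everything needed to reproduce an output byte-for-byte: the
resolved configuration, package version, seeds and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone

import yaml

from .dynamics import IntegratorConfig
from .forcefield import GoForceField
from .protocols import EnsembleSettings


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclasses.dataclass
class ProtocolConfig:
    """Campaign-level settings (desk-scale defaults; see the methods note)."""

    n_trials: int = 100
    timeout_ns: float = 5000.0  # per-trial cap; trials past it are logged as timeouts
    ensemble: EnsembleSettings = dataclasses.field(default_factory=EnsembleSettings)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigError("n_trials must be at least 1")
        if self.timeout_ns <= 0:
            raise ConfigError("timeout_ns must be positive")


@dataclasses.dataclass
class SimulationConfig:
    forcefield: GoForceField = dataclasses.field(default_factory=GoForceField)
    integrator: IntegratorConfig = dataclasses.field(default_factory=IntegratorConfig)
    protocol: ProtocolConfig = dataclasses.field(default_factory=ProtocolConfig)

    def to_dict(self) -> dict:
        return {
            "forcefield": dataclasses.asdict(self.forcefield),
            "integrator": dataclasses.asdict(self.integrator),
            "protocol": dataclasses.asdict(self.protocol),
        }


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path=None, text: str | None = None) -> SimulationConfig:
    """Load and validate a YAML configuration; empty input yields defaults."""
    if text is None:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(data) - {"forcefield", "integrator", "protocol"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    ff = _build_section(GoForceField, data.get("forcefield", {}) or {}, "forcefield")
    integ = _build_section(IntegratorConfig, data.get("integrator", {}) or {}, "integrator")
    proto_data = dict(data.get("protocol", {}) or {})
    ens = proto_data.pop("ensemble", None)
    proto = _build_section(ProtocolConfig, proto_data, "protocol")
    if ens:
        proto.ensemble = _build_section(EnsembleSettings, ens, "protocol.ensemble")
    return SimulationConfig(ff, integ, proto)


def derive_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed: the stage name is hashed into a stream offset.

    One global seed reproduces a whole campaign while keeping stages
    statistically independent.  Result is kept below 2**31.
    """
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Immutable record tying campaign outputs to their provenance."""

    command: str
    config: dict
    seed: int
    inputs: dict  # path -> sha256
    outputs: tuple
    started: str
    finished: str
    code_version: str = ""
    status: str = "ok"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        data = json.loads(text)
        data["outputs"] = tuple(data["outputs"])
        return cls(**data)


def make_manifest(command, config: SimulationConfig, seed, inputs, outputs, started, status="ok"):
    from . import __version__

    return RunManifest(
        command=command,
        config=config.to_dict(),
        seed=int(seed),
        inputs={str(p): file_hash(p) for p in inputs},
        outputs=tuple(str(o) for o in outputs),
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        code_version=__version__,
    )
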