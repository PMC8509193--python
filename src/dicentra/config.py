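"""Run configuration: simulation parameters, YAML loading, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

ASSIGNMENT_MODES = ("content_weighted", "voronoi_territories")


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, rejoining-kernel and scoring parameters for one MC setup."""

    radius_um: float = 3.0
    r0_um: float = 0.8
    c_free: float = 0.1
    assignment_mode: str = "content_weighted"
    visibility_mbp: float = 3.0
    dose_ceiling_gy: float = 3.0
    photon_alpha: float = 0.020  # Gy^-1, Cs-137 reference
    photon_beta: float = 0.047  # Gy^-2, Cs-137 reference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError(f"radius_um must be positive, got {self.radius_um}")
        if self.r0_um <= 0:
            raise ValueError(f"r0_um must be positive, got {self.r0_um}")
        if self.c_free < 0:
            raise ValueError(f"c_free must be non-negative, got {self.c_free}")
        if self.assignment_mode not in ASSIGNMENT_MODES:
            raise ValueError(
                f"assignment_mode must be one of {ASSIGNMENT_MODES}, "
                f"got {self.assignment_mode!r}"
            )
        if self.visibility_mbp < 0:
            raise ValueError("visibility_mbp must be non-negative")
        if self.dose_ceiling_gy <= 0:
            raise ValueError("dose_ceiling_gy must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the configuration for provenance headers."""
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def provenance_lines(config: SimulationConfig, seed: int | None = None, **extra) -> list[str]:
    """'#'-prefixed metadata lines recording seed and parameters."""
    items = config.as_dict()
    if seed is not None:
        items["seed"] = seed
    items["config_hash"] = config.config_hash()
    items.update(extra)
    return [f"# {key} = {value}" for key, value in items.items()]
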