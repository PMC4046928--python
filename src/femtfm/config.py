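"""Run configuration: validated YAML with a stable content hash.

Every output artifact embeds the configuration hash so results can be
traced back to the exact parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .mesh_fem import SubstrateModel

__all__ = ["RunConfig"]

_KNOWN = {
    "substrate": {"E_kPa", "nu", "thickness_um"},
    "grid": {"spacing_um", "margin_um", "z_aspect"},
    "solver": {"tolerance", "max_iter", "direct_limit"},
    "method": {"name", "rms_tol", "smooth_sigma"},
}


@dataclass
class RunConfig:
    """Substrate, grid, solver and method parameters for one run."""

    E_kPa: float = 1.0
    nu: float = 0.45
    thickness_um: float = 70.0
    spacing_um: float = 4.84
    margin_um: float | None = None
    z_aspect: float = 2.0
    tolerance: float = 1e-8
    max_iter: int = 50
    direct_limit: int = 200_000
    method: str = "mixed"
    rms_tol: float = 0.05
    smooth_sigma: float | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("mixed", "iterative"):
            raise ConfigurationError(
                f"method must be 'mixed' or 'iterative', got {self.method!r}"
            )
        # fail early on invalid material/geometry
        SubstrateModel(self.E_kPa, self.nu, self.thickness_um, 1.0, 1.0)
        if self.tolerance <= 0 or self.rms_tol <= 0:
            raise ConfigurationError("tolerances must be > 0")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a YAML mapping")
        kwargs = {}
        for block, keys in _KNOWN.items():
            sub = raw.pop(block, {}) or {}
            if not isinstance(sub, dict):
                raise ConfigurationError(f"config block {block!r} must be a mapping")
            unknown = set(sub) - keys
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in config block {block!r}: {sorted(unknown)}"
                )
            for k, v in sub.items():
                kwargs["method" if k == "name" else k] = v
        if "seed" in raw:
            kwargs["seed"] = raw.pop("seed")
        if raw:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(raw)}")
        return cls(**kwargs)

    def substrate(self, lateral_size_x: float, lateral_size_y: float) -> SubstrateModel:
        return SubstrateModel(
            youngs_modulus=self.E_kPa,
            poissons_ratio=self.nu,
            thickness=self.thickness_um,
            lateral_size_x=lateral_size_x,
            lateral_size_y=lateral_size_y,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
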