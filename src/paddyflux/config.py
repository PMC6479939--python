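"""Run configuration: one structured key-value file with CLI overrides.

Precedence is CLI flag > config file > defaults.  The configuration is
hashable (sha256 over its canonical JSON form) so a run log can record
enough to reproduce any report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .isotopes import PDB_RATIO
from .mic import NetworkConfig


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Input paths may be omitted, in which case the pipeline simulates a
    pot experiment with the given seed.  Chamber geometry defaults to
    the 0.49 m² / 490 L incubation chamber; carbon-pool defaults are the
    pot experiment's fertilizer dose (10.24 g at 23.05% C) and topsoil
    carbon (359.67 g).  p_photo_percent, when set, overrides the
    photosynthesis share estimated from the measurements.
    """

    measurements: Optional[str] = None
    gas: Optional[str] = None
    abundance: Optional[str] = None
    environment: Optional[str] = None
    outdir: str = "paddyflux_out"
    round_digits: int = 2
    pdb_ratio: float = PDB_RATIO
    chamber_area_m2: float = 0.49
    chamber_volume_m3: float = 0.49
    fertilizer_mass_g: float = 10.24
    fertilizer_c_fraction: float = 0.2305
    soil_c_g: float = 359.67
    p_photo_percent: Optional[float] = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.round_digits < 0:
            raise ValueError("round_digits must be >= 0")
        if self.chamber_area_m2 <= 0 or self.chamber_volume_m3 <= 0:
            raise ValueError("chamber geometry must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        net = d.pop("network", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if net is not None:
            cfg.network = NetworkConfig(**net)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
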