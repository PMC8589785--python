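"""Run configuration: one flat record of every tunable constant, with strict
key checking and a content hash that is stamped into every output artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    fa_threshold: float = 0.2
    midline_tolerance_mm: float = 2.0
    midline_search_mm: float = 10.0
    annulus_mm: tuple[float, float] = (5.0, 30.0)
    pivot_step_mm: float = 1.0
    min_limb_voxels: int = 10
    strip_halfwidth_mm: float = 4.0
    completeness: float = 0.9
    pc_tolerance_mm: float = 2.0
    correlation: float = 0.0
    stepwise_criterion: str = "aic"
    equal_var: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON (or simple YAML 'key: value' lines); unknown keys
        are rejected."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition(":")
                data[key.strip()] = json.loads(val.strip())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "annulus_mm" in data:
            data = {**data, "annulus_mm": tuple(data["annulus_mm"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annulus_mm"] = list(d["annulus_mm"])
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stamp(self) -> dict:
        """Provenance block embedded in every artifact."""
        return {"seed": self.seed, "config_hash": self.hash, "config": self.to_dict()}
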