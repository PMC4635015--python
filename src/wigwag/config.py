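"""Run configuration: YAML parsing, validation, and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import yaml

from .arena import FieldGeometry, make_field, named_field
from .simulator import WigwagParams
from .synthetic_data import preset_params


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulation/analysis run.

    ``arena`` is a named field ("rect30x60", "circle90", ...) or a
    mapping with ``kind`` and mm dimensions.  Behavioral parameters
    come from a group ``preset`` optionally overridden by ``params``.
    """

    arena: str | dict
    preset: Optional[str] = None
    params: dict = dc_field(default_factory=dict)
    duration_s: float = 600.0
    n_reps: int = 1
    seed: int = 0
    wall_margin_mm: float = 5.0
    out_dir: str = "wigwag_out"
    analyses: tuple = ("preference",)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.field()  # validate arena spec eagerly
        self.wigwag_params()

    def field(self) -> FieldGeometry:
        if isinstance(self.arena, str):
            return named_field(self.arena)
        spec = dict(self.arena)
        kind = spec.pop("kind")
        return make_field(kind, **spec)

    def wigwag_params(self) -> WigwagParams:
        base = preset_params(self.preset).params if self.preset else WigwagParams()
        return dataclasses.replace(base, **self.params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(d["analyses"])
        return d

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)
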