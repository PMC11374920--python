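"""Run configuration: a flat, YAML-round-trippable record of every knob."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML.

    ``stages`` toggles individual pipeline stages in :func:`oxtrace.pipeline.run_all`.
    Unknown keys in a config file are rejected rather than ignored, so typos
    surface immediately.
    """

    seed: int = 0
    out_dir: str = "oxtrace_out"
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "sdi": True,
            "dcv_cutoff": True,
            "dcv_incidence": True,
            "concordance": True,
            "puncta": True,
        }
    )
    # scoring
    pooling: str = "mean"
    min_obs: int = 2
    # vesicles
    bandwidth: str | float = "silverman"
    ci_level: float = 0.95
    # concordance
    orientation: str = "sdi_on_receptor"
    # puncta
    min_puncta: int = 1
    # logging
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.pooling not in {"mean", "median"}:
            raise ValueError(f"unknown pooling rule {cfg.pooling!r}")
        if cfg.orientation not in {"sdi_on_receptor", "receptor_on_sdi"}:
            raise ValueError(f"unknown orientation {cfg.orientation!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
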