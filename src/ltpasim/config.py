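"""Scenario configuration: YAML loading, validation, hashing.

A scenario file is a flat YAML mapping.  Keys are the ``ModelParams``
field names; the six parameters reported by the sensitivity analyses
may equivalently be given under their report labels (``alpha.behavior``,
``perception.radius``, ``alpha.network``, ``alpha.comm``,
``prop.ltpa.sites``, ``mean.ql``).  Run metadata (``label``,
``n_reps``, ``out_dir``) sits alongside the parameters.  Unknown keys
are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .world import ModelParams, PARAM_LABELS

__all__ = ["ScenarioConfig", "load_config", "save_config", "params_hash"]

_META_KEYS = {"label", "n_reps", "out_dir"}


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated scenario: model parameters plus run metadata."""

    params: ModelParams = ModelParams()
    label: str = "scenario"
    n_reps: int = 80
    out_dir: str = "results"

    def validate(self) -> None:
        self.params.validate()
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.label:
            raise ValueError("label must be non-empty")

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(label=self.label, n_reps=self.n_reps, out_dir=self.out_dir)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        raw = dict(raw or {})
        # report labels are aliases for the corresponding fields
        for label, fname in PARAM_LABELS.items():
            if label in raw:
                if fname in raw:
                    raise ValueError(
                        f"both {label!r} and {fname!r} given; use one"
                    )
                raw[fname] = raw.pop(label)
        meta = {k: raw.pop(k) for k in list(raw) if k in _META_KEYS}
        params = ModelParams.from_dict(raw)  # rejects unknown keys
        cfg = cls(params=params, **meta)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario YAML file; empty file means all defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return ScenarioConfig.from_dict(raw)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario back to YAML (round-trips losslessly)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def params_hash(params: ModelParams) -> str:
    """Stable sha256 of the canonical JSON form of the parameters."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
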