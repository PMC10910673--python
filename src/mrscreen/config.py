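"""YAML run configuration: thresholds, estimator defaults, priors, column maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coloc import DEFAULT_PRIORS
from .exceptions import ConfigurationError
from .instruments import ClumpConfig


@dataclass
class RunConfig:
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    stringent: ClumpConfig = field(default_factory=lambda: ClumpConfig(
        p_threshold=5e-8, r2_threshold=0.001, window_kb=1000.0))
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 5000
    seed: int = 1
    coloc_priors: tuple = DEFAULT_PRIORS
    pp4_threshold: float = 0.5
    bonferroni_m: dict = field(default_factory=dict)  # outcome_id -> m
    alpha: float = 0.05
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        kwargs = {}
        for key in ("clump", "stringent"):
            if key in raw:
                kwargs[key] = ClumpConfig(**raw.pop(key))
        if "coloc_priors" in raw:
            kwargs["coloc_priors"] = tuple(raw.pop("coloc_priors"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown key(s) {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)
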