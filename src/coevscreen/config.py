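"""Pipeline configuration: typed, range-checked, loadable from YAML or a
``key = value`` settings file.  Unknown keys are rejected so that typos in a
config file cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from coevscreen.caps_engine import EngineConfig

__all__ = ["PipelineConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """One or more invalid configuration entries; message lists all."""


@dataclass
class PipelineConfig:
    """All pipeline settings with the screen's standard defaults:
    minimum identity 35%, maximum gaps 25%, divergence cut-off 0.95,
    minimum shared species 20, alpha 0.01, bootstrap threshold 0.6,
    final filters p < 0.005 / good blocks / gaps < 20%.
    """

    # engine
    alpha: float = 0.01
    bootstrap_threshold: float = 0.6
    bootstrap_reps: int = 100
    null_samples: int = 10_000
    min_pair_fraction: float = 0.5
    tail: str = "positive"
    t_min: float = 1e-6
    matrix: str = "BLOSUM62"
    reference_species: str | None = None
    min_usable_columns: int = 10
    # curation
    min_identity: float = 35.0
    max_gaps: float = 25.0
    divergence_cutoff: float = 0.95
    # quality
    min_block: int = 10
    max_nonconserved_stretch: int = 8
    # pairing
    min_shared: int = 20
    use_external_tree: bool = False
    # final filters
    p_max: float = 0.005
    gap_max: float = 0.20
    require_good: bool = True
    per_pair_fdr: bool = False
    # execution
    workers: int = 1
    work_dir: str = "work"
    seed: int = 1

    def validate(self) -> None:
        errors = []
        try:
            self.engine().validate()
        except ValueError as exc:
            errors.extend(str(exc).split("; "))
        if not 0.0 <= self.min_identity <= 100.0:
            errors.append(f"min_identity={self.min_identity} outside [0, 100]")
        if not 0.0 <= self.max_gaps <= 100.0:
            errors.append(f"max_gaps={self.max_gaps} outside [0, 100]")
        if not 0.0 <= self.divergence_cutoff <= 1.0:
            errors.append("divergence_cutoff outside [0, 1]")
        if self.min_shared < 3:
            errors.append("min_shared must be >= 3")
        if self.min_block < 1:
            errors.append("min_block must be >= 1")
        if self.max_nonconserved_stretch < 1:
            errors.append("max_nonconserved_stretch must be >= 1")
        if not 0.0 < self.p_max <= 1.0:
            errors.append(f"p_max={self.p_max} outside (0, 1]")
        if not 0.0 <= self.gap_max <= 1.0:
            errors.append(f"gap_max={self.gap_max} outside [0, 1]")
        if self.workers < 1:
            errors.append("workers must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            errors.append("seed must be in [0, 2**31)")
        if errors:
            raise ConfigError("; ".join(errors))

    def engine(self) -> EngineConfig:
        return EngineConfig(
            alpha=self.alpha,
            bootstrap_threshold=self.bootstrap_threshold,
            bootstrap_reps=self.bootstrap_reps,
            null_samples=self.null_samples,
            seed=self.seed,
            min_pair_fraction=self.min_pair_fraction,
            tail=self.tail,
            t_min=self.t_min,
            matrix=self.matrix,
            reference_species=self.reference_species,
            min_usable_columns=self.min_usable_columns,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        coerced = {}
        for key, value in mapping.items():
            coerced[key] = _coerce(value, known[key].type, key)
        cfg = cls(**coerced)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML mapping or a ``key = value`` settings file."""
        text = Path(path).read_text(encoding="utf-8")
        mapping = _parse_config_text(text, path)
        return cls.from_mapping(mapping)


def _parse_config_text(text: str, path) -> dict:
    if not text.strip():
        return {}
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if isinstance(data, dict):
        return data
    # settings.conf dialect: one "key = value" (or key=value) per line,
    # '#' comments allowed
    mapping = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        mapping[key.strip()] = yaml.safe_load(value.strip())
    return mapping


_TRUE = {"true", "yes", "on", "1"}
_FALSE = {"false", "no", "off", "0"}


def _coerce(value, target_type, key: str):
    if value is None:
        return None
    t = str(target_type)
    try:
        if "bool" in t:
            if isinstance(value, bool):
                return value
            s = str(value).strip().lower()
            if s in _TRUE:
                return True
            if s in _FALSE:
                return False
            raise ValueError(f"not a boolean: {value!r}")
        if "int" in t:
            if isinstance(value, bool):
                raise ValueError("boolean where integer expected")
            return int(value)
        if "float" in t:
            return float(value)
        return str(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a config file; raises :class:`ConfigError` listing
    every violation with its key.  An empty file yields all defaults."""
    return PipelineConfig.from_file(path)
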