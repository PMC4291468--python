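"""Flat key-value (YAML) pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import yaml

from .errors import ConfigError
from .model import DEFAULT_CUTOFFS, DEFAULT_P0, DEFAULT_PRIOR_WEIGHTS


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the count/scan/estimate stages in one place."""

    k: int = 15
    min_base_quality: int = 20
    quality_offset: int = 33
    min_count: int = 5
    usc_threshold_pct: float = 100.0
    p0: float = DEFAULT_P0
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS
    prior_weights: Sequence[float] = DEFAULT_PRIOR_WEIGHTS
    diploid_genome_size_bp: int = 1_000_000_000
    seed: int = 0

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["cutoffs"] = list(d["cutoffs"])
        d["prior_weights"] = [float(w) for w in d["prior_weights"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a flat YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return replace(PipelineConfig(), **raw)
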