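"""Pipeline configuration with every analysis default in one place.

Defaults are the CAGEr-style parameter set this analysis follows:
power-law normalization fitted on counts 5..1000 to a referent with slope
1.53 and 10^6 total tags; distance clustering at 20 bp with a 1 TPM
threshold and singleton rescue above 5 TPM; 0.1/0.9 interquantile bounds;
consensus aggregation at 100 bp and 3 TPM; a 3x2 SOM on profiles above
3 TPM; shifting-promoter selection at BH-FDR 0.01 with no score cutoff;
-250/+250, -35/-20 and -35/+5 motif windows and a -31..-24 W-box interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class NormalizationConfig:
    fit_range: tuple[int, int] = (5, 1000)
    alpha: float = 1.53
    total: float = 1e6


@dataclass
class ClusteringConfig:
    threshold: float = 1.0          # TPM; CTSSs below are discarded pre-clustering
    max_dist: int = 20              # bp gap joining consecutive CTSSs
    keep_singletons_above: float = 5.0
    q_low: float = 0.1
    q_up: float = 0.9
    min_mutant_count: int = 1       # "present in mutant" for subtraction


@dataclass
class ConsensusConfig:
    tpm_threshold: float = 3.0
    max_dist: int = 100


@dataclass
class SomConfig:
    tpm_threshold: float = 3.0
    xdim: int = 3
    ydim: int = 2
    seed: int = 0


@dataclass
class ShiftingConfig:
    fdr_threshold: float = 0.01
    score_threshold: float = float("-inf")
    min_tpm: float = 3.0
    use_raw_counts: bool = True     # effective KS sample sizes from raw tags


@dataclass
class MotifConfig:
    density_window: tuple[int, int] = (-250, 250)   # WW dinucleotide map
    tata_window: tuple[int, int] = (-35, -20)       # best PWM match scan
    logo_window: tuple[int, int] = (-35, 5)
    wbox_interval: tuple[int, int] = (-31, -24)
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PipelineConfig:
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    som: SomConfig = field(default_factory=SomConfig)
    shifting: ShiftingConfig = field(default_factory=ShiftingConfig)
    motifs: MotifConfig = field(default_factory=MotifConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        overrides = []
        for section, values in (d or {}).items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            for key, val in (values or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                default = getattr(sub, key)
                if isinstance(default, tuple) and isinstance(val, (list, tuple)):
                    val = tuple(val)
                setattr(sub, key, val)
                overrides.append(f"{section}.{key}={val}")
        cfg._overrides = overrides  # type: ignore[attr-defined]
        return cfg

    @property
    def overrides(self) -> list[str]:
        return getattr(self, "_overrides", [])


def load_config(path: str | None) -> PipelineConfig:
    """Load a YAML config; missing path means all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
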