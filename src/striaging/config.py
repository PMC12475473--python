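"""Pipeline configuration: defaults for every stage, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .qc import QCThresholds


@dataclass
class ClusteringParams:
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution_tier1: float = 0.08
    resolution_tier2: float = 0.10


@dataclass
class DEParams:
    log2fc_min: float = 0.25
    fdr_max: float = 0.05
    ratio_threshold: float = 2.0
    top_n_markers: int = 10
    top_k_aging: int = 20


@dataclass
class BinningParams:
    origin_y: float = 0.0
    bin_height: float = 500.0
    n_bins: int = 6


@dataclass
class ScoreParams:
    n_ctrl: int = 100
    n_bins: int = 24


@dataclass
class PowerParams:
    enabled: bool = False
    size_grid: list[int] = field(default_factory=lambda: [200, 500, 1000, 2000])
    n_reps: int = 20
    match_jaccard: float = 0.5


@dataclass
class PipelineConfig:
    platform: str = "merfish"  # merfish | scrnaseq
    qc: QCThresholds = field(default_factory=QCThresholds)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    de: DEParams = field(default_factory=DEParams)
    binning: BinningParams = field(default_factory=BinningParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    power: PowerParams = field(default_factory=PowerParams)
    dominance_threshold: float = 0.70
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "qc": QCThresholds, "clustering": ClusteringParams, "de": DEParams,
            "binning": BinningParams, "score": ScoreParams, "power": PowerParams,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sections:
                kwargs[key] = sections[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
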