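"""Pipeline configuration: input paths, screen thresholds, clustering
resolutions, resampling counts and the global random seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortSpec
from .types import ScreenThresholds, UbipanError


@dataclass
class PipelineConfig:
    out_dir: str = "ubipan_out"
    seed: int = 0
    n_cohorts: int = 4
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    # clustering
    n_components: int = 10
    jackstraw_perm: int = 50
    jackstraw_frac: float = 0.05
    k_neighbors: int = 15
    resolution_tumor: float = 0.6
    resolution_normal: float = 0.5
    atlas_k_rows: int = 3
    # resampling
    n_boot: int = 1000
    n_perm: int = 500
    # prognosis
    top_n_association: int = 500
    censor_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cohorts < 2:
            raise UbipanError("n_cohorts must be >= 2 for cross-cohort stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        thresholds = ScreenThresholds(**raw.pop("thresholds", {}))
        return cls(cohort=cohort, thresholds=thresholds, **raw)

    def to_dict(self) -> dict:
        return asdict(self)
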