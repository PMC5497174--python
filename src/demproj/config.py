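"""Named configuration constants and YAML/JSON config loading.

Every headline constant of the analysis is surfaced here with its default:
the -1.5 SD domain-impairment cut, the 3.6 IQCODE cut, the 0.973 per-year
incidence odds ratio, 1000 PSA draws, the 2006 model base year, the 2040
projection horizon, the 2015 age-standardisation year and the 2014
CVD-incidence freeze year.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ascertain import AscertainmentConfig
from .cohort import CohortConfig

Z_IMPAIRMENT_CUT = -1.5
IQCODE_CUT = 3.6
TREND_OR_DEFAULT = 0.973
PSA_DRAWS_DEFAULT = 1000
BASE_YEAR = 2006
HORIZON_YEAR = 2040
STANDARD_POPULATION_YEAR = 2015
CVD_FREEZE_YEAR = 2014


@dataclass
class PipelineConfig:
    """Top-level configuration mirroring the package's module structure."""

    seed: int = 1
    cohort: dict = field(default_factory=dict)
    ascertainment: dict = field(default_factory=dict)
    trends: dict = field(default_factory=lambda: {"n_quad": 9, "max_iter": 45,
                                                  "tol": 0.02})
    calibration: dict = field(default_factory=dict)
    projection: dict = field(default_factory=lambda: {
        "horizon_year": HORIZON_YEAR,
        "standard_population_year": STANDARD_POPULATION_YEAR,
        "cvd_freeze_year": CVD_FREEZE_YEAR,
    })
    uncertainty: dict = field(default_factory=lambda: {"n_draws": PSA_DRAWS_DEFAULT})

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(seed=self.seed, **self.cohort)

    def ascertainment_config(self) -> AscertainmentConfig:
        return AscertainmentConfig(**self.ascertainment)


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
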