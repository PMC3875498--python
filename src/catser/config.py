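"""Run configuration: validated tunables for the whole pipeline.

Defaults follow the whole-brain study setting: sample of 20 000 tracts,
3 partitions, k = 15 LOF neighbours, representatives capped at 40 from a
cluster size of 120 on, two-stage outlier elimination (size < 3 after 80 %
of the preclustering, size < 4 after 60 % of the final pass) and 250 target
clusters.  The assignment gammas default to 5: representatives are selected
to be maximally spread, which concentrates their pairwise distances near
the cluster diameter, so the standard deviation used in the assignment test
under-scales the member-to-nearest-representative distance and the factor
must compensate.  Configs load from a single TOML file; unknown keys are
rejected.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .cluster import STRATEGY_PRESETS, OutlierStrategy, RepCountConfig
from .similarity import MEASURES, CDParams


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    measure: str = "cd"
    sample_size: int = 20000
    n_partitions: int = 3
    k: int = 15
    rep: RepCountConfig = RepCountConfig()
    strategy: OutlierStrategy | None = STRATEGY_PRESETS["default"]  # None: no elimination
    lof_neutral: bool = False  # force unit LOFs (diagnostic)
    precluster_reduction: float = 3.0  # per-partition target = ceil(|part| / q)
    target_clusters: int = 250
    gamma_reassign: float = 5.0
    gamma_label: float = 5.0
    seed: int = 0
    n_workers: int = 1
    min_length_mm: float | None = None
    cd_params: CDParams = CDParams()
    # atlas guidance
    atlas_path: str | None = None
    grid_resolution: float = 1.0
    min_membership: float = 0.0
    atlas_post_merge: bool = True
    atlas_neutral: bool = False  # force all weights to 1 (diagnostic)

    @field_validator("measure")
    @classmethod
    def _check_measure(cls, v: str) -> str:
        if v not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        return v

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data):
        if isinstance(data, dict):
            strat = data.get("strategy")
            if isinstance(strat, str):
                if strat == "none":
                    data["strategy"] = None
                elif strat in STRATEGY_PRESETS:
                    data["strategy"] = STRATEGY_PRESETS[strat]
                else:
                    raise ValueError(
                        f"unknown strategy preset {strat!r}; "
                        f"known: {sorted(STRATEGY_PRESETS)} or 'none'")
            elif isinstance(strat, dict):
                data["strategy"] = OutlierStrategy(**strat)
            rep = data.get("rep")
            if isinstance(rep, dict):
                data["rep"] = RepCountConfig(**rep)
            cd = data.get("cd_params")
            if isinstance(cd, dict):
                if "weights" in cd:
                    cd["weights"] = tuple(cd["weights"])
                data["cd_params"] = CDParams(**cd)
        return data

    @model_validator(mode="after")
    def _check_ranges(self):
        if self.sample_size < 1 or self.n_partitions < 1 or self.target_clusters < 1:
            raise ValueError("sample_size, n_partitions, target_clusters must be >= 1")
        if self.gamma_reassign <= 0 or self.gamma_label <= 0:
            raise ValueError("gammas must be positive")
        if self.precluster_reduction < 1:
            raise ValueError("precluster_reduction must be >= 1")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(**data)
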