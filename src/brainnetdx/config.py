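"""Pipeline configuration: one YAML-serialisable object covering every stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .models import RVFLConfig

__all__ = ["PipelineConfig"]

_CLASSIFIERS = ("rvfl", "elm", "svm")


@dataclass
class PipelineConfig:
    """Everything a full cross-validated run needs, in one round-trippable object.

    ``cohort`` configures the simulator (ignored when a cohort is loaded from
    disk); ``q`` is the CBF quantile-descriptor length; ``w_t1`` the T1 fusion
    weight; ``alpha``/``mrmr_k``/``mrmr_bins`` drive feature selection;
    ``k_folds`` x ``n_repeats`` the repeated stratified CV; ``base_seed`` every
    source of randomness.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    q: int = 50
    w_t1: float = 0.5
    alpha: float = 0.05
    mrmr_k: int = 20
    mrmr_bins: int = 3
    classifier: str = "rvfl"
    rvfl: RVFLConfig = field(default_factory=RVFLConfig)
    k_folds: int = 5
    n_repeats: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in _CLASSIFIERS:
            raise ValueError(f"classifier must be one of {_CLASSIFIERS}")
        if not 0.0 <= self.w_t1 <= 1.0:
            raise ValueError("w_t1 must lie in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.mrmr_k < 1 or self.mrmr_bins < 2:
            raise ValueError("mrmr_k must be >= 1 and mrmr_bins >= 2")
        if self.k_folds < 2 or self.n_repeats < 1:
            raise ValueError("k_folds must be >= 2 and n_repeats >= 1")

    # -- YAML round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["affected_regions"] = list(d["cohort"]["affected_regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "rvfl" in d and not isinstance(d["rvfl"], RVFLConfig):
            d["rvfl"] = RVFLConfig(**d["rvfl"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
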