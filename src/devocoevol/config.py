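"""Pipeline configuration: a single validated YAML/JSON document.

Unknown keys are rejected; any referenced file must exist at load time.
CLI flags override config keys.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MilestoneSection(_Strict):
    age_at_0: float
    age_at_10: float

    @model_validator(mode="after")
    def _ordered(self):
        if not self.age_at_10 > self.age_at_0:
            raise ValueError("age_at_10 must exceed age_at_0")
        return self


class SplineSection(_Strict):
    degree: int = 3
    interior_knots: int = 2


class MarkerSection(_Strict):
    lfc_threshold: float = 3.0
    alpha: float = 0.05
    min_mean: float = 0.0


class StagingSection(_Strict):
    stage_labels: list[str] = Field(default_factory=lambda: (
        ["PEK"] + [f"{i}-SEK" for i in range(1, 8)] + ["crest"]))
    substates: int = 5
    rate_classes: list[int] | None = None
    start_time: float = 0.0
    n_embryos: int = 400
    window: tuple[float, float] = (0.0, 10.0)


class SyntheticSection(_Strict):
    n_genes_per_class: int = 100
    n_timepoints: int = 8
    effect_size: float = 1.0
    dispersion: float = 0.05
    n_markers: int = 100
    mixture_proportions: list[float] = Field(default_factory=lambda: [0.7, 0.3])
    mixture_noise_cv: float = 0.2
    chronology_n: int = 500
    chronology_sigma: float = 0.1


class InputSection(_Strict):
    counts_a: str | None = None
    counts_b: str | None = None
    metadata: str | None = None
    orthology: str | None = None
    staging_observations: str | None = None
    checksums: dict[str, str] = Field(default_factory=dict)


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    milestones: dict[str, MilestoneSection] = Field(default_factory=dict)
    spline: SplineSection = Field(default_factory=SplineSection)
    markers: MarkerSection = Field(default_factory=MarkerSection)
    staging: StagingSection = Field(default_factory=StagingSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    inputs: InputSection = Field(default_factory=InputSection)

    @field_validator("inputs")
    @classmethod
    def _files_exist(cls, v: InputSection):
        for name in ("counts_a", "counts_b", "metadata", "orthology",
                     "staging_observations"):
            path = getattr(v, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"configured input '{name}' does not exist: {path}")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(doc)
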