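"""Pipeline configuration: YAML/JSON loading with strict validation.

Unknown keys are rejected (not warned about) so that a typo in a threshold
name cannot silently fall back to a default; validation errors carry the
field path (e.g. ``screening.fc_threshold``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .screen import ScreeningConfig
from .synth import GENE_CLASSES, ScSimConfig, SingleEventModel

__all__ = [
    "DoseSimSection",
    "ScSimSection",
    "ScreeningSection",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DoseSimSection(_Strict):
    """Synthetic per-cell dose sampling (the Monte-Carlo stand-in)."""

    family: str = "gamma"
    shape: float = Field(2.0, gt=0)
    d1: float = Field(5.0, gt=0, description="macroscopic dose per event, mGy")
    mass_cv: float = Field(0.0, ge=0)
    nucleus_dose_ratio: float = Field(1.2, gt=0)
    event_counts: Tuple[int, ...] = (1, 5, 20, 100)
    n_cells: int = Field(10000, ge=1)
    n_replicates: int = Field(3, ge=1)
    bin_width_mGy: float = Field(0.5, gt=0)

    @field_validator("family")
    @classmethod
    def _family(cls, v: str) -> str:
        if v not in ("gamma", "lognormal"):
            raise ValueError("family must be 'gamma' or 'lognormal'")
        return v

    @field_validator("event_counts")
    @classmethod
    def _counts(cls, v: Tuple[int, ...]) -> Tuple[int, ...]:
        if not v or any(c < 1 for c in v):
            raise ValueError("event_counts must be positive integers")
        return v

    def model(self) -> SingleEventModel:
        return SingleEventModel(
            family=self.family,
            shape=self.shape,
            d1=self.d1,
            mass_cv=self.mass_cv,
            nucleus_dose_ratio=self.nucleus_dose_ratio,
        )


class ScSimSection(_Strict):
    """Synthetic single-cell experiment (see synth.ScSimConfig)."""

    n_genes: int = Field(23517, ge=1)
    n_cells_per_group: int = Field(10000, ge=1)
    dose_groups: Tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)
    class_counts: Dict[str, int] = Field(
        default_factory=lambda: {"A": 200, "B": 200, "D": 200, "E": 50, "AD": 100}
    )
    fc_de: float = Field(2.0, gt=0)
    dispersion_step: float = Field(4.0, gt=1)
    class_e_fc: Tuple[float, ...] = (1.5, 2.0, 0.6)
    nb_size: float = Field(2.0, gt=0)
    base_mean_median: float = Field(3.0, gt=0)
    base_mean_sigma: float = Field(0.8, ge=0)
    planted_mean_floor: float = Field(2.0, ge=0)
    library_cv: float = Field(0.1, ge=0)

    @field_validator("class_counts")
    @classmethod
    def _classes(cls, v: Dict[str, int]) -> Dict[str, int]:
        unknown = set(v) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if any(c < 0 for c in v.values()):
            raise ValueError("class counts must be non-negative")
        return v

    def sim_config(self, seed: int) -> ScSimConfig:
        return ScSimConfig(seed=seed, **self.model_dump())


class ScreeningSection(_Strict):
    """Screen thresholds (see screen.ScreeningConfig)."""

    fc_threshold: float = Field(1.2, gt=0)
    p_threshold: float = Field(0.05, gt=0)
    low_dose_groups: Tuple[float, ...] = (10.0, 100.0)
    top_n_per_group: int = Field(100, ge=1)
    top_n_multifiltered: int = Field(50, ge=1)
    test: str = "welch_t"
    p_adjust: str = "none"
    rmse_aggregation: str = "mean"
    n_bins: int = Field(50, ge=2)
    fc_gate: bool = True
    normalize_library: bool = False

    @field_validator("test")
    @classmethod
    def _test(cls, v: str) -> str:
        if v not in ("welch_t", "wilcoxon"):
            raise ValueError("test must be 'welch_t' or 'wilcoxon'")
        return v

    @field_validator("p_adjust")
    @classmethod
    def _adjust(cls, v: str) -> str:
        if v not in ("none", "BH"):
            raise ValueError("p_adjust must be 'none' or 'BH'")
        return v

    @field_validator("rmse_aggregation")
    @classmethod
    def _agg(cls, v: str) -> str:
        if v not in ("mean", "max", "per_group"):
            raise ValueError("rmse_aggregation must be mean, max or per_group")
        return v

    def screening_config(self) -> ScreeningConfig:
        return ScreeningConfig(**self.model_dump())


class PipelineConfig(_Strict):
    """Top-level run configuration; the master seed is mandatory."""

    seed: int
    out_dir: str = "microdose_run"
    dose_sim: DoseSimSection = Field(default_factory=DoseSimSection)
    sc_sim: ScSimSection = Field(default_factory=ScSimSection)
    screening: ScreeningSection = Field(default_factory=ScreeningSection)

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        missing = set(self.screening.low_dose_groups) - set(self.sc_sim.dose_groups)
        if missing:
            raise ValueError(
                f"screening.low_dose_groups {sorted(missing)} absent from "
                "sc_sim.dose_groups"
            )
        return self


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig(**data)


def dump_config(cfg: PipelineConfig) -> dict:
    """Normalized plain-dict form (round-trips through load)."""
    return json.loads(cfg.model_dump_json())
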