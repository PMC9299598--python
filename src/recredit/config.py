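"""Configuration objects for the synthetic landscape and project generators.

A *landscape* is a set of supersections (the geographic strata over which
common practice is averaged), each subdivided into ecosections (smaller
eco-topographic regions that may be systematically wetter/denser or
drier/sparser than the supersection mean) and populated by forest types
(canonical species groupings with a characteristic species mixture and a
characteristic carbon density).  Assessment areas partition the forest types
of a supersection into the coarse strata a regulator averages over.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "EcosectionSpec",
    "ForestTypeSpec",
    "SupersectionSpec",
    "LandscapeConfig",
    "ProjectSimConfig",
    "build_assessment_map",
]


class EcosectionSpec(BaseModel):
    """One ecosection: an area weight and an additive carbon-density offset.

    The offset (tCO2e/acre) shifts the mean carbon density of every forest
    type occurring in this ecosection, emulating within-supersection
    climatic heterogeneity.
    """

    name: str
    area_weight: float = Field(gt=0)
    carbon_offset: float = 0.0


class ForestTypeSpec(BaseModel):
    """One forest type: carbon-density distribution and species centroid."""

    code: str
    mean_carbon: float = Field(ge=0, description="tCO2e/acre")
    sd_carbon: float = Field(ge=0, description="tCO2e/acre")
    species_centroid: dict[str, float]
    dirichlet_concentration: float = Field(gt=0)

    @field_validator("species_centroid")
    @classmethod
    def _centroid_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("species_centroid must be nonempty")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species_centroid fractions sum to {total}, expected 1")
        if any(f < 0 for f in v.values()):
            raise ValueError("species_centroid fractions must be nonnegative")
        return v


class SupersectionSpec(BaseModel):
    """A supersection: ecosections, forest types, and their partition into
    assessment areas."""

    name: str
    ecosections: list[EcosectionSpec] = Field(min_length=1)
    forest_types: list[ForestTypeSpec] = Field(min_length=1)
    assessment_areas: dict[str, list[str]]

    @model_validator(mode="after")
    def _assessment_areas_partition_types(self) -> "SupersectionSpec":
        codes = [ft.code for ft in self.forest_types]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate forest-type codes in {self.name}")
        assigned: list[str] = []
        for area, members in self.assessment_areas.items():
            if not members:
                raise ValueError(f"assessment area {area!r} is empty")
            assigned.extend(members)
        if sorted(assigned) != sorted(codes):
            raise ValueError(
                f"assessment areas of {self.name} must partition its forest-type "
                f"codes; got {sorted(assigned)} vs {sorted(codes)}"
            )
        return self

    def assessment_area_of(self, forest_type: str) -> str:
        for area, members in self.assessment_areas.items():
            if forest_type in members:
                return area
        raise KeyError(forest_type)


class LandscapeConfig(BaseModel):
    """Full landscape specification with a seed for reproducible generation."""

    supersections: list[SupersectionSpec] = Field(min_length=1)
    n_conditions_per_supersection: int = Field(ge=0)
    expansion_acres_range: tuple[float, float] = (1000.0, 8000.0)
    seed: int = 0

    @model_validator(mode="after")
    def _expansion_range_positive(self) -> "LandscapeConfig":
        lo, hi = self.expansion_acres_range
        if lo <= 0 or hi < lo:
            raise ValueError("expansion_acres_range must satisfy 0 < min <= max")
        return self


class ProjectSimConfig(BaseModel):
    """Parameters of the synthetic offset-project portfolio.

    ``adverse_selection_strength`` (gamma) tilts enrollment toward
    carbon-dense inventory conditions: enrollment probability is
    proportional to exp(gamma * z) where z is the condition's standardized
    carbon density.  gamma = 0 is uniform enrollment.
    """

    n_projects: int = Field(ge=0)
    adverse_selection_strength: float = Field(ge=0, default=0.0)
    baseline_at_cp_fraction: float = Field(ge=0, le=1, default=0.89)
    baseline_noise_sd: float = Field(ge=0, default=2.0)
    acreage_range: tuple[float, float] = (500.0, 5000.0)
    confidence_deduction_range: tuple[float, float] = (0.0, 0.1)
    secondary_effects_range: tuple[float, float] = (-2000.0, 0.0)
    wood_products_range: tuple[float, float] = (0.0, 0.0)
    species_report_level: Literal["per-assessment-area", "project-wide"] = (
        "per-assessment-area"
    )
    seed: int = 0

    @model_validator(mode="after")
    def _ranges_valid(self) -> "ProjectSimConfig":
        if self.acreage_range[0] <= 0 or self.acreage_range[1] < self.acreage_range[0]:
            raise ValueError("acreage_range must satisfy 0 < min <= max")
        lo, hi = self.confidence_deduction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("confidence_deduction_range must lie in [0, 1)")
        lo, hi = self.secondary_effects_range
        if lo > hi or hi > 0 + 1e-12:
            raise ValueError("secondary_effects_range must be nonpositive")
        lo, hi = self.wood_products_range
        if lo < 0 or hi < lo:
            raise ValueError("wood_products_range must satisfy 0 <= min <= max")
        return self


def build_assessment_map(landscape: LandscapeConfig) -> dict[tuple[str, str], str]:
    """Map (supersection, forest_type) -> assessment area for a landscape."""
    out: dict[tuple[str, str], str] = {}
    for ss in landscape.supersections:
        for area, members in ss.assessment_areas.items():
            for code in members:
                out[(ss.name, code)] = area
    return out
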