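"""Upfront-credit arithmetic: issuance replication, common-practice
rescaling, credit recomputation, and portfolio aggregation.

Upfront credits for an improved-forest-management project are the gap
between what the project measured on site and what its 100-year baseline
scenario averages, adjusted for wood products, secondary (market/leakage)
effects and a confidence deduction for inventory uncertainty:

    credits = [ (IC + WP_proj) - (B * A + WP_base) + SE ] * (1 - cd),  floored at 0

where IC is initial onsite carbon (tCO2e, standing pools), WP_* are
wood-product pools (tCO2e), B is the 100-year baseline average onsite
density (tCO2e/acre), A is acreage, SE <= 0 and cd in [0, 1).  The baseline
average is constrained from below by the common practice reported for the
project's assessment area(s), which is what makes common practice the
primary determinant of issuance for the many projects whose baselines sit
exactly at the constraint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from sklearn.metrics import r2_score

logger = logging.getLogger("recredit")

__all__ = [
    "AssessmentAreaShare",
    "ProjectRecord",
    "CreditingOutcome",
    "compute_upfront_credits",
    "replicate_issuance",
    "scale_common_practice",
    "recompute_credits",
    "aggregate_program",
    "buffer_depletion",
    "DEFAULT_PRICE",
]

#: Recent market price of one offset credit, $/tCO2e.
DEFAULT_PRICE = 13.67


class AssessmentAreaShare(BaseModel):
    """One assessment area of a project: acreage share, the common practice
    reported for it, and (optionally) a per-area species composition."""

    assessment_area: str
    acres: float = Field(gt=0)
    reported_common_practice: float = Field(ge=0, description="tCO2e/acre")
    species: dict[str, float] | None = None


class ProjectRecord(BaseModel):
    """Digitized-schema record of one offset project.

    Carbon pools follow registry conventions: ``initial_onsite_carbon``
    bundles the standing onsite pools (IFM-1 + IFM-3); the wood-product
    fields are the IFM-7/IFM-8 pools for the project and baseline
    scenarios.
    """

    project_id: str
    supersection: str
    acreage: float = Field(gt=0)
    assessment_areas: list[AssessmentAreaShare] = Field(min_length=1)
    initial_onsite_carbon: float = Field(ge=0, description="tCO2e")
    wood_products_project: float = Field(ge=0, default=0.0)
    wood_products_baseline: float = Field(ge=0, default=0.0)
    baseline_avg_onsite_density: float = Field(ge=0, description="tCO2e/acre")
    secondary_effects: float = Field(le=0, default=0.0, description="tCO2e")
    confidence_deduction: float = Field(ge=0, lt=1, default=0.0)
    species_project_wide: dict[str, float] | None = None
    species_report_level: Literal["per-assessment-area", "project-wide"] = (
        "per-assessment-area"
    )
    credits_issued: float | None = None
    true_forest_type: str | None = None  # generator ground truth, if synthetic

    @model_validator(mode="after")
    def _consistent(self) -> "ProjectRecord":
        area_total = sum(a.acres for a in self.assessment_areas)
        if abs(area_total - self.acreage) > 1e-6 * max(self.acreage, 1.0):
            raise ValueError(
                f"{self.project_id}: assessment-area acres ({area_total}) must "
                f"sum to project acreage ({self.acreage})"
            )
        cp = self.reported_common_practice
        if self.baseline_avg_onsite_density < cp - 1e-9:
            raise ValueError(
                f"{self.project_id}: baseline average "
                f"({self.baseline_avg_onsite_density}) below reported common "
                f"practice ({cp}); the protocol constraint forbids this"
            )
        return self

    @property
    def initial_onsite_density(self) -> float:
        """tCO2e/acre of standing onsite carbon."""
        return self.initial_onsite_carbon / self.acreage

    @property
    def area_weights(self) -> dict[str, float]:
        """Assessment-area acreage weights, normalized to sum to 1."""
        return {a.assessment_area: a.acres / self.acreage for a in self.assessment_areas}

    @property
    def reported_common_practice(self) -> float:
        """Project-level reported common practice: acreage-weighted over areas."""
        return sum(
            a.acres * a.reported_common_practice for a in self.assessment_areas
        ) / self.acreage

    @property
    def baseline_margin(self) -> float:
        """How far the reported baseline average sits above its constraint."""
        return max(0.0, self.baseline_avg_onsite_density - self.reported_common_practice)


@dataclass(frozen=True)
class CreditingOutcome:
    """Point estimate and Monte Carlo percentile summary of one project's
    crediting error (issued - recomputed; positive = over-credited)."""

    project_id: str
    credits_issued: float
    credits_recomputed: float
    crediting_error: float
    error_percent: float
    scaled_common_practice: float
    percentiles: dict[float, float]  # percentile -> error (tCO2e)
    error_percent_percentiles: dict[float, float]


def _upfront_credits_kernel(
    initial_onsite_carbon,
    wood_products_project,
    wood_products_baseline,
    baseline_density,
    acreage,
    secondary_effects,
    confidence_deduction,
):
    """Vectorizable core of the issuance formula; floors at 0."""
    gross = (
        (initial_onsite_carbon + wood_products_project)
        - (baseline_density * acreage + wood_products_baseline)
        + secondary_effects
    )
    return np.maximum(gross * (1.0 - confidence_deduction), 0.0)


def compute_upfront_credits(
    project: ProjectRecord, baseline_density: float | None = None
) -> float:
    """Replicate the upfront issuance calculation for one project.

    ``baseline_density`` overrides the recorded 100-year baseline average
    (used when recomputing under a rescaled common-practice constraint).
    """
    b = (
        project.baseline_avg_onsite_density
        if baseline_density is None
        else baseline_density
    )
    return float(
        _upfront_credits_kernel(
            project.initial_onsite_carbon,
            project.wood_products_project,
            project.wood_products_baseline,
            b,
            project.acreage,
            project.secondary_effects,
            project.confidence_deduction,
        )
    )


def replicate_issuance(
    projects: Sequence[ProjectRecord],
) -> tuple[list[tuple[str, float, float]], float | None]:
    """Recompute every project's issuance and compare with the recorded value.

    Returns (pairs, r_squared) where pairs is a list of
    (project_id, computed, recorded) and r_squared is the coefficient of
    determination of computed vs recorded credits — or None when fewer than
    two projects carry recorded credits or the recorded credits have zero
    variance.
    """
    pairs = [
        (p.project_id, compute_upfront_credits(p), float(p.credits_issued))
        for p in projects
        if p.credits_issued is not None
    ]
    if len(pairs) < 2:
        logger.warning("issuance replication needs >= 2 recorded projects")
        return pairs, None
    recorded = np.array([r for _, _, r in pairs])
    computed = np.array([c for _, c, _ in pairs])
    if np.ptp(recorded) == 0:
        logger.warning("recorded credits are constant; R^2 undefined")
        return pairs, None
    return pairs, float(r2_score(recorded, computed))


def scale_common_practice(
    project: ProjectRecord,
    alt_cp: Mapping[str, float],
    recomputed_cp: Mapping[str, float],
) -> float:
    """Rescale the project's reported common practice.

    Rather than replacing the reported value outright, the reported common
    practice is multiplied by the acreage-weighted ratio of the alternative
    (species-specific) estimate to our own recomputation of the regulator's
    assessment-area estimate:

        scaled = reported * sum_a w_a * (alt_a / recomputed_a)

    so that any change is attributable purely to the change in aggregation,
    not to discrepancies in reproducing the original numbers.  Both mappings
    are keyed by assessment-area name and must cover every area of the
    project.
    """
    weights = project.area_weights
    ratio = 0.0
    for area, w in weights.items():
        if area not in alt_cp or area not in recomputed_cp:
            raise KeyError(
                f"{project.project_id}: missing common-practice estimate for "
                f"assessment area {area!r}"
            )
        denom = recomputed_cp[area]
        if denom <= 0:
            raise ValueError(
                f"{project.project_id}: recomputed common practice for area "
                f"{area!r} is {denom}; scaling ratio undefined"
            )
        ratio += w * (alt_cp[area] / denom)
    return project.reported_common_practice * ratio


def recompute_credits(project: ProjectRecord, scaled_cp: float) -> tuple[float, float]:
    """Credits the project would have earned under the rescaled constraint.

    The project is assumed to re-select its baseline against the new
    constraint while preserving the absolute margin it originally kept above
    the old one (0 for the many projects whose baselines sat exactly at
    common practice).  A negative rescaled common practice (possible inside
    Gaussian Monte Carlo draws) is floored at 0 here.

    Returns (recomputed_credits, new_baseline_density).
    """
    if scaled_cp < 0:
        logger.warning(
            "%s: negative scaled common practice %.2f floored at 0",
            project.project_id,
            scaled_cp,
        )
        scaled_cp = 0.0
    new_baseline = scaled_cp + project.baseline_margin
    return compute_upfront_credits(project, baseline_density=new_baseline), new_baseline


def aggregate_program(
    outcomes: Sequence[CreditingOutcome] | Sequence[float],
    total_analyzed_credits: float,
    price: float = DEFAULT_PRICE,
    error_draws: np.ndarray | None = None,
    percentiles: Sequence[float] = (5, 50, 95),
) -> dict:
    """Program-wide net crediting error, as credits, percent and dollars.

    ``outcomes`` may be CreditingOutcome objects or raw per-project errors
    (tCO2e).  When ``error_draws`` (per-draw program net totals, tCO2e) is
    given, the same transforms are applied per draw and summarised at
    ``percentiles`` — percentiles of totals, never totals of percentiles.
    """
    if total_analyzed_credits <= 0:
        raise ValueError("total_analyzed_credits must be positive")
    errors = [
        o.crediting_error if isinstance(o, CreditingOutcome) else float(o)
        for o in outcomes
    ]
    net = float(sum(errors))
    summary = {
        "net_error_tco2e": net,
        "total_analyzed_credits": float(total_analyzed_credits),
        "percent_of_analyzed": 100.0 * net / total_analyzed_credits,
        "dollar_value": net * price,
        "price": float(price),
        "n_projects": len(errors),
    }
    if error_draws is not None and len(error_draws) > 0:
        qs = np.percentile(np.asarray(error_draws, dtype=float), list(percentiles))
        summary["percentiles"] = {
            "net_error_tco2e": dict(zip(percentiles, map(float, qs), strict=True)),
            "percent_of_analyzed": {
                p: 100.0 * q / total_analyzed_credits
                for p, q in zip(percentiles, qs, strict=True)
            },
            "dollar_value": {
                p: float(q * price) for p, q in zip(percentiles, qs, strict=True)
            },
        }
    return summary


def buffer_depletion(error: float, buffer_pool: float) -> int:
    """Percent of the program's buffer pool that compensating ``error``
    would consume, rounded to the nearest integer percent."""
    if buffer_pool <= 0:
        raise ValueError("buffer_pool must be positive")
    return int(round(100.0 * error / buffer_pool))
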