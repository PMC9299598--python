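"""Monte Carlo propagation of inventory sampling uncertainty.

Forest-type common-practice estimates carry sampling variances from the
inventory.  Assuming Gaussian noise, each draw perturbs every forest-type
mean density once and pushes the perturbed values coherently through the
whole recrediting chain: the classifier-weighted alternative common
practice (numerator of the scaling ratio) and the recomputed assessment-
area common practice (denominator) are both rebuilt from the *same* draw,
preserving the correlation implied by deriving both from one dataset.

Random streams are keyed per (forest type, draw) — a CRC of the stratum key
mixed with the seed and draw index — so adding or removing projects (or
reordering types) never changes another stratum's draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .crediting import (
    CreditingOutcome,
    ProjectRecord,
    _upfront_credits_kernel,
    compute_upfront_credits,
)
from .inventory import CommonPracticeEstimate

logger = logging.getLogger("recredit")

__all__ = ["MonteCarloConfig", "draw_carbon_estimates", "propagate", "PropagationResult"]


class MonteCarloConfig(BaseModel):
    n_draws: int = Field(ge=1, default=1000)
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)

    @field_validator("percentiles")
    @classmethod
    def _valid_percentiles(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not all(0 < p < 100 for p in v):
            raise ValueError("percentiles must lie strictly between 0 and 100")
        if list(v) != sorted(v) or len(set(v)) != len(v):
            raise ValueError("percentiles must be strictly increasing")
        return v


def _stratum_stream(seed: int, stratum: tuple, draw_index: int) -> np.random.Generator:
    key = zlib.crc32("/".join(map(str, stratum)).encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key, draw_index)))


def draw_carbon_estimates(
    cp_estimates: Sequence[CommonPracticeEstimate],
    config: MonteCarloConfig,
    draw_index: int,
) -> dict[tuple, float]:
    """One Gaussian draw of every stratum's mean density.

    Deterministic given (seed, stratum, draw_index); draws are independent
    across strata and across draw indices.  Negative draws are kept — the
    Gaussian assumption is applied literally here and any resulting negative
    common practice is floored only where credits are computed.
    """
    out: dict[tuple, float] = {}
    for est in cp_estimates:
        if est.variance < 0:
            raise ValueError(f"negative variance for stratum {est.stratum}")
        rng = _stratum_stream(config.seed, est.stratum, draw_index)
        out[est.stratum] = float(
            rng.normal(est.mean_density, np.sqrt(est.variance))
        )
    return out


@dataclass
class PropagationResult:
    """Per-project outcomes plus per-draw program totals."""

    outcomes: list[CreditingOutcome]
    program_error_draws: np.ndarray  # shape (n_draws,), tCO2e
    n_negative_cp_floored: int
    n_bad_ratio_draws: int


def _recredit_matrix(
    projects: Sequence[ProjectRecord],
    assessment_map: Mapping[tuple[str, str], str],
    type_order: list[tuple],
    classifications: Mapping[str, Mapping[str, Mapping[str, float]]],
    type_acres: np.ndarray,
    means_matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Recompute credits for every project under every column of
    ``means_matrix`` (T x D perturbed forest-type mean densities).

    Returns (errors, scaled_cp, n_floored, n_bad_ratio): errors and
    scaled_cp have shape (n_projects, D).
    """
    t_index = {k: i for i, k in enumerate(type_order)}
    n_proj, D = len(projects), means_matrix.shape[1]

    # project-area rows
    alt_rows, rec_rows, w_rows, proj_of_row = [], [], [], []
    for pi, p in enumerate(projects):
        probs_by_area = classifications[p.project_id]
        for share in p.assessment_areas:
            alt = np.zeros(len(type_order))
            for ft, prob in probs_by_area[share.assessment_area].items():
                key = (p.supersection, ft)
                if key not in t_index:
                    raise KeyError(
                        f"{p.project_id}: classifier type {ft!r} has no "
                        f"common-practice estimate in {p.supersection!r}"
                    )
                alt[t_index[key]] = prob
            rec = np.zeros(len(type_order))
            for key, i in t_index.items():
                if key[0] == p.supersection and assessment_map.get(key) == share.assessment_area:
                    rec[i] = type_acres[i]
            total = rec.sum()
            if total <= 0:
                raise ValueError(
                    f"{p.project_id}: no inventory acreage for assessment area "
                    f"{share.assessment_area!r}"
                )
            alt_rows.append(alt)
            rec_rows.append(rec / total)
            w_rows.append(share.acres / p.acreage)
            proj_of_row.append(pi)

    ALT = np.asarray(alt_rows) @ means_matrix  # (n_rows, D)
    REC = np.asarray(rec_rows) @ means_matrix
    bad = REC <= 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%d draw cells had nonpositive recomputed CP; set to NaN", n_bad)
        REC = np.where(bad, np.nan, REC)
    ratio = ALT / REC

    factor = np.zeros((n_proj, D))
    np.add.at(factor, np.asarray(proj_of_row), np.asarray(w_rows)[:, None] * ratio)

    reported = np.array([p.reported_common_practice for p in projects])
    scaled = reported[:, None] * factor
    floored = scaled < 0
    n_floored = int(floored.sum())
    if n_floored:
        logger.warning("%d negative scaled-CP cells floored at 0", n_floored)
    scaled_eff = np.maximum(scaled, 0.0)
    margin = np.array([p.baseline_margin for p in projects])
    new_baseline = scaled_eff + margin[:, None]

    credits_new = _upfront_credits_kernel(
        np.array([p.initial_onsite_carbon for p in projects])[:, None],
        np.array([p.wood_products_project for p in projects])[:, None],
        np.array([p.wood_products_baseline for p in projects])[:, None],
        new_baseline,
        np.array([p.acreage for p in projects])[:, None],
        np.array([p.secondary_effects for p in projects])[:, None],
        np.array([p.confidence_deduction for p in projects])[:, None],
    )
    issued = np.array(
        [
            p.credits_issued if p.credits_issued is not None else compute_upfront_credits(p)
            for p in projects
        ]
    )
    errors = issued[:, None] - credits_new
    return errors, scaled, n_floored, n_bad


def propagate(
    projects: Sequence[ProjectRecord],
    type_estimates: Sequence[CommonPracticeEstimate],
    assessment_map: Mapping[tuple[str, str], str],
    classifications: Mapping[str, Mapping[str, Mapping[str, float]]],
    config: MonteCarloConfig,
    perturb_assessment_cp: bool = True,
) -> PropagationResult:
    """Propagate forest-type sampling uncertainty to crediting errors.

    Parameters
    ----------
    projects : project records (credits_issued populated or recomputable).
    type_estimates : (supersection, forest_type) common-practice estimates
        with variances; these are the perturbed quantities.
    assessment_map : (supersection, forest_type) -> assessment area.
    classifications : project_id -> assessment area -> {forest type: prob}.
    config : draw count, seed, reported percentiles.
    perturb_assessment_cp : rebuild the scaling-ratio denominator from the
        same draw (default).  When False the denominator stays at its point
        estimate and only the species-specific numerator is perturbed.

    Program-level percentiles are computed on per-draw program totals,
    never by summing per-project percentiles.
    """
    if config.n_draws < 20 and any(p <= 5 or p >= 95 for p in config.percentiles):
        logger.warning(
            "extreme percentiles requested with only %d draws; estimates unstable",
            config.n_draws,
        )
    type_order = [est.stratum for est in type_estimates]
    means = np.array([est.mean_density for est in type_estimates])
    acres = np.array([est.total_acres for est in type_estimates])

    # T x n_draws matrix of perturbed means, one keyed stream per (type, draw)
    M = np.empty((len(type_order), config.n_draws))
    for d in range(config.n_draws):
        drawn = draw_carbon_estimates(type_estimates, config, d)
        M[:, d] = [drawn[k] for k in type_order]

    errors, _, n_floor, n_bad = _recredit_matrix(
        projects, assessment_map, type_order, classifications, acres, M
    )
    if not perturb_assessment_cp:
        # numerator perturbed, denominator at point estimate: run the chain
        # once more with unperturbed denominators and splice the ratio there
        errors_fixed, _, nf2, nb2 = _recredit_matrix_fixed_denominator(
            projects, assessment_map, type_order, classifications, acres, M, means
        )
        errors, n_floor, n_bad = errors_fixed, nf2, nb2

    point_errors, point_scaled, _, _ = _recredit_matrix(
        projects, assessment_map, type_order, classifications, acres, means[:, None]
    )

    issued = np.array(
        [
            p.credits_issued if p.credits_issued is not None else compute_upfront_credits(p)
            for p in projects
        ]
    )
    pct = list(config.percentiles)
    outcomes = []
    for i, p in enumerate(projects):
        err_draws = errors[i]
        qs = np.nanpercentile(err_draws, pct)
        err_point = float(point_errors[i, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_point = 100.0 * err_point / issued[i] if issued[i] > 0 else float("nan")
            pct_qs = (
                100.0 * qs / issued[i] if issued[i] > 0 else np.full(len(pct), np.nan)
            )
        outcomes.append(
            CreditingOutcome(
                project_id=p.project_id,
                credits_issued=float(issued[i]),
                credits_recomputed=float(issued[i] - err_point),
                crediting_error=err_point,
                error_percent=pct_point,
                scaled_common_practice=float(point_scaled[i, 0]),
                percentiles=dict(zip(pct, map(float, qs), strict=True)),
                error_percent_percentiles=dict(
                    zip(pct, map(float, pct_qs), strict=True)
                ),
            )
        )
    program_draws = errors.sum(axis=0)
    return PropagationResult(
        outcomes=outcomes,
        program_error_draws=program_draws,
        n_negative_cp_floored=n_floor,
        n_bad_ratio_draws=n_bad,
    )


def _recredit_matrix_fixed_denominator(
    projects, assessment_map, type_order, classifications, type_acres, M, means
):
    """Variant with the assessment-area denominator held at its point
    estimate while the species-specific numerator is perturbed."""
    t_index = {k: i for i, k in enumerate(type_order)}
    n_proj, D = len(projects), M.shape[1]
    factor = np.zeros((n_proj, D))
    for pi, p in enumerate(projects):
        probs_by_area = classifications[p.project_id]
        for share in p.assessment_areas:
            alt = np.zeros(len(type_order))
            for ft, prob in probs_by_area[share.assessment_area].items():
                alt[t_index[(p.supersection, ft)]] = prob
            rec = np.zeros(len(type_order))
            for key, i in t_index.items():
                if key[0] == p.supersection and assessment_map.get(key) == share.assessment_area:
                    rec[i] = type_acres[i]
            denom = float(rec / rec.sum() @ means)
            factor[pi] += (share.acres / p.acreage) * (alt @ M) / denom
    reported = np.array([p.reported_common_practice for p in projects])
    scaled = reported[:, None] * factor
    floored = scaled < 0
    scaled_eff = np.maximum(scaled, 0.0)
    margin = np.array([p.baseline_margin for p in projects])
    credits_new = _upfront_credits_kernel(
        np.array([p.initial_onsite_carbon for p in projects])[:, None],
        np.array([p.wood_products_project for p in projects])[:, None],
        np.array([p.wood_products_baseline for p in projects])[:, None],
        scaled_eff + margin[:, None],
        np.array([p.acreage for p in projects])[:, None],
        np.array([p.secondary_effects for p in projects])[:, None],
        np.array([p.confidence_deduction for p in projects])[:, None],
    )
    issued = np.array(
        [
            p.credits_issued if p.credits_issued is not None else compute_upfront_credits(p)
            for p in projects
        ]
    )
    return issued[:, None] - credits_new, scaled, int(floored.sum()), 0
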