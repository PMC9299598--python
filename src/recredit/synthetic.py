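"""Synthetic forest-inventory and offset-project generator.

Emulates the statistical structure the crediting analysis assumes, with
ground truth known in closed form so every downstream stage can be tested
as a parameter-recovery problem:

* Inventory conditions are drawn per supersection.  Each condition sits in
  an ecosection (sampled by area weight, carrying an additive carbon
  offset), carries one forest type (sampled uniformly over the
  supersection's configured types), a species composition drawn from the
  type's Dirichlet(centroid * concentration), a carbon density drawn from a
  normal truncated at 0, and an acreage expansion factor.
* Projects enroll inventory conditions with probability proportional to
  exp(gamma * z), z the condition's standardized carbon density: gamma = 0
  is uniform enrollment, large gamma emulates developers cherry-picking
  "carbon gems".  Only conditions whose density exceeds the assessment
  area's true common practice become projects, mirroring the eligibility
  rule that only above-average forests earn upfront credits.  Most projects
  place their 100-year baseline average exactly at common practice; the
  rest sit above it by folded-Gaussian noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    EcosectionSpec,
    ForestTypeSpec,
    LandscapeConfig,
    ProjectSimConfig,
    SupersectionSpec,
    build_assessment_map,
)
from .crediting import AssessmentAreaShare, ProjectRecord, compute_upfront_credits

logger = logging.getLogger("recredit")

__all__ = [
    "GroundTruth",
    "landscape_ground_truth",
    "generate_inventory",
    "generate_projects",
    "threshold_species",
    "write_inventory_csv",
    "read_inventory_csv",
    "write_projects_json",
    "read_projects_json",
    "demo_landscape",
    "density_homogeneous_landscape",
    "density_stratified_landscape",
    "species_separable_landscape",
]

INVENTORY_SCHEMA = "recredit.inventory.v1"
PROJECTS_SCHEMA = "recredit.projects.v1"

#: Species below this fractional basal area are dropped from project
#: paperwork (registry digitization rule); the remainder is renormalized.
SPECIES_REPORT_THRESHOLD = 0.05


@dataclass
class GroundTruth:
    """Closed-form population values implied by a LandscapeConfig.

    ``forest_type_cp`` and ``assessment_area_cp`` are the expansion-weighted
    population mean carbon densities (tCO2e/acre); because expansion acreage
    is drawn independently of density, these reduce to ecosection-weighted
    truncated-normal means and their per-assessment-area (equal-type-weight)
    averages.  ``project_forest_type`` is filled by :func:`generate_projects`.
    """

    forest_type_cp: dict[tuple[str, str], float]
    assessment_area_cp: dict[tuple[str, str], float]
    project_forest_type: dict[str, str] = field(default_factory=dict)


def _truncnorm_mean(mu: float, sigma: float) -> float:
    """Mean of N(mu, sigma) truncated to [0, inf)."""
    if sigma == 0:
        return max(mu, 0.0)
    a = (0.0 - mu) / sigma
    return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma))


def landscape_ground_truth(landscape: LandscapeConfig) -> GroundTruth:
    """Population common practice per forest type and per assessment area."""
    ft_cp: dict[tuple[str, str], float] = {}
    aa_cp: dict[tuple[str, str], float] = {}
    for ss in landscape.supersections:
        w = np.array([e.area_weight for e in ss.ecosections], dtype=float)
        w = w / w.sum()
        for ft in ss.forest_types:
            means = [
                _truncnorm_mean(ft.mean_carbon + e.carbon_offset, ft.sd_carbon)
                for e in ss.ecosections
            ]
            ft_cp[(ss.name, ft.code)] = float(np.dot(w, means))
        for area, members in ss.assessment_areas.items():
            aa_cp[(ss.name, area)] = float(
                np.mean([ft_cp[(ss.name, code)] for code in members])
            )
    return GroundTruth(forest_type_cp=ft_cp, assessment_area_cp=aa_cp)


def generate_inventory(config: LandscapeConfig) -> pd.DataFrame:
    """Generate an inventory-condition table; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.expansion_acres_range
    rows: list[dict] = []
    for ss in config.supersections:
        n = config.n_conditions_per_supersection
        if n == 0:
            continue
        eco_w = np.array([e.area_weight for e in ss.ecosections], dtype=float)
        eco_w = eco_w / eco_w.sum()
        eco_idx = rng.choice(len(ss.ecosections), size=n, p=eco_w)
        type_idx = rng.integers(len(ss.forest_types), size=n)
        expansion = rng.uniform(lo, hi, size=n)
        for i in range(n):
            eco = ss.ecosections[int(eco_idx[i])]
            ft = ss.forest_types[int(type_idx[i])]
            species = sorted(ft.species_centroid)
            alpha = np.array(
                [ft.species_centroid[s] for s in species], dtype=float
            ) * ft.dirichlet_concentration
            # Dirichlet requires strictly positive alpha; zero-weight species
            # simply never appear in this type's draws.
            keep = alpha > 0
            fracs = np.zeros(len(species))
            fracs[keep] = rng.dirichlet(alpha[keep])
            mu = ft.mean_carbon + eco.carbon_offset
            if ft.sd_carbon == 0:
                carbon = max(mu, 0.0)
            else:
                a = (0.0 - mu) / ft.sd_carbon
                carbon = float(
                    stats.truncnorm.rvs(
                        a, np.inf, loc=mu, scale=ft.sd_carbon, random_state=rng
                    )
                )
            rows.append(
                {
                    "supersection": ss.name,
                    "ecosection": eco.name,
                    "forest_type": ft.code,
                    "species_fractions": {
                        s: float(f) for s, f in zip(species, fracs, strict=True) if f > 0
                    },
                    "carbon_density": carbon,
                    "expansion_acres": float(expansion[i]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "supersection",
            "ecosection",
            "forest_type",
            "species_fractions",
            "carbon_density",
            "expansion_acres",
        ],
    )


def threshold_species(
    fractions: dict[str, float], threshold: float = SPECIES_REPORT_THRESHOLD
) -> dict[str, float]:
    """Drop species below the reporting threshold and renormalize to sum 1."""
    kept = {s: f for s, f in fractions.items() if f > threshold}
    if not kept:
        # keep the single dominant species rather than reporting nothing
        s = max(fractions, key=fractions.get)
        kept = {s: fractions[s]}
    total = sum(kept.values())
    return {s: f / total for s, f in kept.items()}


def generate_projects(
    config: ProjectSimConfig,
    landscape: LandscapeConfig,
    inventory: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[ProjectRecord], GroundTruth]:
    """Generate a synthetic offset-project portfolio from an inventory.

    Each project enrolls one inventory condition (with the configured
    adverse-selection tilt), adopts its species mixture (thresholded the way
    registries digitize paperwork) and its carbon density, and is issued
    upfront credits by the same formula the analysis later replicates.
    Conditions whose density does not exceed their assessment area's true
    common practice are ineligible and resampled.
    """
    if len(inventory) == 0:
        raise ValueError("inventory must be nonempty")
    gt = ground_truth if ground_truth is not None else landscape_ground_truth(landscape)
    assessment_map = build_assessment_map(landscape)
    rng = np.random.default_rng(config.seed)

    dens = inventory["carbon_density"].to_numpy(dtype=float)
    sd = dens.std()
    z = (dens - dens.mean()) / sd if sd > 0 else np.zeros_like(dens)
    gamma = config.adverse_selection_strength
    logw = gamma * z
    weights = np.exp(logw - logw.max())
    weights = weights / weights.sum()

    eligible_cp = np.array(
        [
            gt.assessment_area_cp[
                (row.supersection, assessment_map[(row.supersection, row.forest_type)])
            ]
            for row in inventory.itertuples()
        ]
    )
    eligible = dens > eligible_cp
    if not eligible.any():
        raise ValueError("no inventory condition exceeds its common practice")

    projects: list[ProjectRecord] = []
    max_attempts = 1000 * max(config.n_projects, 1)
    attempts = 0
    while len(projects) < config.n_projects and attempts < max_attempts:
        attempts += 1
        idx = int(rng.choice(len(inventory), p=weights))
        if not eligible[idx]:
            continue
        cond = inventory.iloc[idx]
        ss = cond["supersection"]
        ft = cond["forest_type"]
        area = assessment_map[(ss, ft)]
        cp = gt.assessment_area_cp[(ss, area)]

        acreage = float(rng.uniform(*config.acreage_range))
        at_cp = rng.random() < config.baseline_at_cp_fraction
        baseline = cp if at_cp else cp + abs(rng.normal(0.0, config.baseline_noise_sd))
        deduction = float(rng.uniform(*config.confidence_deduction_range))
        secondary = float(rng.uniform(*config.secondary_effects_range))
        wp_lo, wp_hi = config.wood_products_range
        wp_project = float(rng.uniform(wp_lo, wp_hi))
        wp_baseline = float(rng.uniform(wp_lo, wp_hi))

        species = threshold_species(dict(cond["species_fractions"]))
        pid = f"SYN{len(projects) + 1:04d}"
        per_area = config.species_report_level == "per-assessment-area"
        record = ProjectRecord(
            project_id=pid,
            supersection=ss,
            acreage=acreage,
            assessment_areas=[
                AssessmentAreaShare(
                    assessment_area=area,
                    acres=acreage,
                    reported_common_practice=cp,
                    species=species if per_area else None,
                )
            ],
            initial_onsite_carbon=float(cond["carbon_density"]) * acreage,
            wood_products_project=wp_project,
            wood_products_baseline=wp_baseline,
            baseline_avg_onsite_density=float(baseline),
            secondary_effects=secondary,
            confidence_deduction=deduction,
            species_project_wide=None if per_area else species,
            species_report_level=config.species_report_level,
            true_forest_type=ft,
        )
        record.credits_issued = compute_upfront_credits(record)
        projects.append(record)
        gt.project_forest_type[pid] = ft
    if len(projects) < config.n_projects:
        logger.warning(
            "only %d of %d requested projects were eligible",
            len(projects),
            config.n_projects,
        )
    return projects, gt


# ---------------------------------------------------------------------------
# serialization


def write_inventory_csv(inventory: pd.DataFrame, path: str | Path) -> None:
    out = inventory.copy()
    out["species_fractions"] = out["species_fractions"].map(json.dumps)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {INVENTORY_SCHEMA}\n")
        out.to_csv(fh, index=False)


def read_inventory_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    frame["species_fractions"] = frame["species_fractions"].map(json.loads)
    return frame


def write_projects_json(projects: Sequence[ProjectRecord], path: str | Path) -> None:
    payload = {
        "schema": PROJECTS_SCHEMA,
        "projects": [p.model_dump() for p in projects],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_projects_json(path: str | Path) -> list[ProjectRecord]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != PROJECTS_SCHEMA:
        raise ValueError(f"unexpected projects schema: {payload.get('schema')!r}")
    return [ProjectRecord.model_validate(p) for p in payload["projects"]]


# ---------------------------------------------------------------------------
# ready-made landscapes
#
# These encode the study conditions used throughout the tests and the demo
# pipeline; carbon densities are loosely modelled on western US forest
# types (tCO2e/acre).


def demo_landscape(
    seed: int = 0, n_conditions_per_supersection: int = 600
) -> LandscapeConfig:
    """Two-supersection landscape with ecologically mixed assessment areas.

    The first supersection averages a wet, carbon-dense conifer/tanoak flora
    with arid pine woodland inside one assessment area — the configuration
    that makes a coarse regional average unrepresentative of almost every
    parcel in it.  The second has a dense redwood/tanoak coastal flora.
    """
    cascades = SupersectionSpec(
        name="Cascades",
        ecosections=[
            EcosectionSpec(name="ECO-WET", area_weight=0.3, carbon_offset=25.0),
            EcosectionSpec(name="ECO-MID", area_weight=0.35, carbon_offset=0.0),
            EcosectionSpec(name="ECO-DRY", area_weight=0.35, carbon_offset=-20.0),
        ],
        forest_types=[
            ForestTypeSpec(
                code="DOUGLAS_FIR",
                mean_carbon=122.5,
                sd_carbon=28.0,
                species_centroid={"PSME": 0.6, "NODE3": 0.15, "ABCO": 0.25},
                dirichlet_concentration=60.0,
            ),
            ForestTypeSpec(
                code="TANOAK",
                mean_carbon=192.4,
                sd_carbon=35.0,
                species_centroid={"NODE3": 0.65, "PSME": 0.2, "ARME": 0.15},
                dirichlet_concentration=60.0,
            ),
            ForestTypeSpec(
                code="PONDEROSA",
                mean_carbon=60.4,
                sd_carbon=16.0,
                species_centroid={"PIPO": 0.75, "CADE27": 0.15, "QUKE": 0.1},
                dirichlet_concentration=60.0,
            ),
            ForestTypeSpec(
                code="OAK_WOODLAND",
                mean_carbon=45.0,
                sd_carbon=12.0,
                species_centroid={"QUKE": 0.6, "QUGA4": 0.3, "PIPO": 0.1},
                dirichlet_concentration=60.0,
            ),
        ],
        assessment_areas={
            "Mixed Conifer": ["DOUGLAS_FIR", "TANOAK", "PONDEROSA"],
            "Oak Woodland": ["OAK_WOODLAND"],
        },
    )
    coast = SupersectionSpec(
        name="North Coast",
        ecosections=[
            EcosectionSpec(name="ECO-COAST", area_weight=0.55, carbon_offset=10.0),
            EcosectionSpec(name="ECO-INLAND", area_weight=0.45, carbon_offset=-12.0),
        ],
        forest_types=[
            ForestTypeSpec(
                code="REDWOOD",
                mean_carbon=225.0,
                sd_carbon=40.0,
                species_centroid={"SESE3": 0.7, "PSME": 0.2, "NODE3": 0.1},
                dirichlet_concentration=60.0,
            ),
            ForestTypeSpec(
                code="COAST_TANOAK",
                mean_carbon=173.7,
                sd_carbon=30.0,
                species_centroid={"NODE3": 0.6, "SESE3": 0.1, "PSME": 0.1, "ARME": 0.2},
                dirichlet_concentration=60.0,
            ),
            ForestTypeSpec(
                code="COAST_OAK",
                mean_carbon=70.0,
                sd_carbon=18.0,
                species_centroid={"QUGA4": 0.55, "QUKE": 0.3, "ARME": 0.15},
                dirichlet_concentration=60.0,
            ),
        ],
        assessment_areas={
            "Redwood Mixed Conifer": ["REDWOOD", "COAST_TANOAK"],
            "Coastal Oak": ["COAST_OAK"],
        },
    )
    return LandscapeConfig(
        supersections=[cascades, coast],
        n_conditions_per_supersection=n_conditions_per_supersection,
        seed=seed,
    )


def density_homogeneous_landscape(
    seed: int = 0, n_conditions_per_supersection: int = 600
) -> LandscapeConfig:
    """One supersection whose forest types share a common carbon-density
    distribution but differ in species composition.

    Because every type in the assessment area has the same mean density, the
    regional average is representative of each type and eligibility
    filtering cannot tilt enrollment toward any type: crediting errors under
    uniform enrollment should be zero in expectation.
    """
    species = [
        {"SPA": 0.7, "SPB": 0.3},
        {"SPC": 0.7, "SPD": 0.3},
        {"SPE": 0.7, "SPF": 0.3},
    ]
    types = [
        ForestTypeSpec(
            code=f"TYPE_{i}",
            mean_carbon=120.0,
            sd_carbon=20.0,
            species_centroid=c,
            dirichlet_concentration=80.0,
        )
        for i, c in enumerate(species)
    ]
    ss = SupersectionSpec(
        name="Uniform",
        ecosections=[EcosectionSpec(name="ECO-1", area_weight=1.0, carbon_offset=0.0)],
        forest_types=types,
        assessment_areas={"All": [t.code for t in types]},
    )
    return LandscapeConfig(
        supersections=[ss],
        n_conditions_per_supersection=n_conditions_per_supersection,
        seed=seed,
    )


def density_stratified_landscape(
    seed: int = 0, n_conditions_per_supersection: int = 600
) -> LandscapeConfig:
    """One assessment area pooling carbon-poor, average, and carbon-dense
    forest types — the configuration under which adverse selection converts
    a coarse average into systematic over-crediting."""
    specs = [
        ("SPARSE", 60.0, {"SPA": 0.8, "SPB": 0.2}),
        ("MIDDLE", 120.0, {"SPC": 0.8, "SPD": 0.2}),
        ("DENSE", 190.0, {"SPE": 0.8, "SPF": 0.2}),
    ]
    types = [
        ForestTypeSpec(
            code=code,
            mean_carbon=mean,
            sd_carbon=18.0,
            species_centroid=c,
            dirichlet_concentration=80.0,
        )
        for code, mean, c in specs
    ]
    ss = SupersectionSpec(
        name="Stratified",
        ecosections=[EcosectionSpec(name="ECO-1", area_weight=1.0, carbon_offset=0.0)],
        forest_types=types,
        assessment_areas={"Pooled": [t.code for t in types]},
    )
    return LandscapeConfig(
        supersections=[ss],
        n_conditions_per_supersection=n_conditions_per_supersection,
        seed=seed,
    )


def species_separable_landscape(
    seed: int = 0,
    n_conditions_per_supersection: int = 300,
    dirichlet_concentration: float = 200.0,
    n_supersections: int = 3,
) -> LandscapeConfig:
    """Landscapes whose forest types have disjoint species supports and tight
    compositions, so a composition-based classifier can be perfect."""
    sss = []
    for k in range(n_supersections):
        types = [
            ForestTypeSpec(
                code=f"S{k}_T{i}",
                mean_carbon=100.0 + 40.0 * i,
                sd_carbon=15.0,
                species_centroid={f"S{k}SP{2 * i}": 0.7, f"S{k}SP{2 * i + 1}": 0.3},
                dirichlet_concentration=dirichlet_concentration,
            )
            for i in range(3)
        ]
        sss.append(
            SupersectionSpec(
                name=f"SS{k}",
                ecosections=[
                    EcosectionSpec(name=f"SS{k}-ECO", area_weight=1.0, carbon_offset=0.0)
                ],
                forest_types=types,
                assessment_areas={f"SS{k}-AA": [t.code for t in types]},
            )
        )
    return LandscapeConfig(
        supersections=sss,
        n_conditions_per_supersection=n_conditions_per_supersection,
        seed=seed,
    )
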