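"""Pipeline orchestration and report generation.

``run_pipeline`` composes the whole analysis from files (or the bundled
demo scenario), writes per-project outcome tables, a program summary, the
ecosection diagnostic, and a run log recording seeds and every fallback or
floor event — the audit trail a program regulator would want.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from pydantic import BaseModel, Field

from . import inventory as _inventory
from .config import ProjectSimConfig, build_assessment_map
from .crediting import DEFAULT_PRICE
from .model import CreditingAnalysis
from .synthetic import (
    demo_landscape,
    generate_inventory,
    generate_projects,
    read_inventory_csv,
    read_projects_json,
    write_inventory_csv,
    write_projects_json,
)

logger = logging.getLogger("recredit")

__all__ = ["RunConfig", "run_pipeline", "write_assessment_map", "read_assessment_map"]

ASSESSMENT_MAP_SCHEMA = "recredit.assessment_map.v1"


def write_assessment_map(
    assessment_map: dict[tuple[str, str], str], path: str | Path
) -> None:
    payload = {
        "schema": ASSESSMENT_MAP_SCHEMA,
        "map": [
            {"supersection": ss, "forest_type": ft, "assessment_area": aa}
            for (ss, ft), aa in sorted(assessment_map.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_assessment_map(path: str | Path) -> dict[tuple[str, str], str]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != ASSESSMENT_MAP_SCHEMA:
        raise ValueError(f"unexpected assessment-map schema: {payload.get('schema')!r}")
    return {
        (e["supersection"], e["forest_type"]): e["assessment_area"]
        for e in payload["map"]
    }


class RunConfig(BaseModel):
    """Flat, declarative pipeline configuration with explicit seeds."""

    inventory_csv: str | None = None
    projects_json: str | None = None
    assessment_map_json: str | None = None
    output_dir: str = "recredit-output"
    price: float = Field(gt=0, default=DEFAULT_PRICE)
    n_draws: int = Field(ge=1, default=1000)
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)
    buffer_pool: float | None = None
    # demo mode: generate inputs instead of reading them
    demo: bool = False
    demo_n_projects: int = 40
    demo_adverse_selection: float = 2.0


def run_pipeline(config: RunConfig):
    """Run the full analysis, write the report bundle, and return the
    fitted :class:`~recredit.model.CreditingResults`.

    Files written to ``config.output_dir``:

    * ``outcomes.csv`` — per-project issued/recomputed credits, error, and
      error percentiles
    * ``project_error_table.csv`` — the same, sorted by median error
    * ``program_summary.json`` — net error, percent of analyzed credits,
      dollar value, CI bounds, optional buffer-pool depletion
    * ``ecosection_diagnostic.csv`` — per-ecosection common practice vs the
      supersection-wide value, per supersection
    * ``run.log`` — seeds, warnings, fallback and floor counters
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run config: %s", config.model_dump())
        if config.demo:
            land = demo_landscape(seed=config.seed)
            inv = generate_inventory(land)
            projects, _ = generate_projects(
                ProjectSimConfig(
                    n_projects=config.demo_n_projects,
                    adverse_selection_strength=config.demo_adverse_selection,
                    seed=config.seed,
                ),
                land,
                inv,
            )
            amap = build_assessment_map(land)
            write_inventory_csv(inv, outdir / "inventory.csv")
            write_projects_json(projects, outdir / "projects.json")
            write_assessment_map(amap, outdir / "assessment_map.json")
        else:
            if not (
                config.inventory_csv
                and config.projects_json
                and config.assessment_map_json
            ):
                raise ValueError(
                    "inventory_csv, projects_json and assessment_map_json are "
                    "required unless demo=True"
                )
            inv = read_inventory_csv(config.inventory_csv)
            projects = read_projects_json(config.projects_json)
            amap = read_assessment_map(config.assessment_map_json)

        analysis = CreditingAnalysis(inv, projects, amap, price=config.price)
        results = analysis.fit(
            n_draws=config.n_draws,
            seed=config.seed,
            percentiles=config.percentiles,
            buffer_pool=config.buffer_pool,
        )
        results.save(outdir)
        results.project_error_table().to_csv(
            outdir / "project_error_table.csv", index=False
        )

        diag_frames = []
        for ss in sorted(inv["supersection"].unique()):
            d = _inventory.ecosection_diagnostic(inv, ss)
            d.insert(0, "supersection", ss)
            diag_frames.append(d)
        import pandas as pd

        pd.concat(diag_frames, ignore_index=True).to_csv(
            outdir / "ecosection_diagnostic.csv", index=False
        )
        logger.info(
            "fallbacks=%d negative_cp_floored=%d",
            sum(m.fallback_count for m in results.classifier_models.values()),
            results.propagation.n_negative_cp_floored,
        )
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
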