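"""Model/Results facade over the full crediting-error analysis.

:class:`CreditingAnalysis` is built from an inventory-condition table and a
project portfolio; :meth:`CreditingAnalysis.fit` runs the whole chain —
regulator-style and species-specific common practice, per-supersection
classifier fits, common-practice rescaling, credit recomputation, and
Monte Carlo propagation of inventory uncertainty — and returns a
:class:`CreditingResults` carrying estimates, uncertainties, diagnostics
and a text ``summary()``.

Example
-------
>>> from recredit import synthetic, CreditingAnalysis
>>> land = synthetic.demo_landscape(seed=7)
>>> inv = synthetic.generate_inventory(land)
>>> projects, _ = synthetic.generate_projects(
...     synthetic.ProjectSimConfig(n_projects=40, adverse_selection_strength=2.0, seed=7),
...     land, inv)
>>> res = CreditingAnalysis.from_landscape(land, inv, projects).fit(seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as _classifier
from . import crediting as _crediting
from . import inventory as _inventory
from . import uncertainty as _uncertainty
from .config import LandscapeConfig, build_assessment_map
from .crediting import DEFAULT_PRICE, CreditingOutcome, ProjectRecord

logger = logging.getLogger("recredit")

__all__ = ["CreditingAnalysis", "CreditingResults"]


class CreditingAnalysis:
    """Crediting-error model for a portfolio of offset projects.

    Parameters
    ----------
    inventory : DataFrame
        Inventory-condition table (see ``recredit.inventory.REQUIRED_COLUMNS``).
    projects : sequence of ProjectRecord
    assessment_map : mapping (supersection, forest_type) -> assessment area
        Must cover every forest type in the inventory.
    price : $/tCO2e used to value crediting errors.
    radius_grid, n_folds : classifier hyperparameter search settings.
    """

    def __init__(
        self,
        inventory: pd.DataFrame,
        projects: Sequence[ProjectRecord],
        assessment_map: Mapping[tuple[str, str], str],
        price: float = DEFAULT_PRICE,
        radius_grid: Sequence[float] = _classifier.DEFAULT_RADIUS_GRID,
        n_folds: int = 5,
    ):
        _inventory.validate_conditions(inventory)
        if len(projects) == 0:
            raise ValueError("portfolio is empty")
        self.inventory = inventory
        self.projects = list(projects)
        self.assessment_map = dict(assessment_map)
        self.price = price
        self.radius_grid = tuple(radius_grid)
        self.n_folds = n_folds

    @classmethod
    def from_landscape(
        cls,
        landscape: LandscapeConfig,
        inventory: pd.DataFrame,
        projects: Sequence[ProjectRecord],
        **kwargs,
    ) -> "CreditingAnalysis":
        return cls(inventory, projects, build_assessment_map(landscape), **kwargs)

    @classmethod
    def from_files(
        cls, inventory_csv, projects_json, assessment_map_json, **kwargs
    ) -> "CreditingAnalysis":
        from .reporting import read_assessment_map
        from .synthetic import read_inventory_csv, read_projects_json

        return cls(
            read_inventory_csv(inventory_csv),
            read_projects_json(projects_json),
            read_assessment_map(assessment_map_json),
            **kwargs,
        )

    def fit(
        self,
        n_draws: int = 1000,
        seed: int = 0,
        percentiles: Sequence[float] = (5, 25, 50, 75, 95),
        total_analyzed_credits: float | None = None,
        buffer_pool: float | None = None,
        perturb_assessment_cp: bool = True,
    ) -> "CreditingResults":
        """Run the analysis chain and return results.

        ``seed`` controls classifier fold shuffling and the Monte Carlo
        streams.  ``total_analyzed_credits`` defaults to the portfolio's
        summed issuance.
        """
        carb_cp = _inventory.carb_common_practice(self.inventory, self.assessment_map)
        species_cp = _inventory.species_specific_common_practice(self.inventory)
        models = _classifier.fit_all_supersections(
            self.inventory, radius_grid=self.radius_grid, n_folds=self.n_folds, seed=seed
        )
        classifications = {
            p.project_id: _classifier.project_forest_types(models, p)
            for p in self.projects
        }
        mc = _uncertainty.MonteCarloConfig(
            n_draws=n_draws, seed=seed, percentiles=tuple(float(p) for p in percentiles)
        )
        prop = _uncertainty.propagate(
            self.projects,
            species_cp,
            self.assessment_map,
            classifications,
            mc,
            perturb_assessment_cp=perturb_assessment_cp,
        )
        _, issuance_r2 = _crediting.replicate_issuance(self.projects)
        total = (
            total_analyzed_credits
            if total_analyzed_credits is not None
            else float(sum(o.credits_issued for o in prop.outcomes))
        )
        program = _crediting.aggregate_program(
            prop.outcomes,
            total,
            price=self.price,
            error_draws=prop.program_error_draws,
            percentiles=[p for p in mc.percentiles],
        )
        if buffer_pool is not None:
            program["buffer_depletion_percent"] = _crediting.buffer_depletion(
                program["net_error_tco2e"], buffer_pool
            )
        return CreditingResults(
            model=self,
            outcomes=prop.outcomes,
            program=program,
            issuance_r2=issuance_r2,
            carb_cp=carb_cp,
            species_cp=species_cp,
            classifier_models=models,
            classifications=classifications,
            propagation=prop,
            mc_config=mc,
        )


@dataclass
class CreditingResults:
    """Fitted results: per-project crediting errors with Monte Carlo
    percentile summaries, program aggregates, and fit diagnostics."""

    model: CreditingAnalysis
    outcomes: list[CreditingOutcome]
    program: dict
    issuance_r2: float | None
    carb_cp: list[_inventory.CommonPracticeEstimate]
    species_cp: list[_inventory.CommonPracticeEstimate]
    classifier_models: dict[str, _classifier.RadiusNeighborsModel]
    classifications: dict[str, dict[str, dict[str, float]]]
    propagation: _uncertainty.PropagationResult
    mc_config: _uncertainty.MonteCarloConfig
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def classifier_scores(self) -> dict[str, float]:
        """Selected cross-validated weighted F1 per supersection."""
        return {ss: m.selected_score for ss, m in self.classifier_models.items()}

    @property
    def outcomes_frame(self) -> pd.DataFrame:
        """Per-project outcomes as a tidy DataFrame."""
        if self._frame is None:
            rows = []
            for o in self.outcomes:
                row = {
                    "project_id": o.project_id,
                    "credits_issued": o.credits_issued,
                    "credits_recomputed": o.credits_recomputed,
                    "crediting_error": o.crediting_error,
                    "error_percent": o.error_percent,
                    "scaled_common_practice": o.scaled_common_practice,
                }
                for p, v in o.percentiles.items():
                    row[f"error_p{p:g}"] = v
                for p, v in o.error_percent_percentiles.items():
                    row[f"error_percent_p{p:g}"] = v
                rows.append(row)
            object.__setattr__(self, "_frame", pd.DataFrame(rows))
        return self._frame

    def project_error_table(self) -> pd.DataFrame:
        """Per-project over/under-crediting table, sorted by median error
        percent, descending (most over-credited first)."""
        frame = self.outcomes_frame.copy()
        median_col = "error_percent_p50"
        if median_col not in frame.columns:
            raise ValueError("results lack a 50th percentile; refit with one")
        return frame.sort_values(median_col, ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        p = self.program
        lines = [
            "Crediting-error analysis",
            "=" * 64,
            f"projects analyzed            {p['n_projects']:>14d}",
            f"credits analyzed (tCO2e)     {p['total_analyzed_credits']:>14,.0f}",
            f"net crediting error (tCO2e)  {p['net_error_tco2e']:>14,.0f}",
            f"  percent of analyzed        {p['percent_of_analyzed']:>13.1f}%",
            f"  value at ${p['price']:.2f}/tCO2e    {p['dollar_value']:>14,.0f}",
        ]
        if "percentiles" in p:
            qs = p["percentiles"]["net_error_tco2e"]
            span = ", ".join(f"p{k:g}={v:,.0f}" for k, v in qs.items())
            lines.append(f"  Monte Carlo ({self.mc_config.n_draws} draws): {span}")
        if "buffer_depletion_percent" in p:
            lines.append(
                f"  buffer-pool depletion      {p['buffer_depletion_percent']:>13d}%"
            )
        if self.issuance_r2 is not None:
            lines.append(f"issuance replication R^2     {self.issuance_r2:>14.4f}")
        scores = self.classifier_scores
        lines.append(
            f"classifier weighted F1       {np.median(list(scores.values())):>14.3f}"
            " (median over supersections)"
        )
        over = sum(1 for o in self.outcomes if o.crediting_error > 0)
        lines.append(
            f"over-credited projects       {over:>14d} of {len(self.outcomes)}"
        )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_errors(self, ax=None):
        """Per-project error-percent medians with interquartile bars."""
        import matplotlib.pyplot as plt

        table = self.project_error_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        x = np.arange(len(table))
        lo = table.get("error_percent_p25", table["error_percent"])
        hi = table.get("error_percent_p75", table["error_percent"])
        ax.vlines(x, lo, hi, color="black", lw=1)
        ax.plot(x, table["error_percent_p50"], "o", color="seagreen", ms=4)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel("project (sorted by median error)")
        ax.set_ylabel("crediting error (% of issuance)")
        return ax

    def save(self, outdir: str | Path) -> None:
        """Write outcomes CSV and program-summary JSON to ``outdir``."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.outcomes_frame.to_csv(outdir / "outcomes.csv", index=False)
        program = dict(self.program)
        program["issuance_r2"] = self.issuance_r2
        program["classifier_scores"] = self.classifier_scores
        program["n_negative_cp_floored"] = self.propagation.n_negative_cp_floored
        (outdir / "program_summary.json").write_text(json.dumps(program, indent=2))
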