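"""Design-based estimation of average carbon density ("common practice").

Inventory conditions carry an acreage expansion factor: each measured
condition stands for ``expansion_acres`` acres of the population.  The
stratum mean density is therefore the ratio of expansion-weighted sums,

    CP = sum_i(carbon_density_i * expansion_acres_i) / sum_i(expansion_acres_i),

i.e. total carbon over total acreage, never a plain average of per-condition
densities.  The variance of this ratio is obtained with the standard
delta-method (Taylor linearisation) ratio-estimator formula, treating
conditions as independent sampling units:

    var(CP) = (1 / (n * xbar^2)) * sum_i (y_i - CP * x_i)^2 / (n - 1)

with x_i = expansion_acres_i, y_i = carbon_density_i * x_i and
xbar = mean(x).  Strata with a single condition get variance 0 (no
within-stratum variance is estimable) and a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("recredit")

__all__ = [
    "REQUIRED_COLUMNS",
    "CommonPracticeEstimate",
    "validate_conditions",
    "estimate_common_practice",
    "carb_common_practice",
    "species_specific_common_practice",
    "ecosection_diagnostic",
]

#: Columns every inventory-condition table must provide.
REQUIRED_COLUMNS = (
    "supersection",
    "ecosection",
    "forest_type",
    "species_fractions",
    "carbon_density",
    "expansion_acres",
)


@dataclass(frozen=True)
class CommonPracticeEstimate:
    """Average standing-live carbon density for one stratum.

    Attributes
    ----------
    stratum : tuple
        Stratum key, e.g. ``(supersection, assessment_area)`` or
        ``(supersection, forest_type)``.
    mean_density : float
        tCO2e/acre, ratio of expansion-weighted sums.
    variance : float
        Delta-method variance of ``mean_density``, (tCO2e/acre)^2.
    n_conditions : int
    total_acres : float
    """

    stratum: tuple
    mean_density: float
    variance: float
    n_conditions: int
    total_acres: float

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.variance))


def validate_conditions(conditions: pd.DataFrame) -> None:
    """Raise ValueError if the condition table violates its schema."""
    missing = [c for c in REQUIRED_COLUMNS if c not in conditions.columns]
    if missing:
        raise ValueError(f"condition table missing columns: {missing}")
    if len(conditions) == 0:
        return
    if (conditions["carbon_density"] < 0).any():
        raise ValueError("carbon_density must be >= 0")
    if (conditions["expansion_acres"] <= 0).any():
        raise ValueError("expansion_acres must be > 0")
    sums = conditions["species_fractions"].map(lambda d: sum(d.values()))
    if (np.abs(np.asarray(sums, dtype=float) - 1.0) > 1e-6).any():
        raise ValueError("species_fractions must sum to 1 within 1e-6")


def _ratio_estimate(group: pd.DataFrame, stratum: tuple) -> CommonPracticeEstimate:
    x = group["expansion_acres"].to_numpy(dtype=float)
    d = group["carbon_density"].to_numpy(dtype=float)
    y = d * x
    total_acres = float(x.sum())
    if total_acres <= 0:
        raise ValueError(f"zero total acreage in stratum {stratum}")
    mean_density = float(y.sum() / total_acres)
    n = len(group)
    if n == 1:
        logger.warning("stratum %s has a single condition; variance set to 0", stratum)
        variance = 0.0
    else:
        resid = y - mean_density * x
        xbar = x.mean()
        variance = float(resid @ resid / (n - 1) / (n * xbar**2))
    return CommonPracticeEstimate(
        stratum=stratum,
        mean_density=mean_density,
        variance=variance,
        n_conditions=n,
        total_acres=total_acres,
    )


def estimate_common_practice(
    conditions: pd.DataFrame,
    grouping: Sequence[str] | Callable[[pd.DataFrame], pd.Series],
) -> list[CommonPracticeEstimate]:
    """Estimate common practice per stratum.

    Parameters
    ----------
    conditions : DataFrame
        Inventory-condition table (see :data:`REQUIRED_COLUMNS`).
    grouping : list of column names, or callable
        Either columns to group by, or a callable mapping the table to a
        Series of stratum keys (tuples).

    Returns
    -------
    list of CommonPracticeEstimate, one per nonempty stratum, in sorted
    stratum order.  Empty strata are simply absent.
    """
    validate_conditions(conditions)
    if len(conditions) == 0:
        logger.warning("empty condition table: no estimates produced")
        return []
    if callable(grouping):
        keys = grouping(conditions)
        frame = conditions.assign(_stratum=keys)
        grouped = frame.groupby("_stratum", sort=True)
        return [
            _ratio_estimate(g, k if isinstance(k, tuple) else (k,))
            for k, g in grouped
        ]
    grouped = conditions.groupby(list(grouping), sort=True)
    out = []
    for key, g in grouped:
        stratum = key if isinstance(key, tuple) else (key,)
        out.append(_ratio_estimate(g, stratum))
    return out


def carb_common_practice(
    conditions: pd.DataFrame,
    assessment_map: Mapping[tuple[str, str], str],
) -> list[CommonPracticeEstimate]:
    """Regulator-style common practice: pooled across all forest types of an
    assessment area, supersection-wide.

    ``assessment_map`` maps ``(supersection, forest_type)`` to the assessment
    area the type belongs to; every type present in ``conditions`` must be
    covered.
    """
    validate_conditions(conditions)
    present = set(
        zip(conditions["supersection"], conditions["forest_type"], strict=True)
    )
    unmapped = sorted(k for k in present if k not in assessment_map)
    if unmapped:
        raise KeyError(
            "forest types missing from assessment_map: "
            + ", ".join(f"{ss}/{ft}" for ss, ft in unmapped)
        )

    def _key(frame: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [
                (ss, assessment_map[(ss, ft)])
                for ss, ft in zip(frame["supersection"], frame["forest_type"], strict=True)
            ],
            index=frame.index,
        )

    return estimate_common_practice(conditions, _key)


def species_specific_common_practice(
    conditions: pd.DataFrame,
) -> list[CommonPracticeEstimate]:
    """Common practice at (supersection, forest type) resolution."""
    return estimate_common_practice(conditions, ["supersection", "forest_type"])


def ecosection_diagnostic(
    conditions: pd.DataFrame,
    supersection: str,
    forest_types: str | Iterable[str] | None = None,
) -> pd.DataFrame:
    """Compare ecosection-level with supersection-wide common practice.

    Restricting to ``forest_types`` (a code, an iterable of codes, or None
    for all), computes for each ecosection e its common practice CP_e, the
    supersection-wide CP, and the distortion a parcel in e experiences from
    being compared against the supersection average:

        percent_change = 100 * (CP_super - CP_e) / CP_e

    Negative values flag ecosections denser than the regional average —
    the adverse-selection sweet spot.  CP_e = 0 yields a missing percent.
    """
    sub = conditions[conditions["supersection"] == supersection]
    if forest_types is not None:
        wanted = {forest_types} if isinstance(forest_types, str) else set(forest_types)
        sub = sub[sub["forest_type"].isin(wanted)]
    if len(sub) == 0:
        raise ValueError(
            f"no conditions for supersection {supersection!r} after filtering"
        )
    super_cp = estimate_common_practice(sub, lambda f: pd.Series(
        [(supersection,)] * len(f), index=f.index
    ))[0]
    rows = []
    for est in estimate_common_practice(sub, ["ecosection"]):
        cp_e = est.mean_density
        pct = 100.0 * (super_cp.mean_density - cp_e) / cp_e if cp_e > 0 else np.nan
        rows.append(
            {
                "ecosection": est.stratum[0],
                "cp_ecosection": cp_e,
                "cp_supersection": super_cp.mean_density,
                "percent_change": pct,
                "n_conditions": est.n_conditions,
            }
        )
    return pd.DataFrame(rows)
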