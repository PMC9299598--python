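"""Species-composition -> forest-type classification.

One classifier per supersection.  Training pairs come straight from the
inventory: the fractional-basal-area vector of each condition (embedded
over the union of species seen in that supersection) and its recorded
forest-type code.  Classification is a radius-neighbors vote: the
probability of type t is the share of training vectors with label t among
all training vectors within Euclidean distance ``radius`` of the query;
a query with no neighbors inside the radius falls back to its single
nearest neighbor with probability 1 (logged, so the fallback rate is
auditable).  The radius is selected by grid search with stratified
five-fold cross-validation, maximizing the class-support-weighted F1 score
of hard (argmax) predictions; ties go to the smallest radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .crediting import ProjectRecord

logger = logging.getLogger("recredit")

__all__ = [
    "DEFAULT_RADIUS_GRID",
    "RadiusNeighborsModel",
    "build_training_pairs",
    "fit_classifier",
    "fit_all_supersections",
    "classify",
    "project_forest_types",
]

#: 21 radii, geometrically spaced; compositions live on the simplex so
#: pairwise Euclidean distances are bounded by sqrt(2).
DEFAULT_RADIUS_GRID = tuple(np.geomspace(0.05, 1.5, 21))


@dataclass
class RadiusNeighborsModel:
    """Fitted per-supersection classifier."""

    supersection: str
    species_axes: list[str]
    radius: float
    training_vectors: np.ndarray
    training_labels: np.ndarray
    cv_radius_grid: list[float]
    selected_score: float
    cv_scores: dict[float, float] = field(default_factory=dict)
    fallback_count: int = 0  # queries resolved by nearest-neighbor fallback

    def to_dict(self) -> dict:
        return {
            "supersection": self.supersection,
            "species_axes": self.species_axes,
            "radius": self.radius,
            "training_vectors": self.training_vectors.tolist(),
            "training_labels": self.training_labels.tolist(),
            "cv_radius_grid": list(self.cv_radius_grid),
            "selected_score": self.selected_score,
            "cv_scores": {str(k): v for k, v in self.cv_scores.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadiusNeighborsModel":
        return cls(
            supersection=d["supersection"],
            species_axes=list(d["species_axes"]),
            radius=float(d["radius"]),
            training_vectors=np.asarray(d["training_vectors"], dtype=float),
            training_labels=np.asarray(d["training_labels"], dtype=object),
            cv_radius_grid=[float(r) for r in d["cv_radius_grid"]],
            selected_score=float(d["selected_score"]),
            cv_scores={float(k): float(v) for k, v in d.get("cv_scores", {}).items()},
        )


def build_training_pairs(
    conditions: pd.DataFrame, supersection: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Embed a supersection's conditions as vectors over its species union.

    Returns (vectors, labels, species_axes); species absent from a
    condition contribute 0.
    """
    sub = conditions[conditions["supersection"] == supersection]
    if len(sub) == 0:
        raise ValueError(f"no inventory conditions for supersection {supersection!r}")
    axes: set[str] = set()
    for fr in sub["species_fractions"]:
        axes.update(fr)
    species_axes = sorted(axes)
    index = {s: i for i, s in enumerate(species_axes)}
    vectors = np.zeros((len(sub), len(species_axes)))
    for row, fr in enumerate(sub["species_fractions"]):
        for s, f in fr.items():
            vectors[row, index[s]] = f
    labels = sub["forest_type"].to_numpy(dtype=object)
    return vectors, labels, species_axes


def _vote(
    vectors: np.ndarray,
    labels: np.ndarray,
    queries: np.ndarray,
    radius: float,
    classes: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Probability matrix (n_queries x n_classes) of radius votes; returns
    also the number of nearest-neighbor fallbacks."""
    nn = NearestNeighbors(radius=radius).fit(vectors)
    neighborhoods = nn.radius_neighbors(queries, return_distance=False)
    class_index = {c: j for j, c in enumerate(classes)}
    probs = np.zeros((len(queries), len(classes)))
    fallback_rows = [i for i, idx in enumerate(neighborhoods) if len(idx) == 0]
    for i, idx in enumerate(neighborhoods):
        if len(idx) == 0:
            continue
        for lab in labels[idx]:
            probs[i, class_index[lab]] += 1.0
        probs[i] /= len(idx)
    if fallback_rows:
        _, nearest = nn.kneighbors(queries[fallback_rows], n_neighbors=1)
        for i, j in zip(fallback_rows, nearest[:, 0], strict=True):
            probs[i, class_index[labels[j]]] = 1.0
    return probs, len(fallback_rows)


def fit_classifier(
    conditions: pd.DataFrame,
    supersection: str,
    radius_grid: tuple[float, ...] | list[float] = DEFAULT_RADIUS_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> RadiusNeighborsModel:
    """Fit the supersection's classifier, selecting the radius by CV.

    With a single forest type present, the degenerate model (that label with
    probability 1, score 1.0) is returned with a warning.
    """
    vectors, labels, axes = build_training_pairs(conditions, supersection)
    radius_grid = sorted(float(r) for r in radius_grid)
    classes = np.unique(labels)
    if len(classes) == 1:
        logger.warning(
            "supersection %s has a single forest type %r; trivial classifier",
            supersection,
            classes[0],
        )
        return RadiusNeighborsModel(
            supersection=supersection,
            species_axes=axes,
            radius=radius_grid[0],
            training_vectors=vectors,
            training_labels=labels,
            cv_radius_grid=list(radius_grid),
            selected_score=1.0,
        )
    if len(vectors) < n_folds:
        raise ValueError(
            f"supersection {supersection!r} has {len(vectors)} conditions; "
            f"need at least n_folds={n_folds}"
        )
    min_class = np.bincount(pd.factorize(labels)[0]).min()
    if min_class >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        logger.warning(
            "supersection %s: smallest class has %d members; folds not stratified",
            supersection,
            min_class,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)

    folds = list(splitter.split(vectors, labels))
    cv_scores: dict[float, float] = {}
    for radius in radius_grid:
        fold_scores = []
        for train_idx, test_idx in folds:
            probs, _ = _vote(
                vectors[train_idx], labels[train_idx], vectors[test_idx], radius, classes
            )
            pred = classes[np.argmax(probs, axis=1)]
            fold_scores.append(
                f1_score(labels[test_idx], pred, average="weighted", zero_division=0)
            )
        cv_scores[radius] = float(np.mean(fold_scores))
    best = max(cv_scores, key=lambda r: (cv_scores[r], -r))  # ties -> smallest radius
    return RadiusNeighborsModel(
        supersection=supersection,
        species_axes=axes,
        radius=best,
        training_vectors=vectors,
        training_labels=labels,
        cv_radius_grid=list(radius_grid),
        selected_score=cv_scores[best],
        cv_scores=cv_scores,
    )


def fit_all_supersections(
    conditions: pd.DataFrame,
    radius_grid: tuple[float, ...] | list[float] = DEFAULT_RADIUS_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, RadiusNeighborsModel]:
    return {
        ss: fit_classifier(conditions, ss, radius_grid=radius_grid, n_folds=n_folds, seed=seed)
        for ss in sorted(conditions["supersection"].unique())
    }


def classify(
    model: RadiusNeighborsModel, composition: dict[str, float]
) -> dict[str, float]:
    """Probability over forest-type codes for one species composition.

    Species the model never saw in training are dropped (logged) and the
    remainder renormalized; an empty composition after that is an error.
    """
    known = {s: f for s, f in composition.items() if s in model.species_axes}
    dropped = sorted(set(composition) - set(known))
    if dropped:
        logger.info(
            "supersection %s: dropping species unseen in training: %s",
            model.supersection,
            dropped,
        )
    total = sum(known.values())
    if total <= 0:
        raise ValueError(
            f"composition has no species known to supersection "
            f"{model.supersection!r} (dropped {dropped})"
        )
    query = np.zeros((1, len(model.species_axes)))
    for s, f in known.items():
        query[0, model.species_axes.index(s)] = f / total
    classes = np.unique(model.training_labels)
    if len(classes) == 1:
        return {str(classes[0]): 1.0}
    probs, n_fallback = _vote(
        model.training_vectors, model.training_labels, query, model.radius, classes
    )
    if n_fallback:
        model.fallback_count += n_fallback
        logger.info(
            "supersection %s: query outside every radius ball; nearest-neighbor fallback",
            model.supersection,
        )
    return {str(c): float(p) for c, p in zip(classes, probs[0], strict=True) if p > 0}


def project_forest_types(
    models: dict[str, RadiusNeighborsModel], project: ProjectRecord
) -> dict[str, dict[str, float]]:
    """Per-assessment-area forest-type distributions for one project.

    Projects reporting species only project-wide get the same composition
    applied uniformly to every assessment area.
    """
    if project.supersection not in models:
        raise KeyError(
            f"no classifier fitted for supersection {project.supersection!r}"
        )
    model = models[project.supersection]
    out: dict[str, dict[str, float]] = {}
    for share in project.assessment_areas:
        comp = share.species if share.species is not None else project.species_project_wide
        if comp is None:
            raise ValueError(
                f"{project.project_id}: no species composition for assessment "
                f"area {share.assessment_area!r} and none project-wide"
            )
        out[share.assessment_area] = classify(model, comp)
    return out
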