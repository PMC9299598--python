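"""Radius-neighbors forest-type classification."""

import numpy as np
import pandas as pd
import pytest

from recredit import (
    ProjectSimConfig,
    build_training_pairs,
    classify,
    fit_classifier,
    project_forest_types,
    synthetic,
)
from recredit.classifier import RadiusNeighborsModel, fit_all_supersections
from recredit.crediting import AssessmentAreaShare, ProjectRecord


def conditions_from(specs):
    """specs: (forest_type, species_fractions) within supersection 'S'."""
    return pd.DataFrame(
        [
            {
                "supersection": "S",
                "ecosection": "E",
                "forest_type": ft,
                "species_fractions": fr,
                "carbon_density": 100.0,
                "expansion_acres": 1.0,
            }
            for ft, fr in specs
        ]
    )


def make_model(specs, radius=0.5):
    vectors, labels, axes = build_training_pairs(conditions_from(specs), "S")
    return RadiusNeighborsModel(
        supersection="S",
        species_axes=axes,
        radius=radius,
        training_vectors=vectors,
        training_labels=labels,
        cv_radius_grid=[radius],
        selected_score=1.0,
    )


class TestTrainingPairs:
    def test_embedding_over_species_union(self):
        conds = conditions_from(
            [("T1", {"A": 0.6, "B": 0.4}), ("T2", {"C": 1.0})]
        )
        vectors, labels, axes = build_training_pairs(conds, "S")
        assert axes == ["A", "B", "C"]
        assert np.allclose(vectors[0], [0.6, 0.4, 0.0])
        assert np.allclose(vectors[1], [0.0, 0.0, 1.0])
        assert list(labels) == ["T1", "T2"]

    def test_disjoint_species_distance(self):
        conds = conditions_from(
            [("T1", {"A": 0.6, "B": 0.4}), ("T2", {"C": 0.7, "D": 0.3})]
        )
        vectors, _, _ = build_training_pairs(conds, "S")
        expected = np.sqrt(0.6**2 + 0.4**2 + 0.7**2 + 0.3**2)
        assert np.linalg.norm(vectors[0] - vectors[1]) == pytest.approx(expected)

    def test_empty_supersection_is_an_error(self):
        with pytest.raises(ValueError, match="NOPE"):
            build_training_pairs(conditions_from([("T", {"A": 1.0})]), "NOPE")


class TestFitClassifier:
    def test_single_label_trivial_model(self, caplog):
        conds = conditions_from([("T", {"A": 1.0})] * 6)
        with caplog.at_level("WARNING", logger="recredit"):
            model = fit_classifier(conds, "S", seed=0)
        assert model.selected_score == 1.0
        assert classify(model, {"A": 0.2, "B": 0.8}) == {"T": 1.0}

    def test_separable_types_reach_perfect_cv_score(self):
        land = synthetic.species_separable_landscape(
            seed=21, n_conditions_per_supersection=150, n_supersections=1
        )
        inv = synthetic.generate_inventory(land)
        model = fit_classifier(inv, "SS0", seed=21)
        assert model.selected_score == pytest.approx(1.0)

    def test_overlapping_types_score_below_one(self):
        land = synthetic.species_separable_landscape(
            seed=22, n_conditions_per_supersection=150, n_supersections=1
        )
        # force every type onto the same species with diffuse compositions
        for ft in land.supersections[0].forest_types:
            ft.species_centroid = {"SPX": 0.5, "SPY": 0.5}
            ft.dirichlet_concentration = 2.0
        inv = synthetic.generate_inventory(land)
        model = fit_classifier(inv, "SS0", seed=22)
        assert model.selected_score < 1.0

    def test_more_composition_overlap_never_helps(self):
        """Held-out F1 is nonincreasing as Dirichlet concentration shrinks
        (compositions get noisier and types blur together)."""
        scores = []
        for conc in (200.0, 5.0, 0.8):
            land = synthetic.species_separable_landscape(
                seed=23, n_conditions_per_supersection=120, n_supersections=1
            )
            for i, ft in enumerate(land.supersections[0].forest_types):
                ft.species_centroid = {
                    "SPX": 0.5 + 0.15 * (i - 1),
                    "SPY": 0.5 - 0.15 * (i - 1),
                }
                ft.dirichlet_concentration = conc
            inv = synthetic.generate_inventory(land)
            scores.append(fit_classifier(inv, "SS0", seed=23).selected_score)
        assert scores[0] >= scores[1] >= scores[2]

    def test_ties_break_toward_smaller_radius(self):
        conds = conditions_from(
            [("T1", {"A": 1.0})] * 5 + [("T2", {"B": 1.0})] * 5
        )
        model = fit_classifier(conds, "S", radius_grid=[0.1, 0.5, 1.0], seed=0)
        assert model.radius == 0.1  # every radius separates; smallest wins

    def test_too_few_conditions_rejected(self):
        conds = conditions_from([("T1", {"A": 1.0}), ("T2", {"B": 1.0})])
        with pytest.raises(ValueError, match="n_folds"):
            fit_classifier(conds, "S", n_folds=5, seed=0)


class TestClassify:
    def test_probabilities_sum_to_one(self, demo_inventory):
        models = fit_all_supersections(demo_inventory, seed=0)
        for model in models.values():
            probs = classify(model, {"PSME": 0.5, "NODE3": 0.5})
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= 0 for p in probs.values())

    def test_permutation_invariance_of_species_order(self, demo_inventory):
        models = fit_all_supersections(demo_inventory, seed=0)
        model = models["Cascades"]
        a = classify(model, {"PSME": 0.6, "NODE3": 0.3, "ABCO": 0.1})
        b = classify(model, {"ABCO": 0.1, "NODE3": 0.3, "PSME": 0.6})
        assert a == b

    def test_pure_neighborhood_gives_probability_one(self):
        model = make_model(
            [("T1", {"A": 1.0}), ("T1", {"A": 0.9, "B": 0.1}), ("T2", {"C": 1.0})],
            radius=0.3,
        )
        assert classify(model, {"A": 1.0}) == {"T1": 1.0}

    def test_equidistant_two_label_neighborhood_splits_evenly(self):
        model = make_model(
            [("T1", {"A": 1.0}), ("T2", {"B": 1.0})], radius=1.5
        )
        probs = classify(model, {"A": 0.5, "B": 0.5})
        assert probs == {"T1": 0.5, "T2": 0.5}

    def test_far_query_falls_back_to_nearest_neighbor(self):
        model = make_model(
            [("T1", {"A": 1.0}), ("T2", {"B": 1.0})], radius=0.05
        )
        probs = classify(model, {"A": 0.6, "B": 0.4})
        assert probs == {"T1": 1.0}
        assert model.fallback_count == 1

    def test_unknown_species_dropped_then_renormalized(self):
        model = make_model([("T1", {"A": 1.0}), ("T2", {"B": 1.0})], radius=0.5)
        probs = classify(model, {"A": 0.3, "ZZZ": 0.7})
        assert probs == {"T1": 1.0}

    def test_fully_unknown_composition_is_an_error(self):
        model = make_model([("T1", {"A": 1.0}), ("T2", {"B": 1.0})])
        with pytest.raises(ValueError, match="no species known"):
            classify(model, {"ZZZ": 1.0})


class TestProjectForestTypes:
    def project(self, report_level, areas, species_pw=None):
        return ProjectRecord(
            project_id="P",
            supersection="S",
            acreage=sum(a.acres for a in areas),
            assessment_areas=areas,
            initial_onsite_carbon=200.0 * sum(a.acres for a in areas),
            baseline_avg_onsite_density=100.0,
            species_project_wide=species_pw,
            species_report_level=report_level,
        )

    def test_per_area_species_gives_one_result_per_area(self):
        models = {"S": make_model([("T1", {"A": 1.0}), ("T2", {"B": 1.0})])}
        areas = [
            AssessmentAreaShare(
                assessment_area="AA1", acres=10, reported_common_practice=100,
                species={"A": 1.0},
            )
        ]
        out = project_forest_types(models, self.project("per-assessment-area", areas))
        assert out == {"AA1": {"T1": 1.0}}

    def test_project_wide_species_applied_uniformly(self):
        """Projects that report species only project-wide get the same
        composition — hence identical classifications — in every area."""
        models = {"S": make_model([("T1", {"A": 1.0}), ("T2", {"B": 1.0})])}
        areas = [
            AssessmentAreaShare(assessment_area=n, acres=10, reported_common_practice=100)
            for n in ("AA1", "AA2")
        ]
        out = project_forest_types(
            models,
            self.project("project-wide", areas, species_pw={"A": 1.0}),
        )
        assert out["AA1"] == out["AA2"] == {"T1": 1.0}

    def test_missing_supersection_model_is_an_error(self):
        with pytest.raises(KeyError, match="S"):
            project_forest_types(
                {},
                self.project(
                    "project-wide",
                    [
                        AssessmentAreaShare(
                            assessment_area="AA1", acres=10, reported_common_practice=100
                        )
                    ],
                    species_pw={"A": 1.0},
                ),
            )


def test_model_json_roundtrip(demo_inventory):
    model = fit_all_supersections(demo_inventory, seed=0)["Cascades"]
    back = RadiusNeighborsModel.from_dict(model.to_dict())
    assert back.radius == model.radius
    assert back.species_axes == model.species_axes
    q = {"PSME": 0.7, "ABCO": 0.3}
    assert classify(back, q) == classify(model, q)


def test_median_f1_on_separable_landscapes():
    """On well-separated synthetic landscapes the median selected weighted F1
    across supersections should be >= 0.9."""
    land = synthetic.species_separable_landscape(
        seed=31, n_conditions_per_supersection=150, n_supersections=3
    )
    inv = synthetic.generate_inventory(land)
    models = fit_all_supersections(inv, seed=31)
    assert np.median([m.selected_score for m in models.values()]) >= 0.9
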