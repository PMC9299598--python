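"""Issuance arithmetic, common-practice rescaling, and portfolio aggregation."""

import numpy as np
import pytest

from recredit import (
    AssessmentAreaShare,
    ProjectRecord,
    aggregate_program,
    buffer_depletion,
    compute_upfront_credits,
    recompute_credits,
    replicate_issuance,
    scale_common_practice,
)


def make_project(
    initial_density=170.0,
    acreage=1000.0,
    baseline_density=130.0,
    reported_cp=130.0,
    secondary_effects=-5000.0,
    confidence_deduction=0.05,
    wood_products_project=0.0,
    wood_products_baseline=0.0,
    areas=None,
    **kwargs,
):
    if areas is None:
        areas = [
            AssessmentAreaShare(
                assessment_area="AA",
                acres=acreage,
                reported_common_practice=reported_cp,
                species={"A": 1.0},
            )
        ]
    return ProjectRecord(
        project_id=kwargs.pop("project_id", "P1"),
        supersection="S",
        acreage=acreage,
        assessment_areas=areas,
        initial_onsite_carbon=initial_density * acreage,
        wood_products_project=wood_products_project,
        wood_products_baseline=wood_products_baseline,
        baseline_avg_onsite_density=baseline_density,
        secondary_effects=secondary_effects,
        confidence_deduction=confidence_deduction,
        **kwargs,
    )


class TestComputeUpfrontCredits:
    def test_no_carbon_delta_means_no_credits(self):
        p = make_project(
            initial_density=130.0,
            baseline_density=130.0,
            reported_cp=130.0,
            secondary_effects=0.0,
            confidence_deduction=0.0,
        )
        assert compute_upfront_credits(p) == 0.0

    def test_hand_computed_issuance(self):
        # (170 - 130) * 1000 - 5000, then a 5% confidence deduction
        p = make_project()
        assert compute_upfront_credits(p) == pytest.approx(33_250.0)

    def test_wood_products_enter_both_scenarios(self):
        p = make_project(
            secondary_effects=0.0,
            confidence_deduction=0.0,
            wood_products_project=2_000.0,
            wood_products_baseline=500.0,
        )
        assert compute_upfront_credits(p) == pytest.approx(40_000.0 + 1_500.0)

    def test_negative_gross_floors_at_zero(self):
        p = make_project(
            initial_density=131.0, secondary_effects=-5_000.0, confidence_deduction=0.0
        )
        assert compute_upfront_credits(p) == 0.0


class TestReplicateIssuance:
    def test_synthetic_portfolio_replicates_exactly(self, demo_portfolio):
        projects, _ = demo_portfolio
        pairs, r2 = replicate_issuance(projects)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        for _, computed, recorded in pairs:
            assert computed == pytest.approx(recorded)

    def test_perturbed_record_drops_r2(self, demo_portfolio):
        projects, _ = demo_portfolio
        perturbed = [p.model_copy(deep=True) for p in projects]
        perturbed[0].credits_issued = perturbed[0].credits_issued * 1.5 + 10_000
        _, r2 = replicate_issuance(perturbed)
        assert r2 is not None and r2 < 1.0

    def test_constant_recorded_credits_undefined(self):
        projects = [
            make_project(project_id=f"P{i}", credits_issued=100.0) for i in range(3)
        ]
        _, r2 = replicate_issuance(projects)
        assert r2 is None

    def test_fewer_than_two_projects_undefined(self):
        _, r2 = replicate_issuance([make_project(credits_issued=5.0)])
        assert r2 is None


class TestScaleCommonPractice:
    def test_identity_when_alt_equals_recomputed(self):
        p = make_project(reported_cp=100.0, baseline_density=100.0)
        assert scale_common_practice(p, {"AA": 87.3}, {"AA": 87.3}) == pytest.approx(100.0)

    def test_single_area_ratio(self):
        p = make_project(reported_cp=100.0, baseline_density=100.0)
        assert scale_common_practice(p, {"AA": 120.0}, {"AA": 100.0}) == pytest.approx(120.0)

    def test_two_area_weighted_ratio(self):
        areas = [
            AssessmentAreaShare(
                assessment_area="A1", acres=250.0, reported_common_practice=100.0
            ),
            AssessmentAreaShare(
                assessment_area="A2", acres=750.0, reported_common_practice=100.0
            ),
        ]
        p = make_project(
            acreage=1000.0, baseline_density=100.0, reported_cp=100.0, areas=areas
        )
        # 100 * (0.25 * 0.9 + 0.75 * 1.1) = 105
        scaled = scale_common_practice(
            p, {"A1": 90.0, "A2": 110.0}, {"A1": 100.0, "A2": 100.0}
        )
        assert scaled == pytest.approx(105.0)

    def test_zero_recomputed_cp_is_an_error(self):
        p = make_project(reported_cp=100.0, baseline_density=100.0)
        with pytest.raises(ValueError, match="undefined"):
            scale_common_practice(p, {"AA": 90.0}, {"AA": 0.0})

    def test_missing_area_is_an_error(self):
        p = make_project()
        with pytest.raises(KeyError, match="AA"):
            scale_common_practice(p, {}, {"AA": 100.0})


class TestRecomputeCredits:
    def clean_project(self, **kw):
        kw.setdefault("secondary_effects", 0.0)
        kw.setdefault("confidence_deduction", 0.0)
        return make_project(**kw)

    def test_unchanged_constraint_reproduces_issuance(self):
        p = self.clean_project(baseline_density=100.0, reported_cp=100.0)
        p.credits_issued = compute_upfront_credits(p)
        recomputed, _ = recompute_credits(p, 100.0)
        assert recomputed == pytest.approx(p.credits_issued)

    def test_higher_constraint_reduces_credits_linearly(self):
        # baseline at CP=100, rescaled CP 110, 1000 acres -> 10,000 fewer credits
        p = self.clean_project(baseline_density=100.0, reported_cp=100.0)
        issued = compute_upfront_credits(p)
        recomputed, new_baseline = recompute_credits(p, 110.0)
        assert new_baseline == pytest.approx(110.0)
        assert issued - recomputed == pytest.approx(10_000.0)

    def test_constraint_above_initial_density_zeroes_credits(self):
        """When the corrected common practice exceeds what the project
        measured on site, it would have earned nothing: 100% over-credited."""
        p = self.clean_project(
            initial_density=170.0, baseline_density=100.0, reported_cp=100.0
        )
        issued = compute_upfront_credits(p)
        recomputed, _ = recompute_credits(p, 180.0)
        assert recomputed == 0.0
        assert 100.0 * (issued - recomputed) / issued == pytest.approx(100.0)

    def test_baseline_margin_is_preserved(self):
        p = self.clean_project(baseline_density=108.0, reported_cp=100.0)
        _, new_baseline = recompute_credits(p, 120.0)
        assert new_baseline == pytest.approx(128.0)

    def test_negative_scaled_cp_floored(self, caplog):
        p = self.clean_project(baseline_density=100.0, reported_cp=100.0)
        with caplog.at_level("WARNING", logger="recredit"):
            _, new_baseline = recompute_credits(p, -5.0)
        assert new_baseline == 0.0

    def test_doubling_acreage_doubles_error_exactly(self):
        for scaled_cp in (90.0, 110.0, 150.0):
            p1 = self.clean_project(acreage=1000.0, baseline_density=100.0, reported_cp=100.0)
            p2 = self.clean_project(acreage=2000.0, baseline_density=100.0, reported_cp=100.0)
            e1 = compute_upfront_credits(p1) - recompute_credits(p1, scaled_cp)[0]
            e2 = compute_upfront_credits(p2) - recompute_credits(p2, scaled_cp)[0]
            assert e2 == pytest.approx(2.0 * e1)

    def test_lower_constraint_means_under_crediting(self):
        """A species-specific common practice below the assessment-area value
        yields a negative error (the project could have claimed more)."""
        p = self.clean_project(baseline_density=100.0, reported_cp=100.0)
        issued = compute_upfront_credits(p)
        recomputed, _ = recompute_credits(p, 85.0)
        assert issued - recomputed < 0


class TestAggregateProgram:
    def test_headline_arithmetic(self):
        summary = aggregate_program([30.0e6], total_analyzed_credits=102.1e6, price=13.67)
        assert round(summary["percent_of_analyzed"], 1) == 29.4
        assert round(summary["dollar_value"] / 1e6) == 410

    def test_percentiles_are_of_totals(self):
        draws = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        summary = aggregate_program(
            [2.0], 10.0, error_draws=draws, percentiles=(50,)
        )
        assert summary["percentiles"]["net_error_tco2e"][50] == pytest.approx(3.0)

    def test_empty_portfolio(self):
        summary = aggregate_program([], 10.0)
        assert summary["net_error_tco2e"] == 0.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            aggregate_program([1.0], 0.0)


class TestBufferDepletion:
    def test_reported_depletion_ratio(self):
        assert buffer_depletion(20.5e6, 24.6e6) == 83

    def test_zero_error(self):
        assert buffer_depletion(0.0, 1.0) == 0

    def test_full_depletion(self):
        assert buffer_depletion(5.0, 5.0) == 100

    def test_nonpositive_pool_rejected(self):
        with pytest.raises(ValueError):
            buffer_depletion(1.0, 0.0)


class TestProjectRecordInvariants:
    def test_baseline_below_common_practice_rejected(self):
        with pytest.raises(ValueError, match="protocol constraint"):
            make_project(baseline_density=90.0, reported_cp=100.0)

    def test_area_acres_must_sum_to_acreage(self):
        with pytest.raises(ValueError, match="sum to project acreage"):
            make_project(
                areas=[
                    AssessmentAreaShare(
                        assessment_area="AA", acres=10.0, reported_common_practice=1.0
                    )
                ]
            )
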