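"""Weighted percentiles, scenario summaries, intervention comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskmx as rx
from riskmx.population_risk import DistributionError
from riskmx.scenarios_io import random_scenario

from conftest import boundary_gap, expanded_percentile


class TestValidateDistribution:
    def test_published_row_accepted_and_renormalised(self):
        # calcium-absent maternal row: printed values sum to 100.4
        dist = rx.validate_distribution((28, 53, 15, 4.3, 0.1), tolerance=0.5)
        assert dist.raw_sum == pytest.approx(100.4)
        assert sum(dist.weights) == pytest.approx(100.0, abs=1e-12)
        assert dist.raw_weights == (28, 53, 15, 4.3, 0.1)

    def test_exact_row_kept_unchanged(self):
        dist = rx.validate_distribution((20, 20, 20, 20, 20))
        assert dist.weights == (20, 20, 20, 20, 20)

    @pytest.mark.parametrize(
        ("weights", "match"),
        [
            ((50, 50, 50, 0, 0), "150"),
            ((20, 20, 20, 20, 19), "99"),
            ((30, 30, 30, -1, 11), "non-negative"),
            ((50, 50), "5 impact weights"),
        ],
    )
    def test_invalid_rows_rejected_with_diagnostic(self, weights, match):
        with pytest.raises(DistributionError, match=match):
            rx.validate_distribution(weights, tolerance=0.5)


class TestWeightedQuantile:
    def test_calcium_absent_published_percentiles(self, calcium_absent):
        assert rx.weighted_quantile(calcium_absent, 50) == 8
        assert rx.weighted_quantile(calcium_absent, 95) == 12
        assert rx.weighted_quantile(calcium_absent, 5) == 4

    def test_degenerate_distribution_pins_to_first_level(self):
        for band in (1, 3, 5):
            s = rx.Scenario.from_weights("deg", {1: 0.05, 3: 2, 5: 50}[band],
                                         (100, 0, 0, 0, 0))
            assert s.band.index == band
            for q in (1, 5, 50, 95, 99):
                assert rx.weighted_quantile(s, q) == band

    @pytest.mark.parametrize("q", [0, 100, -5, 105])
    def test_percentile_domain_enforced(self, calcium_absent, q):
        with pytest.raises(rx.RiskMatrixError):
            rx.weighted_quantile(calcium_absent, q)

    def test_exact_cumulative_boundary_selects_lower_level(self):
        # cumulative weight hits 50 exactly at level 1: >=q rule keeps level 1
        s = rx.Scenario.from_weights("bnd", 50, (50, 30, 20, 0, 0))
        assert rx.weighted_quantile(s, 50) == 5 * 1
        assert rx.weighted_quantile(s, 50.001) == 5 * 2

    def test_agrees_with_expansion_oracle_on_random_scenarios(self):
        """200 Dirichlet-random scenarios vs the nearest-rank percentile of
        a 100k-individual expansion; exact away from cumulative-weight
        boundaries."""
        checked = 0
        for seed in range(200):
            s = random_scenario(seed=seed)
            for q in (5.0, 25.0, 50.0, 75.0, 95.0):
                if boundary_gap(s, q) < 0.01:
                    continue
                assert rx.weighted_quantile(s, q) == expanded_percentile(s, q), (
                    f"seed {seed}, q {q}"
                )
                checked += 1
        assert checked > 900

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_percentile_monotone_in_q(self, seed):
        s = random_scenario(seed=seed)
        qs = np.linspace(1, 99, 25)
        vals = [rx.weighted_quantile(s, q) for q in qs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert all(v % s.band.index == 0 for v in vals)


class TestPopulationRiskSummary:
    @pytest.mark.parametrize(
        ("name", "triplet", "tail"),
        [
            ("calcium-absent", (4, 8, 12), 4.4),
            ("calcium-present", (3, 6, 9), 3.42),
            ("sga-p10", (4, 8, 12), 0.9),
            ("sga-p5", (3, 6, 9), 4.0),
        ],
    )
    def test_published_triplets_and_tails(self, fixtures_by_name, name, triplet, tail):
        summary = rx.population_risk_summary(fixtures_by_name[name])
        assert (summary.p5, summary.p50, summary.p95) == triplet
        assert summary.tail_pct == pytest.approx(tail)
        assert summary.p50_category.name == "moderate"

    def test_percentiles_ordered_and_multiples_of_band(self):
        for seed in range(50):
            s = random_scenario(seed=seed)
            sm = rx.population_risk_summary(s)
            assert sm.p5 <= sm.p50 <= sm.p95
            assert {sm.p5 % s.band.index, sm.p50 % s.band.index,
                    sm.p95 % s.band.index} == {0}


class TestCompare:
    def test_calcium_transitions_match_narrative(self, calcium_absent, calcium_present):
        cmp_ = rx.compare(calcium_absent, calcium_present)
        by_level = {t.impact_index: t for t in cmp_.per_impact_transitions}
        assert len(cmp_.per_impact_transitions) == 5
        # disability: very high (orange) -> high (yellow)
        assert by_level[4].before.color_label == "orange"
        assert by_level[4].after.color_label == "yellow"
        # death: extreme (red) -> very high (orange)
        assert by_level[5].before.color_label == "red"
        assert by_level[5].after.color_label == "orange"
        # the p50 category itself does not move: moderate -> moderate
        assert cmp_.category_rank_reduction == 0
        assert cmp_.p50_delta == -2

    def test_self_comparison_is_null(self, sga_p10):
        cmp_ = rx.compare(sga_p10, sga_p10)
        assert cmp_.p50_delta == 0
        assert cmp_.category_rank_reduction == 0
        assert all(t.before == t.after for t in cmp_.per_impact_transitions)

    def test_antisymmetric_p50_delta(self, calcium_absent, calcium_present, sga_p10, sga_p5):
        for a, b in [(calcium_absent, calcium_present), (sga_p10, sga_p5)]:
            assert rx.compare(a, b).p50_delta == -rx.compare(b, a).p50_delta

    def test_mismatched_impact_labels_rejected(self, calcium_absent):
        other_geom = rx.MatrixGeometry(
            impact_levels=tuple(
                rx.ImpactLevel(i, f"grade-{i}") for i in range(1, 6)
            )
        )
        other = rx.Scenario.from_weights("other", 6.5, (28, 53, 15, 4.3, 0.1),
                                         geometry=other_geom)
        with pytest.raises(rx.RiskMatrixError, match="labels"):
            rx.compare(calcium_absent, other)


class TestReductionThreshold:
    def test_calcium_fails_non_invasive_threshold(self, calcium_absent, calcium_present):
        cmp_ = rx.compare(calcium_absent, calcium_present)
        decision = rx.meets_reduction_threshold(cmp_, "non-invasive")
        assert decision.required == 2
        assert decision.achieved == 0
        assert not decision.met
        assert decision.risk_scope == "population"

    @pytest.mark.parametrize(
        ("base_weights", "base_p", "int_weights", "int_p", "invasiveness", "met"),
        [
            # extreme (5x5=25) -> high (3x3=9): two ranks, very-invasive needs three
            ((0, 0, 0, 0, 100), 50, (0, 0, 100, 0, 0), 2, "very-invasive", False),
            # extreme (25) -> moderate (3x2=6): three ranks
            ((0, 0, 0, 0, 100), 50, (0, 100, 0, 0, 0), 2, "very-invasive", True),
            # extreme (25) -> high (9): two ranks suffice for moderate-invasive
            ((0, 0, 0, 0, 100), 50, (0, 0, 100, 0, 0), 2, "moderate-invasive", True),
        ],
    )
    def test_rank_arithmetic(self, base_weights, base_p, int_weights, int_p,
                             invasiveness, met):
        base = rx.Scenario.from_weights("b", base_p, base_weights)
        inter = rx.Scenario.from_weights("i", int_p, int_weights)
        decision = rx.meets_reduction_threshold(rx.compare(base, inter), invasiveness)
        assert decision.met is met

    def test_unknown_invasiveness_rejected(self, calcium_absent):
        cmp_ = rx.compare(calcium_absent, calcium_absent)
        with pytest.raises(rx.RiskMatrixError, match="invasiveness"):
            rx.meets_reduction_threshold(cmp_, "slightly-invasive")
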