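"""Population-level risk summaries over a matrix row.

A scenario couples an event probability (hence a probability band) with an
impact distribution: the percentages of the affected population ending up
at each of the five impact levels.  The population risk is summarised by
weighted percentiles (p5, p50, p95) of the risk score, the tail
probability of severe outcomes (disability + death), and baseline vs
intervention comparisons judged against invasiveness-dependent
risk-category reduction thresholds.

Conventions
-----------
* Weights are percentages.  Rows may miss 100 % by a small rounding slack
  (published rows sum to 100.4); within tolerance they are renormalised to
  exactly 100 before any quantile arithmetic.
* The weighted q-th percentile of the risk score is the score of the
  *smallest* impact index whose cumulative (renormalised) weight,
  accumulated from least to most severe, reaches at least q.
* The severe-outcome tail is reported on the *raw* weights so that printed
  sums (0.3 + 0.6 = 0.9) are matched digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .matrix_core import (
    DEFAULT_GEOMETRY,
    MatrixGeometry,
    ProbabilityBand,
    RiskCategory,
    RiskMatrixError,
)

#: slack allowed on a row sum, in percentage points
DEFAULT_ROW_SUM_TOLERANCE = 0.5

Invasiveness = Literal["non-invasive", "moderate-invasive", "very-invasive"]

#: risk-category reduction demanded of an intervention, by invasiveness class
REQUIRED_CATEGORY_REDUCTION: dict[str, int] = {
    "non-invasive": 2,
    "moderate-invasive": 2,
    "very-invasive": 3,
}

#: whose risk the professionals expect the intervention to reduce
RISK_SCOPE: dict[str, str] = {
    "non-invasive": "population",
    "moderate-invasive": "highest-risk group",
    "very-invasive": "highest-risk group",
}


class DistributionError(RiskMatrixError):
    """Raised when an impact distribution fails validation."""


@dataclass(frozen=True)
class ImpactDistribution:
    """Validated five-level impact distribution (percent of affected).

    ``weights`` are renormalised to sum exactly 100; ``raw_weights`` keep
    the values as supplied, for audit and for tail probabilities.
    """

    weights: tuple[float, float, float, float, float]
    raw_weights: tuple[float, float, float, float, float]

    @property
    def raw_sum(self) -> float:
        return float(sum(self.raw_weights))


def validate_distribution(
    raw_weights: Sequence[float],
    tolerance: float = DEFAULT_ROW_SUM_TOLERANCE,
) -> ImpactDistribution:
    """Validate and renormalise a five-level impact row.

    Parameters
    ----------
    raw_weights
        Five non-negative percentages, one per impact level, least to most
        severe.  Their sum must lie within ``tolerance`` of 100.
    tolerance
        Allowed deviation of the row sum from 100, in percentage points.

    Raises
    ------
    DistributionError
        On a wrong number of weights, a negative weight, or a row sum
        outside tolerance (the offending sum is reported).
    """
    w = [float(x) for x in raw_weights]
    if len(w) != 5:
        raise DistributionError(f"expected 5 impact weights, got {len(w)}")
    if any(x < 0 for x in w):
        raise DistributionError(f"impact weights must be non-negative, got {w}")
    total = sum(w)
    if abs(total - 100.0) > tolerance:
        raise DistributionError(
            f"impact weights sum to {total:g}, outside 100 +/- {tolerance:g}"
        )
    norm = tuple(x * 100.0 / total for x in w)
    return ImpactDistribution(weights=norm, raw_weights=tuple(w))


@dataclass(frozen=True)
class Scenario:
    """A named clinical situation on the risk matrix.

    The probability band is derived from the event probability at
    construction and always consistent with it.
    """

    name: str
    event_probability: float
    distribution: ImpactDistribution
    geometry: MatrixGeometry = DEFAULT_GEOMETRY
    band: ProbabilityBand = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "band",
            self.geometry.assign_probability_band(self.event_probability),
        )

    @classmethod
    def from_weights(
        cls,
        name: str,
        event_probability: float,
        raw_weights: Sequence[float],
        tolerance: float = DEFAULT_ROW_SUM_TOLERANCE,
        geometry: MatrixGeometry = DEFAULT_GEOMETRY,
    ) -> "Scenario":
        """Build a scenario from raw percentages, validating the row."""
        return cls(
            name=name,
            event_probability=float(event_probability),
            distribution=validate_distribution(raw_weights, tolerance),
            geometry=geometry,
        )


@dataclass(frozen=True)
class PopulationRiskSummary:
    """Weighted percentile summary of a scenario's population risk."""

    p5: int
    p50: int
    p95: int
    p50_category: RiskCategory
    tail_pct: float


@dataclass(frozen=True)
class CategoryTransition:
    """Per-impact-level category change from baseline to intervention."""

    impact_index: int
    impact_label: str
    before: RiskCategory
    after: RiskCategory


@dataclass(frozen=True)
class InterventionComparison:
    """Baseline vs intervention scenario on the same impact scale."""

    baseline: Scenario
    intervention: Scenario
    baseline_summary: PopulationRiskSummary
    intervention_summary: PopulationRiskSummary
    p50_delta: int
    category_rank_reduction: int
    per_impact_transitions: tuple[CategoryTransition, ...]
    tail_delta_pct: float


@dataclass(frozen=True)
class ThresholdDecision:
    """Outcome of checking a comparison against its invasiveness threshold."""

    invasiveness: str
    required: int
    achieved: int
    met: bool
    risk_scope: str


def weighted_quantile(scenario: Scenario, q: float) -> int:
    """Weighted q-th percentile of the risk score over a scenario's row.

    Returns ``risk_score(band, j*)`` where ``j*`` is the smallest impact
    index whose cumulative renormalised weight (accumulated from least to
    most severe) is at least ``q``.

    Parameters
    ----------
    scenario
        A validated scenario.
    q
        Percentile in the open interval (0, 100).
    """
    if not 0 < q < 100:
        raise RiskMatrixError(f"percentile must be in (0, 100), got {q}")
    cum = np.cumsum(scenario.distribution.weights)
    # tiny negative slack so q landing on an exact boundary selects that level
    j = int(np.searchsorted(cum, q - 1e-9)) + 1
    j = min(j, 5)
    return scenario.geometry.risk_score(scenario.band.index, j)


def population_risk_summary(scenario: Scenario) -> PopulationRiskSummary:
    """Summarise a scenario: p5/p50/p95 scores, median category, severe tail.

    The tail is the raw-weight mass at impact levels 4 and 5 (disability
    plus death), before renormalisation, matching published arithmetic.
    """
    p5 = weighted_quantile(scenario, 5)
    p50 = weighted_quantile(scenario, 50)
    p95 = weighted_quantile(scenario, 95)
    tail = scenario.distribution.raw_weights[3] + scenario.distribution.raw_weights[4]
    return PopulationRiskSummary(
        p5=p5,
        p50=p50,
        p95=p95,
        p50_category=scenario.geometry.risk_category(p50),
        tail_pct=tail,
    )


def compare(baseline: Scenario, intervention: Scenario) -> InterventionComparison:
    """Compare an intervention scenario against its baseline.

    Both scenarios must share the same impact-level labels (the comparison
    is per matrix column).  Reports the p50 shift, the reduction in the
    p50 category's rank, per-impact-level category transitions, and the
    change in the severe-outcome tail.
    """
    labels_b = [l.role_label for l in baseline.geometry.impact_levels]
    labels_i = [l.role_label for l in intervention.geometry.impact_levels]
    if labels_b != labels_i:
        raise RiskMatrixError(
            "baseline and intervention use different impact-level labels"
        )
    sb = population_risk_summary(baseline)
    si = population_risk_summary(intervention)
    transitions = tuple(
        CategoryTransition(
            impact_index=lvl.index,
            impact_label=lvl.role_label,
            before=baseline.geometry.risk_category(
                baseline.geometry.risk_score(baseline.band.index, lvl.index)
            ),
            after=intervention.geometry.risk_category(
                intervention.geometry.risk_score(intervention.band.index, lvl.index)
            ),
        )
        for lvl in baseline.geometry.impact_levels
    )
    return InterventionComparison(
        baseline=baseline,
        intervention=intervention,
        baseline_summary=sb,
        intervention_summary=si,
        p50_delta=si.p50 - sb.p50,
        category_rank_reduction=sb.p50_category.rank - si.p50_category.rank,
        per_impact_transitions=transitions,
        tail_delta_pct=si.tail_pct - sb.tail_pct,
    )


def meets_reduction_threshold(
    comparison: InterventionComparison, invasiveness: str
) -> ThresholdDecision:
    """Judge an intervention against its invasiveness-dependent threshold.

    Professionals expect non- and moderate-invasive interventions to lower
    the risk by two categories and very-invasive interventions by three.
    The achieved reduction is measured on the p50 cell's category rank.
    The population vs highest-risk-group scope of each expectation is
    carried as metadata on the decision; no quantitative subgroup model is
    implied.
    """
    if invasiveness not in REQUIRED_CATEGORY_REDUCTION:
        raise RiskMatrixError(
            f"unknown invasiveness class {invasiveness!r}; "
            f"expected one of {sorted(REQUIRED_CATEGORY_REDUCTION)}"
        )
    required = REQUIRED_CATEGORY_REDUCTION[invasiveness]
    achieved = comparison.category_rank_reduction
    return ThresholdDecision(
        invasiveness=invasiveness,
        required=required,
        achieved=achieved,
        met=achieved >= required,
        risk_scope=RISK_SCOPE[invasiveness],
    )
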