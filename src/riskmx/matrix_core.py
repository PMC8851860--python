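"""Geometry of the 5x5 clinical risk matrix.

The matrix crosses five ordinal probability bands (rows; ``rare`` < 0.1 %
up to ``very likely`` > 10 %) against five ordinal impact levels (columns;
managed in primary care up to death).  A cell's risk score is the product
of the two ordinal indices, an integer in 1..25, which maps onto five named
risk categories with conventional traffic-light colour labels.

Probabilities and cell weights are expressed in *percent* throughout the
package (6.5 means 6.5 %), matching how clinical incidences are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


class RiskMatrixError(ValueError):
    """Domain error for out-of-range probabilities, indices or scores."""


@dataclass(frozen=True)
class ProbabilityBand:
    """One matrix row: an ordinal likelihood category.

    Bounds are percentages.  The interval convention is half-open above,
    ``(lower_pct, upper_pct]``, except the first band which is open below
    at 0: band 1 is (0, 0.1), band 2 [0.1, 1], band 3 (1, 5], band 4
    (5, 10], band 5 (10, 100].  This contiguous reading of the printed
    gapped labels (e.g. "5.1-10%") guarantees every probability in
    (0, 100] falls in exactly one band, and places boundary incidences
    such as 10 % (a typical screening prevalence) in band 4.
    """

    index: int
    label: str
    lower_pct: float
    upper_pct: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 5:
            raise RiskMatrixError(f"band index must be 1-5, got {self.index}")
        if not 0 <= self.lower_pct < self.upper_pct <= 100:
            raise RiskMatrixError(
                f"invalid band bounds ({self.lower_pct}, {self.upper_pct}]"
            )

    def contains(self, probability_pct: float) -> bool:
        if self.index == 1:
            return 0 < probability_pct < self.upper_pct
        if self.index == 2:
            return self.lower_pct <= probability_pct <= self.upper_pct
        return self.lower_pct < probability_pct <= self.upper_pct


@dataclass(frozen=True)
class ImpactLevel:
    """One matrix column: an ordinal consequence-severity category.

    Default role labels describe obstetric care escalation but are
    configurable per profession.
    """

    index: int
    role_label: str

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 5:
            raise RiskMatrixError(f"impact index must be 1-5, got {self.index}")


@dataclass(frozen=True)
class RiskCategory:
    """A named band of risk scores with its colour label.

    The five ranges (1-4, 5-8, 9-14, 15-19, 20-25) are irregular, so they
    are data, not arithmetic.
    """

    name: str
    color_label: str
    score_min: int
    score_max: int
    rank: int


DEFAULT_BANDS: tuple[ProbabilityBand, ...] = (
    ProbabilityBand(1, "rare", 0.0, 0.1),
    ProbabilityBand(2, "unlikely", 0.1, 1.0),
    ProbabilityBand(3, "possible", 1.0, 5.0),
    ProbabilityBand(4, "likely", 5.0, 10.0),
    ProbabilityBand(5, "very likely", 10.0, 100.0),
)

DEFAULT_IMPACT_LEVELS: tuple[ImpactLevel, ...] = (
    ImpactLevel(1, "managed-in-primary-care"),
    ImpactLevel(2, "short-hospitalization (<2 days)"),
    ImpactLevel(3, "long-hospitalization (>=2 days)"),
    ImpactLevel(4, "disability/serious-morbidity"),
    ImpactLevel(5, "death"),
)

DEFAULT_CATEGORIES: tuple[RiskCategory, ...] = (
    RiskCategory("small", "dark green", 1, 4, 1),
    RiskCategory("moderate", "light green", 5, 8, 2),
    RiskCategory("high", "yellow", 9, 14, 3),
    RiskCategory("very high", "orange", 15, 19, 4),
    RiskCategory("extreme", "red", 20, 25, 5),
)


@dataclass(frozen=True)
class MatrixGeometry:
    """Complete 5x5 matrix definition: bands, impact labels, categories.

    The default geometry is the published obstetric design; labels and
    bounds may be overridden from a scenario config file, but the matrix
    stays 5x5 and category ranges must tile 1..25.
    """

    bands: tuple[ProbabilityBand, ...] = DEFAULT_BANDS
    impact_levels: tuple[ImpactLevel, ...] = DEFAULT_IMPACT_LEVELS
    categories: tuple[RiskCategory, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if sorted(b.index for b in self.bands) != [1, 2, 3, 4, 5]:
            raise RiskMatrixError("bands must carry indices 1-5 exactly once")
        if sorted(l.index for l in self.impact_levels) != [1, 2, 3, 4, 5]:
            raise RiskMatrixError("impact levels must carry indices 1-5 exactly once")
        covered = sorted(
            s for c in self.categories for s in range(c.score_min, c.score_max + 1)
        )
        if covered != list(range(1, 26)):
            raise RiskMatrixError("category ranges must tile scores 1-25 exactly")
        ranks = [c.rank for c in sorted(self.categories, key=lambda c: c.score_min)]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise RiskMatrixError("category rank must increase with score_min")
        # ordered views for lookups
        object.__setattr__(
            self, "bands", tuple(sorted(self.bands, key=lambda b: b.index))
        )
        object.__setattr__(
            self,
            "impact_levels",
            tuple(sorted(self.impact_levels, key=lambda l: l.index)),
        )
        object.__setattr__(
            self,
            "categories",
            tuple(sorted(self.categories, key=lambda c: c.score_min)),
        )

    def assign_probability_band(self, event_probability: float) -> ProbabilityBand:
        """Map an event probability (percent) to its probability band.

        Raises :class:`RiskMatrixError` for probabilities outside (0, 100].
        """
        if not 0 < event_probability <= 100:
            raise RiskMatrixError(
                f"event probability must be in (0, 100] percent, got {event_probability}"
            )
        for band in self.bands:
            if band.contains(event_probability):
                return band
        raise RiskMatrixError(  # pragma: no cover - bands tile (0, 100]
            f"no band contains {event_probability}%"
        )

    def risk_score(self, band_index: int, impact_index: int) -> int:
        """Risk score of a cell: band index times impact index (1..25)."""
        if not 1 <= band_index <= 5:
            raise RiskMatrixError(f"band index must be 1-5, got {band_index}")
        if not 1 <= impact_index <= 5:
            raise RiskMatrixError(f"impact index must be 1-5, got {impact_index}")
        return band_index * impact_index

    def risk_category(self, score: int) -> RiskCategory:
        """Category (name, colour, rank) containing a risk score 1..25."""
        if not 1 <= score <= 25 or int(score) != score:
            raise RiskMatrixError(f"risk score must be an integer 1-25, got {score}")
        for cat in self.categories:
            if cat.score_min <= score <= cat.score_max:
                return cat
        raise RiskMatrixError(f"no category contains score {score}")  # pragma: no cover


DEFAULT_GEOMETRY = MatrixGeometry()


def assign_probability_band(event_probability: float) -> ProbabilityBand:
    """Assign a probability band under the default geometry."""
    return DEFAULT_GEOMETRY.assign_probability_band(event_probability)


def risk_score(band_index: int, impact_index: int) -> int:
    """Multiplicative risk score under the default geometry."""
    return DEFAULT_GEOMETRY.risk_score(band_index, impact_index)


def risk_category(score: int) -> RiskCategory:
    """Risk category of a score under the default geometry."""
    return DEFAULT_GEOMETRY.risk_category(score)
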