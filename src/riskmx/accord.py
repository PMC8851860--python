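"""Survey triage and consensus arithmetic (ACCORD process).

Guideline statements are scored by professionals on a 10-point Likert
scale (1 = totally disagree, 10 = totally agree).  Each statement is
summarised by its mean and standard deviation and triaged:

* mean > 8 and SD < 2  -> accept without discussion
* mean < 3 and SD < 2  -> reject without discussion
* otherwise (mean in [3, 8], or SD >= 2) -> discuss in the mandated team

Decisions of the mandated team are adopted when at least 85 % of the team
is in favour; the ratio is compared with exact integer arithmetic so the
boundary (17 of 20) is inclusive.

The standard deviation is the sample SD (divisor n - 1), the survey
reporting norm; pass ``ddof=0`` for the population convention.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .matrix_core import RiskMatrixError

Verdict = Literal["accept", "reject", "discuss"]

LIKERT_MIN, LIKERT_MAX = 1, 10


class SurveyError(RiskMatrixError):
    """Raised on malformed survey responses or tables."""


@dataclass(frozen=True)
class Statement:
    """One survey statement with its raw Likert responses."""

    id: str
    text: str
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_responses(self.responses)


@dataclass(frozen=True)
class StatementResult:
    """Mean/SD summary and triage verdict for one statement."""

    id: str
    mean: float
    sd: float
    n: int
    verdict: Verdict


@dataclass(frozen=True)
class ConsensusVote:
    """Mandated-team vote on a discussed statement."""

    n_favor: int
    n_total: int
    adopted: bool


def _check_responses(responses: Sequence[int]) -> None:
    if len(responses) < 2:
        raise SurveyError(
            f"need at least 2 responses for an SD, got {len(responses)}"
        )
    bad = [r for r in responses if not (LIKERT_MIN <= r <= LIKERT_MAX) or int(r) != r]
    if bad:
        raise SurveyError(f"responses must be integers 1-10; offending values: {bad}")


def statement_stats(responses: Sequence[int], ddof: int = 1) -> tuple[float, float]:
    """Arithmetic mean and sample SD of a statement's Likert responses."""
    _check_responses(responses)
    xs = [float(r) for r in responses]
    mean = statistics.fmean(xs)
    sd = statistics.stdev(xs) if ddof == 1 else statistics.pstdev(xs)
    return mean, sd


def triage(mean: float, sd: float) -> Verdict:
    """Triage a statement from its mean and SD.

    Accept and reject require a decisive mean (strictly above 8 or below
    3) *and* low dispersion (SD strictly below 2).  A mean in the closed
    interval [3, 8], or an SD of 2 or more, sends the statement to
    discussion; SD exactly 2 discusses, the conservative reading.
    """
    if not LIKERT_MIN <= mean <= LIKERT_MAX:
        raise SurveyError(f"mean must lie in [1, 10], got {mean}")
    if sd < 0:
        raise SurveyError(f"SD must be non-negative, got {sd}")
    if mean > 8 and sd < 2:
        return "accept"
    if mean < 3 and sd < 2:
        return "reject"
    return "discuss"


def consensus(n_favor: int, n_total: int) -> ConsensusVote:
    """Apply the >= 85 % mandated-team rule with exact rational arithmetic."""
    if n_total < 1:
        raise SurveyError("mandated team must have at least one member")
    if not 0 <= n_favor <= n_total:
        raise SurveyError(f"n_favor must be in [0, {n_total}], got {n_favor}")
    adopted = n_favor * 100 >= 85 * n_total
    return ConsensusVote(n_favor=n_favor, n_total=n_total, adopted=adopted)


def evaluate_statement(statement: Statement, ddof: int = 1) -> StatementResult:
    """Summarise and triage one statement."""
    mean, sd = statement_stats(statement.responses, ddof=ddof)
    return StatementResult(
        id=statement.id,
        mean=mean,
        sd=sd,
        n=len(statement.responses),
        verdict=triage(mean, sd),
    )


def read_survey_csv(path) -> list[Statement]:
    """Read a long-format survey table.

    Expects columns ``statement_id``, ``respondent_id``, ``score``; one
    row per response.
    """
    df = pd.read_csv(path)
    required = {"statement_id", "respondent_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyError(f"survey table missing columns: {sorted(missing)}")
    if df.empty:
        raise SurveyError("survey table contains no responses")
    statements = []
    for sid, grp in df.groupby("statement_id", sort=True):
        statements.append(
            Statement(
                id=str(sid),
                text="",
                responses=tuple(int(s) for s in grp["score"]),
            )
        )
    return statements


def triage_survey(statements: Iterable[Statement], ddof: int = 1) -> pd.DataFrame:
    """Per-statement results table: columns id, n, mean, sd, verdict."""
    rows = [evaluate_statement(s, ddof=ddof) for s in statements]
    return pd.DataFrame(
        {
            "statement_id": [r.id for r in rows],
            "n": [r.n for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "verdict": [r.verdict for r in rows],
        }
    )
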