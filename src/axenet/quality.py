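"""Five-question publication appraisal rubric with three-rater aggregation.

Each publication describing an axenisation procedure is appraised by three
raters against five questions: (1) is the source of the organism reported,
(2) are technical details of the method reproducible, (3) is the growth
medium clearly described, (4) was axenicity verified after treatment, and
(5) were the contaminating organisms identified.  Answers map to point
values; a rater's total lies in [-3, 5] and the publication's final score is
the rounded mean of the three totals.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .master_table import MasterTable

N_RATERS = 3
MIN_TOTAL, MAX_TOTAL = -3, 5

#: Point values per question.  Question keys are q1..q5; answers are the
#: enumerated strings accepted in the master table.
QUESTION_POINTS: Mapping[str, Mapping[str, int]] = {
    "q1": {"yes": 1, "no": 0},
    "q2": {"yes": 1, "incompletely": 0, "no": -1},
    "q3": {"yes": 1, "referenced": 0, "no": -1},
    "q4": {"multiple": 1, "one": 0, "none": -1},
    "q5": {"yes": 1, "no": 0},
}


@dataclass(frozen=True)
class RubricResponse:
    """One rater's answers to the five appraisal questions."""

    q1: str
    q2: str
    q3: str
    q4: str
    q5: str

    def __post_init__(self) -> None:
        for q, answer in self.answers().items():
            if answer not in QUESTION_POINTS[q]:
                raise ValueError(
                    f"invalid answer {answer!r} for {q} "
                    f"(allowed: {sorted(QUESTION_POINTS[q])})"
                )

    def answers(self) -> dict[str, str]:
        return {"q1": self.q1, "q2": self.q2, "q3": self.q3, "q4": self.q4, "q5": self.q5}


def score_response(response: RubricResponse) -> int:
    """Total points for one rater's response (sum of the five mapped values)."""
    return sum(QUESTION_POINTS[q][a] for q, a in response.answers().items())


def round_half_away_from_zero(x: float) -> int:
    """Round with ties going away from zero (0.5 -> 1, -0.5 -> -1).

    Python's built-in ``round`` uses banker's rounding, which would make the
    below-zero classification depend on parity at half-integer means.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def aggregate_raters(totals: Iterable[int]) -> int:
    """Final publication score: rounded mean of the three rater totals."""
    totals = list(totals)
    if len(totals) != N_RATERS:
        raise ValueError(f"expected {N_RATERS} rater totals, got {len(totals)}")
    for t in totals:
        if not MIN_TOTAL <= t <= MAX_TOTAL:
            raise ValueError(f"rater total {t} outside [{MIN_TOTAL}, {MAX_TOTAL}]")
    return round_half_away_from_zero(sum(totals) / N_RATERS)


@dataclass(frozen=True)
class RaterScores:
    """Three raters' responses plus derived totals and the final score."""

    responses: tuple[RubricResponse, RubricResponse, RubricResponse]

    def __post_init__(self) -> None:
        if len(self.responses) != N_RATERS:
            raise ValueError(f"expected {N_RATERS} responses")

    @property
    def per_rater_totals(self) -> tuple[int, int, int]:
        return tuple(score_response(r) for r in self.responses)  # type: ignore[return-value]

    @property
    def final_score(self) -> int:
        return aggregate_raters(self.per_rater_totals)


@dataclass(frozen=True)
class QualitySummary:
    """Publication-level histogram of final scores."""

    histogram: Mapping[int, int]        # final score -> number of publications
    by_period: Mapping[str, Mapping[int, int]]  # decade label -> histogram
    n_publications: int
    n_below_zero: int


def summarize_scores(table: "MasterTable") -> QualitySummary:
    """Histogram of final scores at publication level and the below-zero count.

    Multi-species publications replicate their quality scores across rows; the
    summary deduplicates by publication id.  Periods are decades derived from
    the publication year.
    """
    per_pub: dict[str, tuple[int, int]] = {}  # pub id -> (final score, year)
    missing: list[str] = []
    for rec in table.records:
        if rec.quality is None:
            missing.append(rec.publication_id)
            continue
        per_pub[rec.publication_id] = (rec.quality.final_score, rec.year)
    if missing:
        raise ValueError(f"publications without quality scores: {sorted(set(missing))}")

    hist = Counter(score for score, _ in per_pub.values())
    by_period: dict[str, Counter] = {}
    for score, year in per_pub.values():
        decade = f"{(year // 10) * 10}s"
        by_period.setdefault(decade, Counter())[score] += 1
    return QualitySummary(
        histogram=dict(sorted(hist.items())),
        by_period={k: dict(sorted(v.items())) for k, v in sorted(by_period.items())},
        n_publications=len(per_pub),
        n_below_zero=sum(n for score, n in hist.items() if score < 0),
    )
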