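"""SUS questionnaire scoring, dataset summaries and flatten-the-curve metrics.

The System Usability Scale has ten statements rated 1–5; odd-numbered
statements are positively worded (converted score = rating − 1) and
even-numbered ones negatively worded (converted = 5 − rating), so every
converted item lies in [0, 4].  The overall score is 2.5 × the item sum,
on a 0–100 scale.  Statements 4 and 10 measure learnability; the remaining
eight measure usability (each dimension reported as the mean converted
score, 0–4).

Reported means and percentages are rounded half-up to 2 decimal places.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .epidemic_sim import SimResult, peak_metrics
from .record_store import CheckinRecord

__all__ = [
    "SUSResponse",
    "SUSScores",
    "SurveyError",
    "convert_items",
    "sus_scores",
    "dataset_summary",
    "flatten_comparison",
    "round2",
]

POSITIVE_ITEMS = (1, 3, 5, 7, 9)
LEARNABILITY_ITEMS = (4, 10)


class SurveyError(ValueError):
    pass


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (presentation convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SUSResponse:
    """One participant's ten Likert ratings, in statement order S1..S10."""

    ratings: tuple[int, ...]

    def __post_init__(self):
        if len(self.ratings) != 10:
            raise SurveyError(f"need 10 ratings, got {len(self.ratings)}")
        for i, r in enumerate(self.ratings, start=1):
            if r not in (1, 2, 3, 4, 5):
                raise SurveyError(f"S{i}: rating {r!r} outside 1..5")


@dataclass(frozen=True)
class SUSScores:
    items: tuple[float, ...]  # converted scores, each in [0, 4]
    overall: float            # 0..100
    learnability: float       # 0..4
    usability: float          # 0..4


def convert_items(response: SUSResponse) -> tuple[float, ...]:
    """Polarity-aware conversion of raw ratings to 0–4 scores."""
    out = []
    for i, r in enumerate(response.ratings, start=1):
        out.append(float(r - 1 if i in POSITIVE_ITEMS else 5 - r))
    return tuple(out)


def sus_scores(item_scores: Sequence[float]) -> SUSScores:
    """Aggregate ten converted item scores (or per-item means) to SUS scores."""
    if len(item_scores) != 10:
        raise SurveyError(f"need 10 item scores, got {len(item_scores)}")
    items = tuple(float(s) for s in item_scores)
    for i, s in enumerate(items, start=1):
        if not 0 <= s <= 4:
            raise SurveyError(f"S{i}: converted score {s} outside [0, 4]")
    learn = [items[i - 1] for i in LEARNABILITY_ITEMS]
    usab = [items[i - 1] for i in range(1, 11) if i not in LEARNABILITY_ITEMS]
    return SUSScores(
        items=items,
        overall=round2(2.5 * sum(items)),
        learnability=round2(float(np.mean(learn))),
        usability=round2(float(np.mean(usab))),
    )


def score_survey(responses: Iterable[SUSResponse]) -> SUSScores:
    """Score a survey: mean converted score per item, then aggregate."""
    converted = np.array([convert_items(r) for r in responses])
    if converted.size == 0:
        raise SurveyError("no survey responses")
    return sus_scores(tuple(converted.mean(axis=0)))


def dataset_summary(records: Sequence[CheckinRecord] | int,
                    n_users: int, n_venues: int,
                    ) -> dict[str, float]:
    """Check-in volume summaries: means and maxima per user and per venue.

    ``records`` may be an explicit record collection or just a total count
    (maxima are then unavailable and reported as NaN).
    """
    if n_users < 1 or n_venues < 1:
        raise SurveyError("need positive user and venue counts")
    if isinstance(records, int):
        total = records
        max_user = max_venue = float("nan")
    else:
        total = len(records)
        by_user = Counter(r.visitor for r in records)
        by_venue = Counter(r.venue for r in records)
        max_user = float(max(by_user.values(), default=0))
        max_venue = float(max(by_venue.values(), default=0))
    return {
        "total_checkins": float(total),
        "mean_per_user": round2(total / n_users),
        "mean_per_venue": round2(total / n_venues),
        "max_per_user": max_user,
        "max_per_venue": max_venue,
    }


def flatten_comparison(baseline: SimResult | Sequence[float],
                       treated: SimResult | Sequence[float],
                       ) -> tuple[float, int]:
    """(% peak reduction, peak delay in days) of treated vs baseline.

    reduction = 100 · (1 − treated_peak / baseline_peak);
    delay = treated_t_peak − baseline_t_peak.
    """
    base = baseline.active if isinstance(baseline, SimResult) else baseline
    trt = treated.active if isinstance(treated, SimResult) else treated
    if len(base) == 0 or len(trt) == 0:
        raise SurveyError("both series must be nonempty")
    if len(base) != len(trt):
        raise SurveyError("series must share a horizon")
    peak_b, t_b = peak_metrics(base)
    peak_t, t_t = peak_metrics(trt)
    if peak_b == 0:
        raise SurveyError("baseline peak is zero; reduction undefined")
    return round2(100.0 * (1.0 - peak_t / peak_b)), int(t_t - t_b)
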