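"""Visitor liability scoring from voluntary-form answers.

Visitors disclose six items spanning three aspects — *Residence* (home,
workplace), *Mobility* (travel record, means of transport) and *Health*
(symptoms, close contact).  A configurable rubric maps each answer token to a
numeric score; the six scores form a vector ``V`` plotted on a six-axis radar
map.  The liability score φ(u) is the polygon area enclosed by ``V``
normalized by the area at the per-item upper bounds ``V̂``:

    φ(u) = Σ_{i=0}^{a-1} V_{i mod a} · V_{(i+1) mod a}
         / Σ_{i=0}^{a-1} V̂_{i mod a} · V̂_{(i+1) mod a}

with ``a = 6`` axes (the common 1/2·sin(2π/a) area factor cancels in the
ratio).  Higher φ means a *safer* visitor; a visitor with φ strictly below
the threshold θ_liability is classified as low-liability.

The ratio is order-dependent (each term couples cyclically adjacent axes),
so the axis order is fixed and recorded in the rubric.  Unanswered items
score zero — visitors are thereby incentivized to fill the form completely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "AXES",
    "ScoringRubric",
    "FormResponse",
    "ScoreVector",
    "LiabilityScore",
    "RubricError",
    "ScoringError",
    "apply_rubric",
    "radar_score",
    "classify",
    "default_rubric",
    "load_rubric",
]

#: Canonical axis order of the radar map.
AXES = ("Home", "Workplace", "TravelRecord", "MeansOfTransport",
        "Symptoms", "CloseContact")

LOW_LIABILITY = "low_liability"
ACCEPTABLE = "acceptable"


class RubricError(ValueError):
    """Invalid rubric configuration."""


class ScoringError(ValueError):
    """A form answer that the rubric cannot score."""


@dataclass(frozen=True)
class ScoringRubric:
    """Answer→score maps for the six radar axes plus per-axis upper bounds."""

    items: tuple[str, ...]
    answer_scores: Mapping[str, Mapping[str, float]]
    upper_bounds: tuple[float, ...]
    theta_liability: float = 0.8

    def __post_init__(self):
        if tuple(self.items) != AXES:
            raise RubricError(
                f"rubric must define exactly the six axes {list(AXES)} in "
                f"order, got {list(self.items)}")
        if len(self.upper_bounds) != len(AXES):
            raise RubricError("need one upper bound per axis")
        for ub in self.upper_bounds:
            if not ub > 0:
                raise RubricError(f"upper bounds must be positive, got {ub}")
        for item, mapping in self.answer_scores.items():
            if item not in AXES:
                raise RubricError(f"unknown rubric item {item!r}")
            ub = self.upper_bounds[AXES.index(item)]
            for answer, score in mapping.items():
                if not 0 <= score <= ub:
                    raise RubricError(
                        f"{item}: score {score} for answer {answer!r} "
                        f"outside [0, {ub}]")
        if not 0 < self.theta_liability <= 1:
            raise RubricError(
                f"theta_liability must lie in (0, 1], got {self.theta_liability}")


@dataclass(frozen=True)
class FormResponse:
    """Per-item answer tokens; any subset of axes may be answered."""

    answers: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.answers) - set(AXES)
        if unknown:
            raise ScoringError(f"unknown form item(s) {sorted(unknown)}")


@dataclass(frozen=True)
class ScoreVector:
    """The 6-dimensional rubric score vector V."""

    V: tuple[float, ...]

    def __post_init__(self):
        if len(self.V) != len(AXES):
            raise ScoringError(f"score vector must have {len(AXES)} components")
        for v in self.V:
            if v < 0:
                raise ScoringError(f"negative score component {v}")


@dataclass(frozen=True)
class LiabilityScore:
    phi: float
    threshold: float

    @property
    def low_liability(self) -> bool:
        return self.phi < self.threshold

    @property
    def category(self) -> str:
        return LOW_LIABILITY if self.low_liability else ACCEPTABLE


def apply_rubric(form: FormResponse, rubric: ScoringRubric) -> ScoreVector:
    """Score a form response; unanswered items score zero."""
    scores = []
    for i, item in enumerate(AXES):
        answer = form.answers.get(item)
        if answer is None:
            scores.append(0.0)
            continue
        mapping = rubric.answer_scores.get(item, {})
        if answer not in mapping:
            raise ScoringError(
                f"item {item!r}: answer {answer!r} not in rubric "
                f"(known: {sorted(mapping)})")
        scores.append(float(mapping[answer]))
    return ScoreVector(tuple(scores))


def _cyclic_area(values: Sequence[float]) -> float:
    a = len(values)
    return sum(values[i % a] * values[(i + 1) % a] for i in range(a))


def radar_score(V: ScoreVector | Sequence[float],
                upper_bounds: Sequence[float]) -> float:
    """Normalized radar-map area φ(u) ∈ [0, 1].

    φ = 0 whenever no two cyclically adjacent components are both positive
    (each area term couples neighbouring axes), and φ = 1 at V = V̂.
    """
    values = V.V if isinstance(V, ScoreVector) else tuple(float(v) for v in V)
    if len(values) != len(upper_bounds):
        raise ScoringError("V and upper bounds must have equal length")
    for ub in upper_bounds:
        if not ub > 0:
            raise RubricError(f"upper bounds must be positive, got {ub}")
    for v, ub in zip(values, upper_bounds):
        if not 0 <= v <= ub:
            raise ScoringError(f"score component {v} outside [0, {ub}]")
    return _cyclic_area(values) / _cyclic_area(tuple(float(u) for u in upper_bounds))


def classify(phi: float, theta_liability: float) -> str:
    """Strictly-below rule: φ < θ ⇒ low-liability, otherwise acceptable."""
    if not 0 <= phi <= 1:
        raise ScoringError(f"phi {phi} outside [0, 1]")
    if not 0 < theta_liability <= 1:
        raise RubricError(f"theta_liability {theta_liability} outside (0, 1]")
    return LOW_LIABILITY if phi < theta_liability else ACCEPTABLE


def score_form(form: FormResponse, rubric: ScoringRubric) -> LiabilityScore:
    """Convenience: rubric application plus radar scoring."""
    V = apply_rubric(form, rubric)
    phi = radar_score(V, rubric.upper_bounds)
    return LiabilityScore(phi=phi, threshold=rubric.theta_liability)


def default_rubric(theta_liability: float = 0.8) -> ScoringRubric:
    """Rubric shipped as a reasonable default, not a normative standard.

    Residence and travel items follow the five-tier regional risk grading
    (tier 1 = highest-risk region → score 1, tier 5 = lowest risk → 5).
    Transport scores congested public options low and individual commuting
    high.  Symptoms / close contact use a severity map.  Venue managers are
    expected to adapt these values to the phase of the epidemic.
    """
    tiers = {f"tier{i}": float(i) for i in range(1, 6)}
    return ScoringRubric(
        items=AXES,
        answer_scores={
            "Home": dict(tiers),
            "Workplace": dict(tiers),
            "TravelRecord": dict(tiers),
            "MeansOfTransport": {
                "metro": 1.0, "bus": 2.0, "bicycle": 4.0,
                "driving": 5.0, "walking": 5.0,
            },
            "Symptoms": {"severe": 1.0, "mild": 2.0, "none": 5.0},
            "CloseContact": {"confirmed": 1.0, "suspected": 2.0, "none": 5.0},
        },
        upper_bounds=(5.0,) * 6,
        theta_liability=theta_liability,
    )


def load_rubric(path: str | Path) -> ScoringRubric:
    """Load a rubric from a YAML file (see ``default_rubric`` for semantics).

    Expected keys: ``items`` (ordered axis names), ``answer_scores``
    (item → {answer: score}), ``upper_bounds``, ``theta_liability``.
    """
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    try:
        return ScoringRubric(
            items=tuple(cfg["items"]),
            answer_scores={k: {a: float(s) for a, s in v.items()}
                           for k, v in cfg["answer_scores"].items()},
            upper_bounds=tuple(float(u) for u in cfg["upper_bounds"]),
            theta_liability=float(cfg.get("theta_liability", 0.8)),
        )
    except KeyError as exc:
        raise RubricError(f"rubric file missing key {exc}") from exc
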