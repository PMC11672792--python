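"""Venue availability from member, propagation and crowdedness risk.

A venue's availability ω(v) is the probability that a random visitor avoids
infection in random contacts inside the venue:

    ω(v) = (1 − β)^{(R1 + R2) · R3}

where

* ``R1 = n_l`` — the number of low-liability visitors currently inside,
* ``R2 = Σ_i r_i · n_i / m_i`` — the expected low-liability inflow from
  neighbouring venues, estimated from historical check-in transitions
  (``n_i`` transfers from venue i to the target out of ``m_i`` departures,
  weighted by the ``r_i`` low-liability visitors currently in venue i),
* ``R3 = N / N_c`` — occupancy over capacity (unbounded above: an
  over-capacity venue scales contact opportunities beyond 1), and
* ``β = R0 / τ`` — the per-contact transmission probability, the basic
  reproduction number spread over the τ person-to-person contacts an
  infectious case makes during the infectious period.

``(R1 + R2) · R3`` plays the role of the expected number of contacts with
low-liability visitors, so ω is the survival probability over those
contacts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .record_store import CheckinRecord

__all__ = [
    "VenueState",
    "TransitionStats",
    "TransmissionRate",
    "RiskProfile",
    "RiskError",
    "member_risk",
    "transition_stats",
    "propagation_risk",
    "crowdedness_risk",
    "availability",
    "risk_profile",
]

DEFAULT_MAX_GAP_S = 2 * 3600.0  # linkage window between check-out and next check-in


class RiskError(ValueError):
    pass


@dataclass(frozen=True)
class VenueState:
    """Current occupants of a venue with their liability scores."""

    venue_id: str
    occupants: tuple[tuple[str, float], ...]  # (anon_id, phi)
    theta_liability: float = 0.8

    @property
    def N(self) -> int:
        return len(self.occupants)

    @property
    def n_low(self) -> int:
        return sum(1 for _, phi in self.occupants if phi < self.theta_liability)


@dataclass(frozen=True)
class TransitionStats:
    """Historical transfer counts into one target venue.

    ``n[i]`` transfers i → target out of ``m[i]`` departures from venue i;
    ``r[i]`` is the current low-liability head count in venue i.  Sources
    with no departure history are retained with n = 0.
    """

    target: str
    n: Mapping[str, int]
    m: Mapping[str, int]
    r: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for src, m_i in self.m.items():
            n_i = self.n.get(src, 0)
            if not 0 <= n_i <= m_i:
                raise RiskError(
                    f"source {src!r}: need 0 <= n ({n_i}) <= m ({m_i})")

    def with_current_counts(self, r: Mapping[str, int]) -> "TransitionStats":
        return TransitionStats(self.target, dict(self.n), dict(self.m), dict(r))


@dataclass(frozen=True)
class TransmissionRate:
    """β = R0/τ with τ = contacts/day × infectious days."""

    R0: float = 2.24
    contacts_per_day: float = 50.0
    infectious_days: float = 15.0

    def __post_init__(self):
        if self.R0 <= 0 or self.contacts_per_day <= 0 or self.infectious_days <= 0:
            raise RiskError("R0, contacts_per_day and infectious_days must be > 0")
        if self.beta >= 1:
            raise RiskError(f"beta = {self.beta:.4f} must be < 1")

    @property
    def tau(self) -> float:
        return self.contacts_per_day * self.infectious_days

    @property
    def beta(self) -> float:
        return self.R0 / self.tau


@dataclass(frozen=True)
class RiskProfile:
    R1: float
    R2: float
    R3: float
    beta: float

    @property
    def omega(self) -> float:
        return availability(self.R1, self.R2, self.R3, self.beta)


def member_risk(state: VenueState) -> int:
    """R1: the number of low-liability visitors inside the venue."""
    return state.n_low


def transition_stats(history: Iterable[CheckinRecord], target: str,
                     max_gap: float = DEFAULT_MAX_GAP_S) -> TransitionStats:
    """Count historical venue-to-venue transfers into ``target``.

    A transfer is a visitor's check-out from venue i followed by their next
    check-in (at any venue) within ``max_gap`` seconds; it increments
    ``m[i]`` and, when the next venue is the target, ``n[i]``.  Open
    sessions are ignored.  Consecutive check-ins separated by more than the
    window do not count as departures at all — the visitor is assumed to
    have left the campus in between.
    """
    by_visitor: dict[str, list[CheckinRecord]] = defaultdict(list)
    for rec in history:
        if rec.closed:
            by_visitor[rec.visitor].append(rec)

    n: dict[str, int] = defaultdict(int)
    m: dict[str, int] = defaultdict(int)
    venues_seen: set[str] = set()
    for sessions in by_visitor.values():
        sessions.sort(key=lambda r: r.t_in)
        for prev, nxt in zip(sessions, sessions[1:]):
            venues_seen.add(prev.venue)
            venues_seen.add(nxt.venue)
            gap = nxt.t_in - prev.t_out
            if 0 <= gap <= max_gap:
                m[prev.venue] += 1
                if nxt.venue == target:
                    n[prev.venue] += 1
    # retain sources with no linked departures
    for v in venues_seen:
        m.setdefault(v, 0)
        n.setdefault(v, 0)
    return TransitionStats(target=target, n=dict(n), m=dict(m))


def propagation_risk(stats: TransitionStats) -> float:
    """R2 = Σ_i r_i · n_i / m_i; sources with m_i = 0 contribute zero."""
    total = 0.0
    for src, m_i in stats.m.items():
        if m_i <= 0:
            continue
        r_i = stats.r.get(src, 0)
        total += r_i * stats.n.get(src, 0) / m_i
    return total


def crowdedness_risk(N: int, N_c: int) -> float:
    """R3 = N/N_c; exceeds 1 when the venue is over capacity."""
    if N_c < 1:
        raise RiskError(f"capacity must be >= 1, got {N_c}")
    if N < 0:
        raise RiskError(f"occupancy must be >= 0, got {N}")
    return N / N_c


def availability(R1: float, R2: float, R3: float, beta: float) -> float:
    """ω = (1 − β)^{(R1 + R2) · R3} ∈ (0, 1]."""
    if not 0 < beta < 1:
        raise RiskError(f"beta must lie in (0, 1), got {beta}")
    if R1 < 0 or R2 < 0 or R3 < 0:
        raise RiskError("risk factors must be nonnegative")
    return (1.0 - beta) ** ((R1 + R2) * R3)


def risk_profile(state: VenueState, stats: TransitionStats, capacity: int,
                 rate: TransmissionRate) -> RiskProfile:
    """Bundle the three factors for a venue at one evaluation instant."""
    return RiskProfile(
        R1=float(member_risk(state)),
        R2=propagation_risk(stats),
        R3=crowdedness_risk(state.N, capacity),
        beta=rate.beta,
    )
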