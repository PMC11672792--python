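"""Agent-based epidemic replay of check-in streams through venues.

Venues are modelled as well-mixed compartments: within a venue-day, an
infectious agent draws ``min(round(contacts_per_day × f), N − 1)`` distinct
uniform contacts from the other co-present agents, where ``f`` is the
fraction of the day the agent spends checked in; each susceptible contact is
infected with the per-contact probability β.  Disease progresses through
susceptible → asymptomatic → infectious → recovered: the exposed and
asymptomatic phases are merged into a single non-infectious period of
``asymptomatic_days`` (the data only pin down the 6/21-day split, and
asymptomatic agents cannot transmit), followed by ``course_days −
asymptomatic_days`` infectious days.  Stage transitions tick once per day;
within-day occupancy is resolved from the check-in timestamps.

Initial cases are the low-liability visitors: seeding assigns exactly
``round(I0 · n)`` agents a liability below θ and starts them asymptomatic,
so the initial infection rate equals the initial low-liability fraction.

With access control enabled, the stream is first replayed through each
venue's priority admission queue: the server count is refreshed every
midnight as ``s = max(1, floor(ω · N_c))`` from the venue's current risk
profile, arrivals beyond ``s`` wait in priority order (class from
``ceil(1/φ)``), and a visitor's check-out time is *not* shifted — waiting
eats into the visit, and a visit whose window closes before admission is
cancelled.  This is what lets the policy lower and delay the epidemic peak.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .access_control import priority_of
from .record_store import CheckinRecord, Venue
from .venue_risk import TransmissionRate, transition_stats

__all__ = [
    "SUSCEPTIBLE", "ASYMPTOMATIC", "INFECTIOUS", "RECOVERED",
    "SimParams", "SimResult", "SimulationError",
    "seed_infections", "step_day", "run_simulation", "peak_metrics",
    "apply_access_control",
]

SUSCEPTIBLE, ASYMPTOMATIC, INFECTIOUS, RECOVERED = 0, 1, 2, 3
STAGE_NAMES = ("susceptible", "asymptomatic", "infectious", "recovered")

HOURS_PER_DAY = 24.0
SECONDS_PER_HOUR = 3600.0


def _hours(t: float, t0: float) -> float:
    """Epoch seconds → hours since the stream origin."""
    return (t - t0) / SECONDS_PER_HOUR


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Disease and control parameters for one simulation run."""

    I0: float = 0.10
    contacts_per_day: float = 50.0
    course_days: int = 21
    asymptomatic_days: int = 6
    rate: TransmissionRate = field(default_factory=TransmissionRate)
    theta_liability: float = 0.8
    priority_classes: int = 5
    seed: int = 0
    control_on: bool = False

    def __post_init__(self):
        if not 0 <= self.I0 <= 1:
            raise SimulationError(f"I0 {self.I0} outside [0, 1]")
        if not 0 < self.asymptomatic_days < self.course_days:
            raise SimulationError(
                "need 0 < asymptomatic_days < course_days, got "
                f"{self.asymptomatic_days} / {self.course_days}")

    @property
    def infectious_days(self) -> int:
        return self.course_days - self.asymptomatic_days

    @property
    def beta(self) -> float:
        return self.rate.beta


@dataclass(frozen=True)
class SimResult:
    """Daily stage counts; ``active = asymptomatic + infectious``."""

    counts: pd.DataFrame  # columns: day, susceptible, asymptomatic, infectious, recovered, active_cases

    @property
    def active(self) -> np.ndarray:
        return self.counts["active_cases"].to_numpy()

    @property
    def peak_active(self) -> int:
        return peak_metrics(self.active)[0]

    @property
    def t_peak(self) -> int:
        return peak_metrics(self.active)[1]


def peak_metrics(active: Sequence[float]) -> tuple[float, int]:
    """(peak height, first day attaining it) of an active-case series."""
    arr = np.asarray(active)
    if arr.size == 0:
        raise SimulationError("empty active-case series")
    t = int(np.argmax(arr))  # argmax returns the first maximum
    return arr[t].item(), t


def seed_infections(n: int, I0: float, seed: int,
                    theta_liability: float = 0.8,
                    phis: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Seed exactly ``round(I0·n)`` initial asymptomatic cases.

    Returns ``(stages, phis)``.  When ``phis`` is given (e.g. scored from
    generated forms), the ``round(I0·n)`` lowest-liability agents are
    seeded; otherwise liabilities are sampled so that seeded agents fall
    below θ and the rest at or above it.
    """
    if not 0 <= I0 <= 1:
        raise SimulationError(f"I0 {I0} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_cases = int(round(I0 * n))
    stages = np.full(n, SUSCEPTIBLE, dtype=np.int8)
    if phis is None:
        phis = np.empty(n)
        idx = rng.permutation(n)
        low, high = idx[:n_cases], idx[n_cases:]
        phis[low] = rng.uniform(0.05, theta_liability, size=low.size)
        phis[high] = rng.uniform(theta_liability, 1.0, size=high.size)
    else:
        phis = np.asarray(phis, dtype=float)
        if phis.shape != (n,):
            raise SimulationError("phis must have one entry per agent")
        low = np.argsort(phis, kind="stable")[:n_cases]
    stages[low] = ASYMPTOMATIC
    return stages, phis


# --------------------------------------------------------------------------
# presence tables


def _presence_by_day(records: Sequence[CheckinRecord],
                     visitor_index: Mapping[str, int],
                     horizon_days: int,
                     t0: float = 0.0) -> dict[tuple[int, str], tuple[np.ndarray, np.ndarray]]:
    """Per (day, venue): co-present visitor indices and day fractions.

    Session times are hours relative to ``t0``; open sessions are treated
    as lasting to the horizon.  Fractions are capped at 1 (a visitor with
    several overlapping sessions in one venue cannot exceed a full day).
    """
    horizon_h = horizon_days * HOURS_PER_DAY
    rows_vis, rows_ven, rows_day, rows_hours = [], [], [], []
    venues = sorted({r.venue for r in records})
    venue_index = {v: i for i, v in enumerate(venues)}
    t_in = np.array([_hours(r.t_in, t0) for r in records])
    t_out = np.array([horizon_h if r.t_out is None else _hours(r.t_out, t0)
                      for r in records])
    vis = np.array([visitor_index[r.visitor] for r in records], dtype=np.int64)
    ven = np.array([venue_index[r.venue] for r in records], dtype=np.int64)
    t_in = np.clip(t_in, 0.0, horizon_h)
    t_out = np.clip(t_out, 0.0, horizon_h)
    keep = t_out > t_in
    t_in, t_out, vis, ven = t_in[keep], t_out[keep], vis[keep], ven[keep]

    d0 = np.floor(t_in / HOURS_PER_DAY).astype(np.int64)
    d1 = np.ceil(t_out / HOURS_PER_DAY).astype(np.int64) - 1
    max_span = int((d1 - d0).max()) if d0.size else 0
    for j in range(max_span + 1):
        day = d0 + j
        sel = day <= d1
        if not sel.any():
            break
        day_s = day[sel]
        lo = np.maximum(t_in[sel], day_s * HOURS_PER_DAY)
        hi = np.minimum(t_out[sel], (day_s + 1) * HOURS_PER_DAY)
        rows_vis.append(vis[sel])
        rows_ven.append(ven[sel])
        rows_day.append(day_s)
        rows_hours.append(hi - lo)

    if not rows_vis:
        return {}
    df = pd.DataFrame({
        "visitor": np.concatenate(rows_vis),
        "venue": np.concatenate(rows_ven),
        "day": np.concatenate(rows_day),
        "hours": np.concatenate(rows_hours),
    })
    grouped = df.groupby(["day", "venue", "visitor"], sort=True)["hours"].sum()
    grouped = grouped.clip(upper=HOURS_PER_DAY).reset_index()
    table: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    for (day, ven_i), sub in grouped.groupby(["day", "venue"], sort=True):
        table[(int(day), venues[ven_i])] = (
            sub["visitor"].to_numpy(),
            (sub["hours"] / HOURS_PER_DAY).to_numpy(),
        )
    return table


# --------------------------------------------------------------------------
# daily transmission step


def step_day(day: int,
             presence: Mapping[tuple[int, str], tuple[np.ndarray, np.ndarray]],
             stages: np.ndarray, stage_entry: np.ndarray,
             params: SimParams, rng: np.random.Generator) -> None:
    """Advance stages at the start of ``day``, then run venue transmission.

    Mutates ``stages`` and ``stage_entry`` in place.  New infections use
    the susceptible set as of the start of the day (simultaneous update):
    for each infectious agent the number of susceptibles among its distinct
    uniform contacts is hypergeometric, infections among those are binomial
    in β, and the infected identities are a uniform subset of the venue's
    susceptibles — equivalent in distribution to drawing the contact set
    explicitly, one agent at a time.
    """
    # stage clock
    to_infectious = (stages == ASYMPTOMATIC) & \
        (day - stage_entry >= params.asymptomatic_days)
    stages[to_infectious] = INFECTIOUS
    stage_entry[to_infectious] = day
    to_recovered = (stages == INFECTIOUS) & \
        (day - stage_entry >= params.infectious_days)
    stages[to_recovered] = RECOVERED
    stage_entry[to_recovered] = day

    newly_infected: set[int] = set()
    for (d, venue), (visitors, fracs) in presence.items():
        if d != day:
            continue
        n_present = visitors.size
        if n_present < 2:
            continue
        present_stages = stages[visitors]
        inf_mask = present_stages == INFECTIOUS
        if not inf_mask.any():
            continue
        sus_idx = visitors[present_stages == SUSCEPTIBLE]
        n_sus = sus_idx.size
        if n_sus == 0:
            continue
        draws = np.minimum(
            np.rint(params.contacts_per_day * fracs[inf_mask]).astype(np.int64),
            n_present - 1)
        draws = draws[draws > 0]
        if draws.size == 0:
            continue
        # a contacted agent is susceptible or not by hypergeometric sampling
        contacted_sus = rng.hypergeometric(
            ngood=n_sus, nbad=n_present - 1 - n_sus, nsample=draws)
        hits = rng.binomial(contacted_sus, params.beta)
        for h in hits[hits > 0]:
            chosen = sus_idx[rng.choice(n_sus, size=int(h), replace=False)]
            newly_infected.update(int(c) for c in chosen)

    if newly_infected:
        idx = np.fromiter(newly_infected, dtype=np.int64)
        stages[idx] = ASYMPTOMATIC
        stage_entry[idx] = day


# --------------------------------------------------------------------------
# access-control replay


def apply_access_control(records: Sequence[CheckinRecord],
                         phi_by_visitor: Mapping[str, float],
                         venues: Sequence[Venue],
                         params: SimParams,
                         horizon_days: int,
                         t0: float = 0.0) -> list[CheckinRecord]:
    """Replay a check-in stream through per-venue priority admission.

    Each venue admits at most ``s`` concurrent visitors, where ``s`` is
    refreshed every midnight from the venue's availability ω (member risk
    from currently-present low-liability visitors, propagation risk from
    the historical transition structure of the raw stream, crowdedness from
    the current head count).  Excess arrivals wait in priority order; a
    waiting visit is cancelled once its original check-out time passes.
    Admitted sessions keep their original check-out time, so every shifted
    ``t_in`` shortens the visit.
    """
    if not records:
        return []
    theta = params.theta_liability
    beta = params.beta
    m = params.priority_classes
    capacity = {v.venue_id: v.capacity for v in venues}
    venue_ids = [v.venue_id for v in venues]
    ln_surv = math.log1p(-beta)

    # historical transition ratios n_i/m_i per target venue, from the raw stream
    ratios: dict[str, dict[str, float]] = {}
    for target in venue_ids:
        stats = transition_stats(records, target)
        ratios[target] = {
            src: (stats.n.get(src, 0) / m_i) if m_i > 0 else 0.0
            for src, m_i in stats.m.items()
        }

    # event loop: arrivals, departures and midnight capacity refreshes
    # (all event times in hours since the stream origin)
    ARRIVE, DEPART, MIDNIGHT = 0, 1, 2
    horizon_h = horizon_days * HOURS_PER_DAY
    events: list[tuple[float, int, int, object]] = []
    for i, rec in enumerate(records):
        t_in = _hours(rec.t_in, t0)
        t_end = horizon_h if rec.t_out is None else _hours(rec.t_out, t0)
        if t_end <= max(t_in, 0.0) or t_in >= horizon_h:
            continue
        events.append((max(t_in, 0.0), ARRIVE, i, rec))
    for d in range(1, horizon_days + 1):
        events.append((d * HOURS_PER_DAY, MIDNIGHT, -d, None))
    heapq.heapify(events)

    # occupancy is counted in concurrent sessions (entry slots), the same
    # unit as the capacity N_c and the queueing servers
    occ: dict[str, int] = {v: 0 for v in venue_ids}
    occ_low: dict[str, int] = {v: 0 for v in venue_ids}
    servers: dict[str, int] = dict(capacity)  # day 0: empty venues, omega = 1
    waiting: dict[str, list[tuple[int, int, float, CheckinRecord]]] = \
        {v: [] for v in venue_ids}
    admitted: list[CheckinRecord] = []
    seq = 0

    def try_admit(venue: str, now: float) -> None:
        q = waiting[venue]
        while q and occ[venue] < servers[venue]:
            _, _, t_end, rec = heapq.heappop(q)
            if t_end <= now:
                continue  # visit window already closed: cancelled
            low = phi_by_visitor.get(rec.visitor, 0.0) < theta
            occ[venue] += 1
            occ_low[venue] += low
            admit_t = max(now, _hours(rec.t_in, t0))
            admitted.append(CheckinRecord(
                visitor=rec.visitor, venue=rec.venue,
                t_in=admit_t * SECONDS_PER_HOUR + t0,
                t_out=rec.t_out, reason=rec.reason,
                liability=phi_by_visitor.get(rec.visitor)))
            heapq.heappush(events, (t_end, DEPART, seq_next(), (venue, low)))

    def seq_next() -> int:
        nonlocal seq
        seq += 1
        return seq

    def refresh_servers() -> None:
        for v in venue_ids:
            R1 = occ_low[v]
            R2 = sum(occ_low.get(src, 0) * ratio
                     for src, ratio in ratios[v].items())
            R3 = occ[v] / capacity[v]
            omega = math.exp(ln_surv * (R1 + R2) * R3)
            servers[v] = max(1, math.floor(omega * capacity[v]))

    while events:
        now, kind, _, payload = heapq.heappop(events)
        if kind == MIDNIGHT:
            refresh_servers()
            for v in venue_ids:
                try_admit(v, now)
        elif kind == DEPART:
            venue, low = payload
            occ[venue] -= 1
            occ_low[venue] -= low
            try_admit(venue, now)
        else:  # ARRIVE
            rec = payload
            phi = phi_by_visitor.get(rec.visitor, 0.0)
            k = priority_of(phi, m)
            t_end = horizon_h if rec.t_out is None else _hours(rec.t_out, t0)
            heapq.heappush(waiting[rec.venue], (k, seq_next(), t_end, rec))
            try_admit(rec.venue, now)

    admitted.sort(key=lambda r: (r.t_in, r.visitor, r.venue))
    return admitted


# --------------------------------------------------------------------------
# full run


def run_simulation(records: Sequence[CheckinRecord],
                   phi_by_visitor: Mapping[str, float],
                   venues: Sequence[Venue],
                   params: SimParams,
                   horizon_days: int | None = None) -> SimResult:
    """Replay a check-in stream and return the daily stage-count series."""
    if not records:
        raise SimulationError("empty check-in stream")
    t0 = min(r.t_in for r in records)
    if horizon_days is None:
        t_max = max((r.t_out if r.t_out is not None else r.t_in)
                    for r in records)
        horizon_days = int(math.ceil(_hours(t_max, t0) / HOURS_PER_DAY)) or 1

    visitor_ids = sorted(phi_by_visitor)
    visitor_index = {v: i for i, v in enumerate(visitor_ids)}
    unknown = {r.visitor for r in records} - set(visitor_index)
    if unknown:
        raise SimulationError(
            f"{len(unknown)} visitors in the stream have no liability score")
    n = len(visitor_ids)
    phis = np.array([phi_by_visitor[v] for v in visitor_ids])

    stages, phis = seed_infections(
        n, params.I0, params.seed, params.theta_liability, phis=phis)
    stage_entry = np.zeros(n, dtype=np.int64)

    stream = records
    if params.control_on:
        stream = apply_access_control(
            records, phi_by_visitor, venues, params, horizon_days, t0=t0)
    presence = _presence_by_day(stream, visitor_index, horizon_days, t0=t0)

    rng = np.random.default_rng(params.seed)
    rows = []
    for day in range(horizon_days):
        step_day(day, presence, stages, stage_entry, params, rng)
        counts = np.bincount(stages, minlength=4)
        rows.append({
            "day": day,
            "susceptible": int(counts[SUSCEPTIBLE]),
            "asymptomatic": int(counts[ASYMPTOMATIC]),
            "infectious": int(counts[INFECTIOUS]),
            "recovered": int(counts[RECOVERED]),
            "active_cases": int(counts[ASYMPTOMATIC] + counts[INFECTIOUS]),
        })
    return SimResult(pd.DataFrame(rows))
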