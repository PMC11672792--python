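"""Priority-queue access control: the M/M/s non-preemptive priority model.

Visitors arriving at a venue form an M/M/s queue with ``m`` priority
classes: class-``i`` arrivals are Poisson with rate λᵢ, service (the visit
itself) is exponential with rate μ = 1/T at each of ``s`` servers (the
venue's available entry slots), and a freed server always takes the
highest-priority waiting visitor, first-come-first-served within a class,
never interrupting a visit in progress.

The liability score sets the class through the reciprocal map
``k = clamp(ceil(1/φ), 1, m)`` (an unfilled form, φ = 0, lands in the lowest
class ``m``), and the venue's availability sets the server count through
``s = max(1, floor(ω · N_c))``.

The mean queue wait of class ``k`` is the classical non-preemptive priority
result

    W_k = A⁻¹ / ((1 − σ_{k−1})(1 − σ_k)),
    A   = s!(1 − ρ)(sμ) Σ_{i=0}^{s−1} (sρ)^{i−s}/i!  +  sμ,

with cumulative utilizations σ_r = Σ_{i≤r} ρᵢ (σ_0 = 0), ρᵢ = λᵢ/(sμ),
ρ = λ/(sμ).  At m = 1 this collapses to the Erlang-C delay, implemented
separately in :func:`erlang_c_wq` as an independent cross-check, and the
per-class waits obey the conservation law Σ (λ_k/λ) W_k = W_FCFS.

Waits are queue delay only; service time is excluded.  Stability requires
σ_m < 1 — the per-class condition ρᵢ < 1 alone is not sufficient.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "QueueParams",
    "WaitingTimes",
    "DESResult",
    "EntryQueue",
    "QueueError",
    "InstabilityError",
    "priority_of",
    "capacity_servers",
    "waiting_times",
    "erlang_c_wq",
    "simulate_queue_des",
]


class QueueError(ValueError):
    pass


class InstabilityError(QueueError):
    """The queue is saturated for some reported class."""

    def __init__(self, k: int, sigma_k: float):
        self.k = k
        self.sigma_k = sigma_k
        super().__init__(
            f"priority classes 1..{k} saturate the venue "
            f"(cumulative utilization sigma_{k} = {sigma_k:.4f} >= 1)")


def priority_of(phi: float, m: int) -> int:
    """Map liability φ ∈ [0, 1] to a priority class k ∈ 1..m.

    Safer visitors (higher φ) get lower k, hence earlier entry; φ = 0 (no
    form filled) maps to the lowest priority m.
    """
    if not 0 <= phi <= 1:
        raise QueueError(f"phi {phi} outside [0, 1]")
    if m < 1:
        raise QueueError(f"need at least one priority class, got m={m}")
    if phi == 0:
        return m
    return min(max(math.ceil(1.0 / phi), 1), m)


def capacity_servers(omega: float, N_c: int) -> int:
    """Available entry slots s = floor(ω · N_c), at least 1."""
    if not 0 < omega <= 1:
        raise QueueError(f"omega {omega} outside (0, 1]")
    if N_c < 1:
        raise QueueError(f"capacity must be >= 1, got {N_c}")
    return max(1, math.floor(omega * N_c))


@dataclass(frozen=True)
class QueueParams:
    """Arrival rates per priority class, service rate and server count.

    Rates are per hour; ``mu = 1/T`` with T the mean dwell time in hours.
    """

    lambdas: tuple[float, ...]
    mu: float
    s: int

    def __post_init__(self):
        if len(self.lambdas) < 1:
            raise QueueError("need at least one priority class")
        if any(lam < 0 for lam in self.lambdas):
            raise QueueError("arrival rates must be nonnegative")
        if self.mu <= 0:
            raise QueueError(f"service rate must be positive, got {self.mu}")
        if self.s < 1:
            raise QueueError(f"server count must be >= 1, got {self.s}")

    @property
    def m(self) -> int:
        return len(self.lambdas)

    @property
    def lam(self) -> float:
        return sum(self.lambdas)

    @property
    def rho(self) -> float:
        return self.lam / (self.s * self.mu)

    def rho_i(self, i: int) -> float:
        return self.lambdas[i - 1] / (self.s * self.mu)

    def sigma(self, r: int) -> float:
        """Cumulative utilization of classes 1..r (σ_0 = 0)."""
        if r == 0:
            return 0.0
        return sum(self.lambdas[:r]) / (self.s * self.mu)

    @property
    def stable(self) -> bool:
        return self.sigma(self.m) < 1.0

    def check_stability(self) -> None:
        for k in range(1, self.m + 1):
            if self.sigma(k) >= 1.0:
                raise InstabilityError(k, self.sigma(k))


@dataclass(frozen=True)
class WaitingTimes:
    """Per-class mean queue waits W_k (hours), nondecreasing in k."""

    W: tuple[float, ...]

    def __getitem__(self, k: int) -> float:
        """1-based class index, matching the k in W_k."""
        return self.W[k - 1]


def _inverse_bracket(params: QueueParams) -> float:
    """A⁻¹ for the bracket term of the priority-wait formula.

    Evaluated in log space (s! and (sρ)^{i−s} overflow beyond s ≈ 170).
    """
    s, mu, rho = params.s, params.mu, params.rho
    smu = s * mu
    srho = s * rho  # = lam / mu, the offered load
    if srho == 0:
        return 1.0 / smu  # λ = 0: bracket reduces to sμ
    log_sfact = math.lgamma(s + 1)
    total = 0.0
    for i in range(s):
        total += math.exp(log_sfact + (i - s) * math.log(srho) - math.lgamma(i + 1))
    A = (1.0 - rho) * smu * total + smu
    return 1.0 / A


def waiting_times(params: QueueParams) -> WaitingTimes:
    """Mean queue wait per priority class in the M/M/s priority queue."""
    params.check_stability()
    inv_A = _inverse_bracket(params)
    W = tuple(
        inv_A / ((1.0 - params.sigma(k - 1)) * (1.0 - params.sigma(k)))
        for k in range(1, params.m + 1)
    )
    return WaitingTimes(W)


def waiting_time_for_class(params: QueueParams, k: int) -> float:
    """Mean queue wait of class ``k`` alone (requires only σ_k < 1)."""
    if not 1 <= k <= params.m:
        raise QueueError(f"class {k} outside 1..{params.m}")
    if params.sigma(k) >= 1.0:
        raise InstabilityError(k, params.sigma(k))
    inv_A = _inverse_bracket(params)
    return inv_A / ((1.0 - params.sigma(k - 1)) * (1.0 - params.sigma(k)))


def erlang_c_wq(lam: float, mu: float, s: int) -> float:
    """Mean queue delay of a single-class M/M/s (Erlang-C) system.

    Independent of :func:`waiting_times`: uses the Erlang-B recursion
    B(k, a) = aB/(k + aB) and C = B / (1 − ρ(1 − B)), then Wq = C/(sμ − λ).
    """
    if lam < 0 or mu <= 0 or s < 1:
        raise QueueError("need lam >= 0, mu > 0, s >= 1")
    if lam == 0:
        return 0.0
    if lam >= s * mu:
        raise QueueError(f"saturated: lam={lam} >= s*mu={s * mu}")
    a = lam / mu
    B = 1.0
    for k in range(1, s + 1):
        B = a * B / (k + a * B)
    rho = lam / (s * mu)
    C = B / (1.0 - rho * (1.0 - B))
    return C / (s * mu - lam)


# --------------------------------------------------------------------------
# discrete-event validation


@dataclass(frozen=True)
class DESResult:
    """Empirical per-class waits from the event-driven simulation."""

    mean: tuple[float, ...]
    se: tuple[float, ...]
    n: tuple[int, ...]


def simulate_queue_des(params: QueueParams, horizon: float, seed: int,
                       warmup_fraction: float = 0.1,
                       n_batches: int = 32) -> DESResult:
    """Event-driven simulation of the M/M/s non-preemptive priority queue.

    Poisson arrivals per class (generated as a superposed stream with
    class labels drawn proportionally to λᵢ), exponential service at ``s``
    identical servers, highest-priority-first dispatch, FCFS within class.
    Waits recorded after a warm-up window are summarized per class with
    batch-means standard errors (waits are serially correlated, so a naive
    SE would be optimistic).
    """
    rng = np.random.default_rng(seed)
    m, s, mu = params.m, params.s, params.mu
    lam = params.lam
    if lam == 0:
        return DESResult((0.0,) * m, (0.0,) * m, (0,) * m)
    class_p = np.asarray(params.lambdas) / lam

    waits: list[list[float]] = [[] for _ in range(m)]
    waiting: list[tuple[int, float, int]] = []  # (k, t_arr, seq) min-heap
    departures: list[float] = []  # min-heap of in-service completion times
    warmup = warmup_fraction * horizon
    t = rng.exponential(1.0 / lam)
    seq = 0
    while t < horizon or waiting:
        if departures and (t >= horizon or departures[0] <= t):
            now = heapq.heappop(departures)
            if waiting:
                k, t_arr, _ = heapq.heappop(waiting)
                if t_arr > warmup:
                    waits[k - 1].append(now - t_arr)
                heapq.heappush(departures, now + rng.exponential(1.0 / mu))
            continue
        if t >= horizon:
            break  # no departures pending, only the closed arrival stream
        k = int(rng.choice(m, p=class_p)) + 1
        if len(departures) < s:
            if t > warmup:
                waits[k - 1].append(0.0)
            heapq.heappush(departures, t + rng.exponential(1.0 / mu))
        else:
            seq += 1
            heapq.heappush(waiting, (k, t, seq))
        t += rng.exponential(1.0 / lam)

    means, ses, ns = [], [], []
    for w in waits:
        arr = np.asarray(w)
        ns.append(arr.size)
        if arr.size == 0:
            means.append(0.0)
            ses.append(0.0)
            continue
        means.append(float(arr.mean()))
        nb = min(n_batches, max(1, arr.size // 4))
        batches = np.array_split(arr, nb)
        bm = np.array([b.mean() for b in batches if b.size])
        if bm.size > 1:
            ses.append(float(bm.std(ddof=1) / math.sqrt(bm.size)))
        else:
            ses.append(float(arr.std(ddof=1) / math.sqrt(arr.size))
                       if arr.size > 1 else 0.0)
    return DESResult(tuple(means), tuple(ses), tuple(ns))


# --------------------------------------------------------------------------
# head-of-queue wait assignment


@dataclass
class _Waiter:
    anon_id: str
    k: int
    seq: int


@dataclass
class EntryQueue:
    """Waiting line at one venue under the head-of-queue wait policy.

    Arrivals are held in priority order (k ascending, FCFS within class).
    The head of the queue is told the analytic mean wait W_k for its class;
    whenever the head enters the venue, the displayed wait is recomputed for
    the new head.  If the venue is saturated for the arrival's class, the
    arrival is deferred with a ``venue saturated`` status instead of being
    promised a (divergent) wait.
    """

    params: QueueParams
    _heap: list[tuple[int, int, _Waiter]] = field(default_factory=list)
    _seq: int = 0

    def __len__(self) -> int:
        return len(self._heap)

    @property
    def head(self) -> _Waiter | None:
        return self._heap[0][2] if self._heap else None

    def head_wait(self) -> float | None:
        """Scheduled wait currently displayed to the queue head (hours)."""
        if not self._heap:
            return None
        return waiting_time_for_class(self.params, self.head.k)

    def assign_wait(self, anon_id: str, k: int) -> tuple[str, float | None]:
        """Append an arrival; returns (status, scheduled wait if head).

        Status is ``"head"`` (with the displayed W_k), ``"queued"`` (wait
        will be assigned on promotion to head) or ``"venue saturated"``
        (class k is unstable; the arrival is not enqueued).
        """
        if not 1 <= k <= self.params.m:
            raise QueueError(f"class {k} outside 1..{self.params.m}")
        if self.params.sigma(k) >= 1.0:
            return "venue saturated", None
        self._seq += 1
        waiter = _Waiter(anon_id, k, self._seq)
        heapq.heappush(self._heap, (k, self._seq, waiter))
        if self.head is waiter:
            return "head", self.head_wait()
        return "queued", None

    def admit_head(self) -> tuple[_Waiter, float | None]:
        """Head enters the venue; returns it plus the new head's wait."""
        if not self._heap:
            raise QueueError("queue is empty")
        _, _, admitted = heapq.heappop(self._heap)
        return admitted, self.head_wait()
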