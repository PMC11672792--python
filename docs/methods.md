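# Methods

This note documents the models implemented in `healthpass`, the default
parameters and where they come from, what the synthetic campus generator
does and does not emulate, and the numerical and design choices made where
the design was genuinely open.

## Liability scoring

The score φ(u) is the area of the six-axis radar polygon spanned by the
rubric scores V, normalized by the area at the per-axis upper bounds V̂.
Because each area term couples cyclically adjacent axes
(`Σ V_i·V_{(i+1) mod 6}`; the common `½·sin(60°)` factor cancels), the
score is order-dependent. The axis order is therefore fixed —
(Home, Workplace, TravelRecord, MeansOfTransport, Symptoms, CloseContact) —
and recorded in the rubric file; any reordering changes φ and would break
reproducibility.

Consequences worth knowing:

* φ = 0 whenever no two adjacent axes are both positive (e.g. the
  alternating vector (5,0,5,0,5,0)); a form with isolated answers scores
  zero area even though items were filled.
* φ is monotone nondecreasing in every component and scale-equivariant
  (multiplying V and V̂ jointly by c > 0 leaves φ unchanged). Both
  properties are verified exhaustively over the {0..5}⁶ lattice.
* Classification is strict: φ < θ ⇒ low-liability; the boundary φ = θ is
  acceptable. Default θ = 0.8.

The shipped rubric (residence/travel tiers 1–5 following five-tier regional
risk grading, public transport scored low, symptoms and close contact by
severity) is an explicit configuration default, not a normative standard:
the tier definitions are governmental and change over an epidemic's course.

## Venue availability

ω(v) = (1−β)^((R1+R2)·R3) is read as survival over an expected number of
risky contacts: R1+R2 potential low-liability contacts, scaled by the
crowdedness ratio R3 = N/N_c. R3 is deliberately *not* capped at 1 — an
over-capacity venue multiplies contact opportunities. β = R₀/τ with
R₀ = 2.24 and τ = contacts/day × infectious days = 50 × 15 = 750, giving
β ≈ 0.002987. The 15 infectious days derive from a 21-day disease course
minus a 6-day non-infectious initial period.

For R2, a "transfer" from venue i is a visitor's check-out followed by
their next check-in within a linkage window (default 2 h). The window is a
design choice — without it, a check-in days later would count as a
transfer. Sources with no linked departures contribute zero (the ratio
n_i/m_i is otherwise undefined; zero is the conservative limit). Open
sessions never enter history-based statistics.

## Priority queueing

The per-class mean wait uses the classical non-preemptive M/M/s priority
form `W_k = A⁻¹/((1−σ_{k−1})(1−σ_k))`, with σ_r the cumulative utilization
of classes 1..r and σ₀ = 0, and A the standard M/M/s bracket
`s!(1−ρ)(sμ)Σ_{i<s}(sρ)^{i−s}/i! + sμ`. The bracket is evaluated in log
space (`lgamma`), so server counts in the hundreds remain stable. Waits
are queue delay only; service time is excluded.

Three independent validations are wired into the tests:

1. at m = 1 the expression equals the Erlang-C delay (implemented
   separately via the Erlang-B recursion) to < 10⁻¹⁰ relative error over
   an (s, ρ) grid;
2. the conservation law Σ(λ_k/λ)W_k = W_FCFS holds to < 10⁻¹⁰ (identical
   exponential service across classes);
3. a hand-written event-driven simulator (heap of departures, priority
   heap of waiters, superposed Poisson arrivals) reproduces every class
   mean within 3 batch-means standard errors. Batch means are used because
   successive waits are serially correlated and a naive SE would be
   optimistic.

Stability is enforced as σ_m < 1; the per-class condition ρ_i < 1 is
necessary but not sufficient, and a saturated class raises an explicit
error naming the first saturated class rather than returning a negative
wait.

Two integerizations are needed around the queue. The liability-to-class
map is the clamped reciprocal `k = clamp(ceil(1/φ), 1, m)` (φ = 0 maps to
the lowest priority m): priorities must be integer class indices and lower
k must mean safer visitor. The server count is `s = max(1, floor(ω·N_c))`:
a venue with positive availability must admit someone eventually. An
alternative reading — binning φ by quantiles into classes — is possible;
the reciprocal map is recorded as the package's assumption.

## Epidemic replay

Venues are well-mixed compartments; spatial trajectories inside a venue
are presentation, not epidemiology, and are out of scope. Per venue-day,
an infectious agent present for a fraction f of the day draws
`min(round(50·f), N−1)` distinct uniform contacts from the co-present set;
each susceptible contact is infected with probability β. Sampling is done
in distribution-exact form: the susceptible count among the contacts is
hypergeometric, infections among those binomial(β), and the infected
identities a uniform subset of the venue's susceptibles — equivalent to
drawing the contact set explicitly, but vectorizable. Infections use the
susceptible set at the start of the day (simultaneous update); newly
infected agents are non-infectious that day and for the following
asymptomatic period.

Stages are susceptible → asymptomatic → infectious → recovered, ticked
once per day. The "exposed" and "asymptomatic" phases are merged into one
6-day non-infectious period: only the 6/21-day split is pinned down, and
asymptomatic agents cannot transmit, so a finer split would be
unidentifiable. Seeding assigns exactly `round(I0·n)` agents to start
asymptomatic; these are the low-liability visitors (φ < θ), so the initial
infection rate equals the initial low-liability fraction. Liability and
disease state are independent after seeding — recovered visitors keep
their low φ and low queue priority.

### Access-control replay semantics

With control on, the stream is first replayed through per-venue admission
queues before the disease process runs (liability is fixed at seeding, so
the admission process does not depend on the evolving disease state):

* Occupancy is counted in concurrent *sessions* — the same unit as the
  capacity N_c, the crowdedness ratio R3 and the queueing servers.
* Every midnight each venue recomputes ω from its current state (R1 from
  low-liability sessions inside, R2 from the raw stream's historical
  transition ratios weighted by current low-liability counts, R3 from the
  head count) and sets s = max(1, floor(ω·N_c)). The daily cadence matches
  the one-day epidemic tick; a finer cadence changes little because ω
  moves with slowly-varying occupancy.
* Arrivals beyond s wait in priority order (class k ascending, FCFS
  within class) and are admitted as slots free. The check-out time is
  *not* shifted: waiting eats into the visit, and a visit whose window
  closes before admission is cancelled. This is the reading under which
  both stated behaviours — shifted check-in times and occupancy respecting
  s — hold simultaneously, and it is what gives the policy its epidemic
  effect: if shifted visits kept their full duration, control would merely
  translate contact hours in time and barely change transmission.

## Synthetic campus

The generator emulates the statistical shape the models assume: homogeneous
Poisson chain starts per venue, exponential dwells, venue-to-venue
transfers from a row-stochastic matrix (continuation probability 0.4, gap
uniform on [0, 30 min]), visitors drawn with replacement (dispersed
per-visitor session counts), and voluntary forms sampled from the rubric's
answer sets with a rejection step pinning the low-liability fraction to I0.

The deployment-scale default reproduces the study deployment's scale:
1,416 visitors, five venues, a 62-day horizon, and chain-start rates tuned
so the expected session count is 128,656 (`starts = sessions·(1−p)`;
end-of-horizon truncation loses ≈ 1%, within the 5% tolerance the tests
allow). Venue traffic shares, dwells and capacities are not recorded
anywhere for the original campus and are package defaults chosen by the
following a-priori reasoning:

* **Long dwells.** Contacts are prorated by presence (50·f per venue-day),
  so the epidemic grows only if visitors spend most of the day on campus:
  with ~1.47 sessions per visitor-day (fixed by 128,656/62/1,416), a
  session-share-weighted mean dwell of ~12 h gives ≈ 17–18 presence
  hours/visitor-day, hence ~36 contact draws/day and an effective
  reproduction number ≈ 1.6 — an epidemic that rises and peaks inside the
  horizon, the regime the flatten-the-curve comparison needs. Venues are
  therefore long-dwell campus zones: dormitory (16 h, 45% of chain
  starts), academic building (12 h, 28%), library (10 h, 13%), canteen
  (2 h, 9%), gym (3 h, 5%).
* **Tight capacities.** Capacities are 1.05× each venue's expected
  steady-state session occupancy, so peak-hour demand reaches the
  admission constraint and the availability feedback (more low-liability
  inside → lower ω → fewer slots) has traction, as in the deployed
  system, whose own case study shows occupancy held at capacity by
  extended waits. At this margin the replay removes roughly a third of
  low-liability presence hours and under a tenth of overall hours.

What the generator does **not** emulate: diurnal/weekday arrival profiles
(arrivals are time-homogeneous), the real campus's heavy-tailed per-user
check-in distribution (only qualitatively dispersed), reasons-for-visit
text, and any spatial structure. Passing tests therefore demonstrate the
mechanisms — not calibrated forecasts for a real campus; the deployment's
headline curve numbers (peak 1302 → 471, day 11 → 19) depend on the
undeposited real check-in data and are deliberately not targets.

## Problem sizes and runtimes

The test suite and the acceptance script run everything at the scale named
above: 10 paired deployment-scale replays for the flatten-the-curve
property (a paired run takes ~2 s), 5-seed means per I0 for the ordering
check, 1,000 replicates for the single-day transmission calibration,
~40,000 simulated arrivals per queueing DES configuration. These sizes
give 3-SE margins comfortably narrower than the effects being tested
while keeping the full suite under a minute of compute.

## Numerical choices and degenerate inputs

* Timestamps: epoch seconds internally, ISO-8601 with offset on disk;
  sessions are half-open [t_in, t_out) so occupancy never double-counts a
  visitor at a transition instant.
* Peak metrics break ties by first attainment.
* `round2` uses decimal half-up rounding (presentation convention for
  reported means and percentages).
* Division-by-zero guards: empty venues give R3 = 0 and ω = 1; sources
  with no departures contribute 0 to R2; λ = 0 queues have zero wait.
* All randomness flows from seeded `numpy` generators; identical seeds
  give bit-identical streams, replays and series.

## Known limitations

* The admission replay refreshes server counts daily and drops visits
  whose windows close; real deployments would re-negotiate visit windows.
* Waiting-time displays for a stable class in a globally saturated queue
  use the printed bracket expression, which is exact only below overall
  saturation.
* The merged exposed/asymptomatic stage makes the early epidemic slightly
  more synchronized than a four-stage model with separate durations.
* Survey scoring reports the learnability dimension as the mean of items
  4 and 10 per the standard two-factor split; published per-dimension
  values derived with other item groupings will not match.
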