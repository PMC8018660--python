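# Methods

## Model overview

`emobook` simulates N (default 20) primate-like individuals on a continuous
300 x 300 toroidal arena.  One grid unit represents 1 m and one time step
1 min; only the active part of the day is modelled (a day is 720 min, a
year 350 days, so a simulated year is 252 000 min).  The environment is
purely social: there is no foraging, no energetics, and the only inputs to
an individual's state are its interactions with group mates.

Each individual carries

* a fixed dominance strength, `(N + 1 - rank)/N`, from 1.00 (top) to 0.05
  (bottom of a 20-rank ladder) — the hierarchy is stable by construction;
* a fixed, directed FEAR attitude toward each partner,
  `max(0, dom_other - dom_self)` normalized by the ladder's maximal gap;
* three dynamic emotional states in [0, 1] — arousal, anxiety,
  satisfaction — that relax exponentially toward their baselines;
* a directed, dynamic LIKE attitude toward each partner (N(N-1) = 380
  directed dyads at N = 20), raised only by *received* grooming and eroded
  only by time.  Grooming rates and LIKE are directed: `like[i, j]` need
  not equal `like[j, i]`, and nothing in the pipeline symmetrizes them.

## LIKE bookkeeping (the object of study)

Four update rules are compared, the cross of {linear, logistic} increase
with {exponential, logistic} decrease: *original* (linear + exponential),
*alternative* (logistic + logistic), and the two mixed rules *dynamics3*
(linear + logistic) and *dynamics4* (logistic + exponential).

All four are calibrated analytically from two speed contracts rather than
from free steepness constants:

* **LINC** (increase speed): uninterrupted grooming traverses the full
  LIKE range in exactly 10 / 30 / 60 min (fast / intermediate / slow).
  Linear slope `a = (ub - lb) / period`; logistic steepness
  `k_inc = 2 ln(99) / period`, because the clipped sigmoid spans
  logit(0.99) - logit(0.01) = 2 ln 99.
* **LHW** (decrease timescale): exponential decay halves LIKE every LHW
  minutes (`0.5^(x/LHW)`); logistic decay starting at the upper bound first
  crosses 0.5 after exactly LHW minutes (`k_dec = ln(99) / LHW`).

The logistic curves never reach 0 or 1, so they are clipped to
[0.01, 0.99]; the pure original dynamics keeps [0, 1] so that the printed
slope 1/period is exact.  For the mixed dynamics a logistic component
forces the clipped bounds, and the linear slope is rescaled to
`0.98/period` to keep the traversal-time contract exact.  `LHW = 0` is a
special very-fast rule: linear emptying of the full range in 50 min for an
exponential decrease, and LHW = 25 for a logistic decrease (the grid's
"0 or 25" pairing).

Updates are closed-form: increase inverts the sigmoid through the logit to
an effective time, advances it, and re-evaluates; decay likewise.  Both
operators obey the semigroup law (composing updates equals one update over
the summed duration), which licenses the engine's **lazy decay**: each
dyad stores its value with a last-update timestamp, and reads realize the
elapsed decay in one jump.  The test suite verifies the closed forms
against an independent step-wise numerical integration (RK4 at 1e-3-min
steps) of the curve derivatives.

## Event-driven engine

The scheduler repeatedly activates the individual with the smallest
personal clock (`myTIME`; ties broken by id), resolves one action, and
reschedules it one minute later.  Grooming bouts are chains of 1-minute
grooming actions with a continuation probability of 0.9/min (expected bout
about 10 min) that occupy both partners; the chain form keeps every LIKE
write timestamped at its own minute, so recording triggers that fall inside
a bout never see a future-stamped value.  A single seeded RNG stream drives
every stochastic decision; identical configuration and seed give
bit-identical outputs.  The hot loop is numba-compiled; the Python
functions in `agents.py`/`dynamics.py` define the same rules on the spec's
module surface and are tied to the compiled kernel by exact (update
formulas) and statistical (partner-choice frequencies) equivalence tests.

An activation resolves in this order:

1. being groomed — passively occupied;
2. continuing one's own grooming bout (probability 0.9/min; on bout end the
   groomer leaves with probability 0.5);
3. fleeing a recent aggressor (probability 0.8);
4. the arousal gate: with probability `1 - myAROUSAL`, rest;
5. perception: others within 50 grid units and +-60 degrees of heading; a
   scan event (probability `myPscan` = 0.2) widens the view to 360 degrees.
   A solitary individual searches persistently (directed walk);
6. anxiety: rises by 0.02 per much-feared individual (FEAR > 0.5) within
   5 units; an anxious individual (probability = anxiety) either avoids a
   close feared dominant or seeks its strongest established bond
   (LIKE >= 0.5) to groom — grooming is anxiolytic (-0.05/min for both);
7. agonism: with probability 0.02 an attack or aggressive signal at a
   lower-ranked perceived individual (anxiety +0.2 / +0.1 to the victim,
   who tends to flee next activation), or a submissive signal if only
   higher-ranked individuals are in view.  Agonism never touches LIKE;
8. the satiation gate: with probability `satiation_strength * satisfaction`
   the individual does not seek affiliation and instead random-walks,
   drifting back toward the perceived group's centroid when more than 20
   units away (group cohesion);
9. affiliative choice: a perceived partner is *proposed* with probability
   falling off with distance (`1/(1 + d)` weights — interaction opportunity
   is local) and *accepted* with probability
   `((1 - LPS) + LPS * LIKE) * (1 - 0.5 * FEAR)`.  Conditional on
   acceptance, partner frequencies equal the normalized LPS weighting;
   unconditionally, overall grooming propensity tracks the LIKE landscape,
   which is what lets differentiation feed back into behaviour.  An
   accepted partner is pursued for up to 30 min; within arm's reach
   (1 unit) a bout starts, otherwise the actor approaches (or, rarely,
   emits an affiliative signal).

Grooming raises the receiver's LIKE toward the actor by the increase curve,
raises satisfaction of *both* partners by 0.1/min (half-life 180 min), and
both partners' arousal briefly.  Giving grooming never raises the giver's
own LIKE.

### Why these sub-rules

The published description of this model family fixes the bookkeeping
curves, states, world constants and protocol precisely, but leaves the
behaviour-engine sub-rules qualitative.  The rules above were designed
against the reported emergent phenomena and have these roles:

* *satiation* bounds grooming at realistic levels (roughly 10-20 % of
  active time in equilibrium) and breaks the otherwise absorbing
  groom-forever pair lock;
* *proposal-acceptance* choice makes grooming volume itself LIKE-dependent,
  sharpening differentiation (a committee-style normalized choice produced
  a uniform mid-LIKE attractor instead);
* *both-partner satisfaction gain* reflects that affiliative contact is
  rewarding to groomer and groomee alike; a receiver-only gain left the
  groomer's drive unbounded;
* *anxiety-driven preferred-partner grooming* gives established bonds a
  dedicated maintenance channel, without which bond turnover is far too
  high; tying it to FEAR-proximity also reproduces up-hierarchy grooming
  by low-ranked individuals;
* *half-strength FEAR damping* (`1 - 0.5 FEAR`): full damping silenced all
  extreme-rank-gap dyads, contradicting the all-high slow-decay regime;
* *centroid cohesion* keeps the group a single compact party (mean
  pairwise distance ~15-25 units), as assumed by a purely social world.

All constants live in `BehaviorConfig` and are configurable.

## Protocol and recording

A run is a stabilization period of `max(6000, 30*LHW)` minutes (longer for
slower decay, which equilibrates more slowly) followed by a 2-year
recording period (504 000 min).  During recording the engine captures:
five LIKE snapshot matrices separated by half a year; daily LIKE samples
(for second-year averaging); the directed grooming-minutes matrix; and
symmetric pairwise proximity rates (fraction of 10-min samples with the
pair within 2 units).  A `scale` factor shrinks stabilization, recording,
snapshot spacing and the LIKE-sampling interval proportionally for
desk-scale work; the LIKE and emotion timescales themselves are never
scaled, so strongly scaled runs under-saturate slow-decay regimes (see
Limitations).

The sweep module builds the full factorial grid (2 dynamics x 3 LINC x
6 LHW x 4 LPS = 144 cells, 2 replicates, plus the 4 mixed-dynamics cells),
derives per-run seeds reproducibly from a base seed, executes runs
idempotently (completed cells are skipped by config hash) and writes
CSV/JSON products plus manifests.

## Analysis

* `second_year_mean`: per-dyad mean over samples in the second half of the
  recording clock (inclusive window).
* `categorize`: high (>= 0.75) / intermediate / low (<= 0.25) dyad counts
  and per-category means; the boundary convention follows the printed
  thresholds exactly.
* `transition_r2`: squared Pearson correlation over the 380 directed dyad
  values of two snapshots — affine-invariant, symmetric, and undefined
  (NaN) when a snapshot has no dyadic variance (all-low or all-high
  regimes); undefined transitions are excluded from the mean with a
  warning rather than coerced.
* `stability_score`: the four consecutive-transition R^2 values and their
  mean.  Under independence the null mean of r^2 is 1/(380 - 1).

## Synthetic fixtures

`generate_fixture_snapshots` emulates the *shape* of simulator output — a
sequence of directed LIKE snapshot matrices — without any behaviour: each
individual gets a planted set of near-ceiling dyads (0.9) against a
near-floor background (0.1), evolved as a per-dyad AR(1) process around the
range midpoint with persistence rho and Gaussian noise, clipped to
[0.01, 0.99].  With noise chosen to keep the dyad variance stationary, the
mean transition r^2 recovers rho^2; rho = 1 with zero noise freezes the
planted pattern, rho = 0 reproduces the null level.  The planted mask is
returned for recovery tests.  These fixtures deliberately lack everything
that makes real runs interesting — reciprocity, rank structure, volume
feedback — so tests that pass on them validate the *analysis stage* only,
not the simulator.

## Numerical choices

Sigmoid inversion is closed-form (logit), not iterative; exponents are
guarded against overflow far outside the clip range.  All schedule times
are integral minutes; snapshot spacing is rounded so five snapshots always
fit exactly.  Zero-variance guards use a 1e-9 range tolerance.  Per-run
seeds derive from `SeedSequence(base, spawn_key=(index,))` reduced below
2^31.

## Known limitations

* The behaviour-engine sub-rules are this package's own designs (see
  above); they reproduce the qualitative regime structure — all-low under
  very fast decay, all-high under very slow decay at full length, stronger
  and near-categorical differentiation under the alternative dynamics,
  stability ordered alternative/slow >> original/slow > original/fast >
  alternative/fast — and three of the four published stability magnitudes,
  but the alternative/slow stability plateaus around 0.5-0.7 rather than
  ~0.9: bond turnover per half-year remains higher than in the original
  implementation.
* Scaled-down runs shorten stabilization without scaling the LIKE
  timescales, so slow-decay (high-LHW) regimes do not reach their
  saturated all-high state at strong scaling; conclusions about those
  regimes require full-length runs.
* Kinship, age/sex classes, rank dynamics, coalitions and FEAR learning
  are out of scope; the hierarchy and FEAR matrix are fixed for a run.
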