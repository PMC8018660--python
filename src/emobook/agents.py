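"""Individual state, behaviour selection and interaction effects.

Each of the (default 20) primate-like individuals carries a fixed dominance
strength, a position on the torus, three dynamic emotional states (arousal,
anxiety, satisfaction), a fixed partner-specific FEAR row derived from the
dominance gap, and a dynamic partner-specific LIKE row maintained by the
bookkeeping curves in :mod:`emobook.dynamics`.

The behavioural repertoire is: groom, affiliative signal, attack,
aggressive signal, submissive signal, approach, leave, avoid, random walk
and rest.  Arousal gates activity; the LIKE-partner-selectivity parameter
(LPS) biases grooming-partner choice toward high-LIKE partners; FEAR damps
affiliation toward much higher-ranked individuals.  LIKE is changed by
affiliative behaviour and the passage of time only — never by agonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams, groom_increase, idle_decay
from .world import Position, WorldConfig, torus_distance, visible_others, wrap

__all__ = [
    "Individual",
    "AttitudeMatrix",
    "BehaviorConfig",
    "ACTIONS",
    "init_group",
    "fear_value",
    "partner_weights",
    "select_behavior",
    "execute_grooming",
    "execute_agonism",
]

ACTIONS = (
    "groom", "affiliative_signal", "attack", "aggressive_signal",
    "submissive_signal", "approach", "leave", "avoid", "random_walk", "rest",
)


@dataclass
class BehaviorConfig:
    """Behaviour-engine constants.

    ``lps`` is the LIKE-partner-selectivity of the study grid
    ({0.5, 0.9, 0.95, 0.99}; any value in [0, 1] is accepted).  The
    remaining couplings are qualitative in origin and configurable; the
    defaults keep activity levels non-degenerate (see the methods note).
    """

    lps: float = 0.99
    #: probability per minute that a grooming bout continues (expected bout ~10 min)
    groom_continuation: float = 0.9
    #: satisfaction gained by the receiver per received grooming minute
    satisfaction_gain: float = 0.1
    satisfaction_halflife: float = 180.0
    #: anxiety gained per received attack / aggressive signal
    anxiety_gain_attack: float = 0.2
    anxiety_gain_signal: float = 0.1
    anxiety_halflife: float = 120.0
    arousal_baseline: float = 0.5
    arousal_halflife: float = 60.0
    #: arousal bump for both partners at the start of an interaction
    arousal_bump: float = 0.1
    #: probability that an active decision is agonistic (directed down-hierarchy)
    agonism_prob: float = 0.02
    #: probability that a just-attacked individual flees on its next activation
    flee_prob: float = 0.8
    #: probability of signalling instead of approaching an out-of-reach partner
    affiliative_signal_prob: float = 0.05
    #: probability of leaving the partner when a grooming bout ends
    leave_prob: float = 0.5
    #: FEAR above which a nearby dominant triggers avoidance when anxious
    avoid_fear_threshold: float = 0.5
    avoid_distance: float = 5.0
    avoid_anxiety_threshold: float = 0.5
    #: preferred distance to the nearest group mate; beyond it, drift back
    cohesion_distance: float = 20.0
    #: fraction by which the maximal dominance gap damps affiliative choice
    fear_damping: float = 0.5
    #: how long a chosen grooming partner is pursued before giving up
    pursuit_minutes: float = 30.0
    #: how strongly satisfaction damps the drive to seek affiliation (0-1)
    satiation_strength: float = 1.0
    #: anxiety gained per activation per much-feared individual close by
    anxiety_gain_proximity: float = 0.02
    #: anxiety relieved per grooming minute, groomer and groomee alike
    anxiety_relief: float = 0.05
    view_angle_deg: float = 120.0
    pscan: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.lps <= 1.0:
            raise ValueError("lps must be in [0, 1]")


@dataclass
class Individual:
    """One agent.  ``rank`` 1 is the highest-ranked individual."""

    id: int
    rank: int
    dominance: float
    position: Position
    my_time: float = 0.0
    pscan: float = 0.2
    view_angle_deg: float = 120.0
    arousal: float = 0.5
    anxiety: float = 0.0
    satisfaction: float = 0.0
    fear_row: np.ndarray = field(default_factory=lambda: np.zeros(0))


class AttitudeMatrix:
    """Directed N x N LIKE values with per-dyad last-update timestamps.

    ``like[i, j]`` is individual ``i``'s valuation of ``j`` (actor ->
    partner); it need not equal ``like[j, i]``.  Values decay lazily: the
    stored number is exact at ``last_update[i, j]`` and :meth:`get` applies
    the elapsed idle decay on read without advancing the timestamp.
    """

    def __init__(self, n: int, params: DynamicsParams, t0: float = 0.0):
        self.n = n
        self.params = params
        self.like = np.full((n, n), params.lower_bound)
        np.fill_diagonal(self.like, np.nan)  # no self-LIKE
        self.last_update = np.full((n, n), t0)

    def get(self, actor: int, partner: int, now: float) -> float:
        if actor == partner:
            raise ValueError("no self-directed LIKE")
        gap = now - self.last_update[actor, partner]
        if gap < 0:
            raise RuntimeError("time reversal in LIKE read")
        return idle_decay(self.like[actor, partner], gap, self.params)

    def set(self, actor: int, partner: int, value: float, now: float) -> None:
        self.like[actor, partner] = value
        self.last_update[actor, partner] = now

    def snapshot(self, now: float) -> np.ndarray:
        """All decay realized up to ``now``; timestamps untouched."""
        out = np.empty_like(self.like)
        for i in range(self.n):
            for j in range(self.n):
                out[i, j] = np.nan if i == j else self.get(i, j, now)
        return out


def fear_value(dom_self: float, dom_other: float, max_gap: float = 0.95) -> float:
    """Fixed FEAR toward a partner: the dominance gap, normalized.

    Zero toward equally or lower-ranked partners; 1 for the maximal gap
    (0.05 vs 1.0 in the default 20-rank ladder, hence ``max_gap = 0.95``).
    """
    return max(0.0, dom_other - dom_self) / max_gap


def init_group(n: int, seed: int, params: DynamicsParams,
               world: WorldConfig | None = None,
               cfg: BehaviorConfig | None = None) -> tuple[list[Individual], AttitudeMatrix]:
    """A fresh group on random torus positions with the standard ladder.

    Dominance is ``(n + 1 - rank) / n``: 1.0 for rank 1 down to ``1/n``
    (0.05 for n = 20) for the lowest rank, a stable linear hierarchy.  All
    LIKE values start at the dynamics' lower bound.
    """
    if n < 2:
        raise ValueError("a group needs at least 2 individuals")
    world = world or WorldConfig()
    cfg = cfg or BehaviorConfig()
    rng = np.random.RandomState(seed)
    dominance = np.array([(n + 1 - r) / n for r in range(1, n + 1)])
    max_gap = dominance[0] - dominance[-1]
    group = []
    for i in range(n):
        pos = Position(rng.uniform(0, world.width), rng.uniform(0, world.height),
                       rng.uniform(0, 2 * math.pi))
        ind = Individual(
            id=i + 1, rank=i + 1, dominance=dominance[i], position=pos,
            pscan=cfg.pscan, view_angle_deg=cfg.view_angle_deg,
            arousal=cfg.arousal_baseline,
        )
        ind.fear_row = np.array([fear_value(dominance[i], dominance[j], max_gap)
                                 for j in range(n)])
        group.append(ind)
    return group, AttitudeMatrix(n, params)


def partner_weights(like_row: np.ndarray, lps: float) -> np.ndarray:
    """Grooming-partner choice probabilities under LIKE-partner-selectivity.

    Each candidate's weight is ``(1 - lps) + lps * like``, normalized to sum
    to one: ``lps = 0`` is the uniform distribution, ``lps = 1`` pure
    LIKE-proportional choice, and higher ``lps`` makes high-LIKE partners
    increasingly preferred.
    """
    like_row = np.asarray(like_row, dtype=float)
    if like_row.size == 0:
        raise ValueError("empty candidate set")
    if not 0.0 <= lps <= 1.0:
        raise ValueError("lps must be in [0, 1]")
    w = (1.0 - lps) + lps * like_row
    total = w.sum()
    if total <= 0:
        return np.full(like_row.size, 1.0 / like_row.size)
    return w / total


def select_behavior(me: Individual, others: list[Individual], likes: AttitudeMatrix,
                    cfg: BehaviorConfig, world: WorldConfig, now: float,
                    rng: np.random.RandomState) -> tuple[str, Individual | None]:
    """One activation's decision: ``(action, target)``.

    With probability ``myAROUSAL`` an active behaviour is drawn, else rest.
    Active: perceive (a scan event widens the view to 360 degrees with
    probability ``myPscan``); with no one in view, random-walk.  A small
    fixed probability selects agonism toward a lower-ranked perceived
    individual.  Otherwise a grooming partner is drawn from
    :func:`partner_weights` over the perceived candidates, damped by FEAR;
    the partner is groomed if within reach and approached (or, rarely,
    signalled at) if not.  A nearby much-feared dominant is avoided when
    anxiety is high.
    """
    if rng.random_sample() >= me.arousal:
        return "rest", None
    full_view = rng.random_sample() < me.pscan
    perceived = visible_others(me, others, world, full_view=full_view)
    if not perceived:
        return "random_walk", None

    if me.anxiety > cfg.avoid_anxiety_threshold:
        for other in perceived:
            if (me.fear_row[other.id - 1] > cfg.avoid_fear_threshold
                    and torus_distance(me.position, other.position, world)
                    < cfg.avoid_distance):
                return "avoid", other

    if rng.random_sample() < cfg.agonism_prob:
        lower = [o for o in perceived if o.dominance < me.dominance]
        if lower:
            target = lower[rng.randint(len(lower))]
            action = "attack" if rng.random_sample() < 0.5 else "aggressive_signal"
            return action, target
        return "submissive_signal", perceived[rng.randint(len(perceived))]

    # recent grooming satiates (but does not abolish) the affiliative drive
    if rng.random_sample() < cfg.satiation_strength * me.satisfaction:
        return "random_walk", None

    # interaction opportunity is local: propose a partner with probability
    # falling off with distance, then accept by the LPS-LIKE mixing
    dists = np.array([torus_distance(me.position, o.position, world)
                      for o in perceived])
    prop = 1.0 / (1.0 + dists)
    cand = perceived[rng.choice(len(perceived), p=prop / prop.sum())]
    like = likes.get(me.id - 1, cand.id - 1, now)
    accept = (((1.0 - cfg.lps) + cfg.lps * like)
              * (1.0 - cfg.fear_damping * me.fear_row[cand.id - 1]))
    if rng.random_sample() >= accept:
        return "random_walk", None
    target = cand
    if torus_distance(me.position, target.position, world) <= world.grooming_reach:
        return "groom", target
    if rng.random_sample() < cfg.affiliative_signal_prob:
        return "affiliative_signal", target
    return "approach", target


def execute_grooming(actor: Individual, receiver: Individual, minutes: float,
                     likes: AttitudeMatrix, groom_minutes: np.ndarray,
                     cfg: BehaviorConfig, world: WorldConfig, now: float) -> None:
    """Apply a grooming bout's effects.

    The *receiver's* LIKE toward the actor advances by the increase curve
    (valuation is based on received grooming); receiver satisfaction rises;
    the directed grooming-minutes tally is incremented actor -> receiver.
    The actor's own LIKE toward the receiver changes only by lazy decay.
    """
    if minutes < 1:
        raise ValueError("a grooming bout lasts at least 1 minute")
    if torus_distance(actor.position, receiver.position, world) > world.grooming_reach:
        raise ValueError("grooming partners must be within reach")
    current = likes.get(receiver.id - 1, actor.id - 1, now)
    likes.set(receiver.id - 1, actor.id - 1,
              groom_increase(current, minutes, likes.params), now + minutes)
    receiver.satisfaction = min(1.0, receiver.satisfaction
                                + cfg.satisfaction_gain * minutes)
    actor.satisfaction = min(1.0, actor.satisfaction
                             + cfg.satisfaction_gain * minutes)
    groom_minutes[actor.id - 1, receiver.id - 1] += minutes


def execute_agonism(actor: Individual, receiver: Individual, action: str,
                    cfg: BehaviorConfig) -> None:
    """Apply an agonistic interaction: anxiety only, never LIKE.

    A submissive signal carries no anxiety to its (higher-ranked) receiver.
    """
    if action == "attack":
        receiver.anxiety = min(1.0, receiver.anxiety + cfg.anxiety_gain_attack)
    elif action == "aggressive_signal":
        receiver.anxiety = min(1.0, receiver.anxiety + cfg.anxiety_gain_signal)
    elif action == "submissive_signal":
        pass
    else:
        raise ValueError(f"not an agonistic action: {action!r}")
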