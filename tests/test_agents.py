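"""Group initialization, FEAR, partner choice and interaction effects."""

import numpy as np
import pytest

from emobook.agents import (AttitudeMatrix, BehaviorConfig, execute_agonism,
                            execute_grooming, fear_value, init_group,
                            partner_weights, select_behavior)
from emobook.dynamics import make_dynamics
from emobook.world import Position, WorldConfig


@pytest.fixture()
def alt_fast():
    return make_dynamics("alternative", "fast", 2880.0)


def test_init_group_ladder_and_dyads(alt_fast):
    group, likes = init_group(20, seed=1, params=alt_fast)
    assert len(group) == 20
    assert group[0].dominance == pytest.approx(1.0)
    assert group[-1].dominance == pytest.approx(0.05)
    doms = [g.dominance for g in group]
    assert all(a > b for a, b in zip(doms, doms[1:]))
    offdiag = ~np.eye(20, dtype=bool)
    assert offdiag.sum() == 380
    assert np.all(likes.like[offdiag] == alt_fast.lower_bound)
    assert np.isnan(np.diag(likes.like)).all()


def test_init_group_deterministic(alt_fast):
    g1, m1 = init_group(20, seed=7, params=alt_fast)
    g2, m2 = init_group(20, seed=7, params=alt_fast)
    for a, b in zip(g1, g2):
        assert (a.position.x, a.position.y) == (b.position.x, b.position.y)
    assert np.array_equal(m1.like, m2.like, equal_nan=True)
    g3, _ = init_group(20, seed=8, params=alt_fast)
    assert any((a.position.x, a.position.y) != (c.position.x, c.position.y)
               for a, c in zip(g1, g3))


def test_init_group_too_small(alt_fast):
    with pytest.raises(ValueError):
        init_group(1, seed=0, params=alt_fast)


@pytest.mark.parametrize("ds,do,expect", [
    (1.0, 1.0, 0.0),       # no gap
    (0.05, 1.0, 1.0),      # maximal gap, normalized
    (1.0, 0.05, 0.0),      # fear points up-hierarchy only
    (0.5, 0.975, 0.5),
])
def test_fear_value(ds, do, expect):
    assert fear_value(ds, do) == pytest.approx(expect)


def test_fear_monotone_in_gap():
    fears = [fear_value(0.3, d) for d in np.linspace(0.3, 1.0, 10)]
    assert all(b >= a for a, b in zip(fears, fears[1:]))


def test_partner_weights_examples():
    assert partner_weights([0.3, 0.6], 0.0) == pytest.approx([0.5, 0.5])
    assert partner_weights([0.2, 0.8], 1.0) == pytest.approx([0.2, 0.8])
    assert partner_weights([0.2, 0.8], 0.5) == pytest.approx([0.4, 0.6])
    with pytest.raises(ValueError):
        partner_weights([], 0.5)
    with pytest.raises(ValueError):
        partner_weights([0.5], 1.5)


def test_partner_weights_monotone_in_like(rng):
    likes = np.sort(rng.uniform(0, 1, 8))
    for lps in (0.3, 0.9, 0.99):
        w = partner_weights(likes, lps)
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) >= -1e-12).all()


def _scene(alt_fast, n=5, like_values=None, reach_all=True):
    """A focal individual with equidistant in-reach candidates."""
    world = WorldConfig()
    group, likes = init_group(n, seed=3, params=alt_fast)
    me = group[0]
    me.arousal = 1.0
    me.anxiety = 0.0
    me.satisfaction = 0.0
    me.view_angle_deg = 360.0
    me.fear_row = np.zeros(n)  # isolate choice from FEAR damping
    r = 0.5 if reach_all else 30.0
    for k, other in enumerate(group[1:]):
        ang = 2 * np.pi * k / (n - 1)
        other.position = Position((me.position.x + r * np.cos(ang)) % 300,
                                  (me.position.y + r * np.sin(ang)) % 300)
    if like_values is not None:
        for other, v in zip(group[1:], like_values):
            likes.set(0, other.id - 1, v, 0.0)
    return me, group, likes, world


def test_select_behavior_gates(alt_fast):
    cfg = BehaviorConfig(lps=0.99)
    me, group, likes, world = _scene(alt_fast)
    rng = np.random.RandomState(0)
    me.arousal = 0.0
    for _ in range(50):
        assert select_behavior(me, group, likes, cfg, world, 0.0, rng)[0] == "rest"
    me.arousal = 1.0
    assert select_behavior(me, [me], likes, cfg, world, 0.0, rng)[0] == "random_walk"


def test_groom_choice_frequencies_match_partner_weights(alt_fast):
    """Conditional on grooming, partner frequencies follow the LPS weighting."""
    cfg = BehaviorConfig(lps=0.99, agonism_prob=0.0)
    like_values = [0.9, 0.01, 0.01, 0.01]
    me, group, likes, world = _scene(alt_fast, like_values=like_values)
    rng = np.random.RandomState(1)
    counts = np.zeros(4)
    n_groom = 0
    for _ in range(10000):
        action, target = select_behavior(me, group, likes, cfg, world, 0.0, rng)
        if action == "groom":
            counts[target.id - 2] += 1
            n_groom += 1
    expected = partner_weights(np.array(like_values), cfg.lps)
    freq = counts / n_groom
    se = np.sqrt(expected * (1 - expected) / n_groom)
    assert np.all(np.abs(freq - expected) < 5 * se + 1e-3)


def test_top_partner_preference_monotone_in_lps(alt_fast):
    """Across the study's LPS levels the top-LIKE partner is chosen more."""
    like_values = [0.9, 0.1, 0.1, 0.1]
    fractions = []
    for lps in (0.5, 0.9, 0.95, 0.99):
        cfg = BehaviorConfig(lps=lps, agonism_prob=0.0)
        me, group, likes, world = _scene(alt_fast, like_values=like_values)
        rng = np.random.RandomState(123)
        hit = tot = 0
        for _ in range(4000):
            action, target = select_behavior(me, group, likes, cfg, world, 0.0, rng)
            if action == "groom":
                tot += 1
                hit += target.id == group[1].id
        fractions.append(hit / tot)
    assert all(b >= a - 0.02 for a, b in zip(fractions, fractions[1:]))
    assert fractions[-1] > fractions[0]


def test_execute_grooming_semantics(alt_fast):
    cfg = BehaviorConfig()
    world = WorldConfig()
    group, likes = init_group(3, seed=5, params=alt_fast)
    actor, receiver = group[0], group[1]
    receiver.position = Position(actor.position.x, (actor.position.y + 0.5) % 300)
    groom = np.zeros((3, 3))
    actor_like_before = likes.get(0, 1, now=0.0)
    execute_grooming(actor, receiver, 10.0, likes, groom, cfg, world, now=0.0)
    # receiver's LIKE toward actor reaches the top (fast LINC, full bout)
    assert likes.get(1, 0, now=10.0) == pytest.approx(alt_fast.upper_bound)
    # actor's own LIKE toward receiver was not raised by giving grooming
    assert likes.get(0, 1, now=10.0) <= actor_like_before
    assert receiver.satisfaction == pytest.approx(1.0)  # 10 min * 0.1, clipped
    assert groom[0, 1] == 10.0 and groom[1, 0] == 0.0
    with pytest.raises(ValueError):
        execute_grooming(actor, receiver, 0.0, likes, groom, cfg, world, now=0.0)
    receiver.position = Position((actor.position.x + 50) % 300, actor.position.y)
    with pytest.raises(ValueError):
        execute_grooming(actor, receiver, 5.0, likes, groom, cfg, world, now=0.0)


def test_execute_agonism_touches_anxiety_not_like(alt_fast):
    cfg = BehaviorConfig()
    group, likes = init_group(3, seed=5, params=alt_fast)
    before = likes.like.copy()
    actor, receiver = group[0], group[2]
    execute_agonism(actor, receiver, "attack", cfg)
    assert receiver.anxiety == pytest.approx(cfg.anxiety_gain_attack)
    for _ in range(20):
        execute_agonism(actor, receiver, "attack", cfg)
    assert receiver.anxiety == 1.0  # clipped
    execute_agonism(receiver, actor, "submissive_signal", cfg)
    assert actor.anxiety == 0.0  # submission carries no anxiety upward
    assert np.array_equal(likes.like, before, equal_nan=True)
    with pytest.raises(ValueError):
        execute_agonism(actor, receiver, "groom", cfg)


def test_attitude_matrix_lazy_read(alt_fast):
    m = AttitudeMatrix(3, alt_fast)
    m.set(0, 1, 0.99, now=100.0)
    from emobook.dynamics import idle_decay
    assert m.get(0, 1, now=100.0) == 0.99
    assert m.get(0, 1, now=2980.0) == pytest.approx(
        idle_decay(0.99, 2880.0, alt_fast))
    # reading twice does not advance the stored timestamp
    assert m.last_update[0, 1] == 100.0
    with pytest.raises(RuntimeError):
        m.get(0, 1, now=50.0)
    with pytest.raises(ValueError):
        m.get(1, 1, now=200.0)
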