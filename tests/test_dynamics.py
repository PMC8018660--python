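"""Calibration, shape and composition laws of the LIKE bookkeeping curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emobook.dynamics import (
    DYNAMICS_NAMES, LINC_MINUTES, ConfigurationError, groom_increase,
    idle_decay, make_dynamics, time_to_reach, tabulate_curves,
)

ALL = sorted(DYNAMICS_NAMES)
LINCS = list(LINC_MINUTES)


# --------------------------------------------------------------- calibration

@pytest.mark.parametrize("name", ALL)
@pytest.mark.parametrize("linc,period", [("fast", 10), ("intermediate", 30),
                                         ("slow", 60)])
def test_min_to_max_travel_time(name, linc, period):
    """Uninterrupted grooming spans the full range in the LINC period."""
    p = make_dynamics(name, linc, 2880.0)
    t = time_to_reach(p.lower_bound, p.upper_bound, "increase", p)
    assert t == pytest.approx(period, abs=1e-9)
    assert groom_increase(p.lower_bound, period, p) == pytest.approx(
        p.upper_bound, abs=1e-9)


@pytest.mark.parametrize("lhw", [720.0, 21600.0])
def test_exponential_half_life(lhw):
    """Exponential decay halves any LIKE value in exactly LHW minutes."""
    p = make_dynamics("original", "fast", lhw)
    for v in (0.8, 0.3, 1.0):
        assert idle_decay(v, lhw, p) == pytest.approx(v / 2, abs=1e-12)
    assert time_to_reach(0.8, 0.4, "decrease", p) == pytest.approx(lhw)


@pytest.mark.parametrize("lhw", [180.0, 2880.0, 21600.0])
def test_logistic_decay_crosses_half_at_lhw(lhw):
    """Logistic decay from the upper bound first reaches 0.5 after LHW."""
    p = make_dynamics("alternative", "slow", lhw)
    assert idle_decay(p.upper_bound, lhw, p) == pytest.approx(0.5, abs=1e-9)
    assert time_to_reach(p.upper_bound, 0.5, "decrease", p) == pytest.approx(lhw)


def test_lhw_zero_rules():
    """LHW = 0: linear 50-minute emptying (exponential kind) or LHW = 25."""
    orig = make_dynamics("original", "fast", 0.0)
    assert time_to_reach(orig.upper_bound, orig.lower_bound, "decrease",
                         orig) == pytest.approx(50.0)
    assert idle_decay(1.0, 50.0, orig) == pytest.approx(0.0)
    assert idle_decay(1.0, 500.0, orig) == 0.0  # floored, not negative
    alt = make_dynamics("alternative", "fast", 0.0)
    assert alt.lhw == 25.0


def test_derived_constants():
    orig = make_dynamics("original", "fast", 720.0)
    assert orig.a == pytest.approx(0.1)
    assert (orig.lower_bound, orig.upper_bound) == (0.0, 1.0)
    alt = make_dynamics("alternative", "fast", 2880.0)
    assert alt.k_inc == pytest.approx(2 * math.log(99) / 10)
    assert alt.k_dec == pytest.approx(math.log(99) / 2880)
    assert (alt.lower_bound, alt.upper_bound) == (0.01, 0.99)


# ------------------------------------------------------------------ examples

def test_point_examples():
    orig = make_dynamics("original", "fast", 720.0)
    assert groom_increase(0.5, 2.0, orig) == pytest.approx(0.7)
    alt = make_dynamics("alternative", "fast", 2880.0)
    # calibrated sigmoid is symmetric: the lower bound sits at -period/2
    assert groom_increase(0.01, 5.0, alt) == pytest.approx(0.5, abs=1e-9)
    for p in (orig, alt):
        assert groom_increase(0.4, 0.0, p) == 0.4
        assert idle_decay(0.4, 0.0, p) == 0.4


# -------------------------------------------------------------------- errors

def test_configuration_errors():
    with pytest.raises(ConfigurationError):
        make_dynamics("nope", "fast", 720.0)
    with pytest.raises(ConfigurationError):
        make_dynamics("original", "medium", 720.0)
    with pytest.raises(ConfigurationError):
        make_dynamics("original", "fast", -1.0)


def test_argument_errors():
    p = make_dynamics("original", "fast", 720.0)
    with pytest.raises(ValueError):
        groom_increase(0.5, -1.0, p)
    with pytest.raises(ValueError):
        idle_decay(0.5, -1.0, p)
    with pytest.raises(ValueError):
        time_to_reach(0.2, 0.8, "decrease", p)  # decay cannot raise
    with pytest.raises(ValueError):
        time_to_reach(0.8, 0.2, "increase", p)
    with pytest.raises(ValueError):
        time_to_reach(0.5, 0.5, "increase", p)


# ------------------------------------------------------- composition / shape

@pytest.mark.parametrize("name", ALL)
@given(v=st.floats(0.0, 1.0), t1=st.floats(0.0, 5000.0), t2=st.floats(0.0, 5000.0))
@settings(max_examples=40, deadline=None)
def test_decay_and_increase_semigroup(name, v, t1, t2):
    """Composing two updates equals one update over the summed duration."""
    p = make_dynamics(name, "intermediate", 2880.0)
    v = p.lower_bound + v * (p.upper_bound - p.lower_bound)
    two = idle_decay(idle_decay(v, t1, p), t2, p)
    one = idle_decay(v, t1 + t2, p)
    assert two == pytest.approx(one, abs=1e-9)
    two = groom_increase(groom_increase(v, t1, p), t2, p)
    one = groom_increase(v, t1 + t2, p)
    assert two == pytest.approx(one, abs=1e-9)


@pytest.mark.parametrize("name", ALL)
@given(v=st.floats(0.0, 1.0), data=st.data())
@settings(max_examples=25, deadline=None)
def test_bounds_preserved_under_any_sequence(name, v, data):
    p = make_dynamics(name, "fast", 180.0)
    x = p.lower_bound + v * (p.upper_bound - p.lower_bound)
    for _ in range(20):
        dt = data.draw(st.floats(0.0, 1000.0))
        if data.draw(st.booleans()):
            x = groom_increase(x, dt, p)
        else:
            x = idle_decay(x, dt, p)
        assert p.lower_bound <= x <= p.upper_bound


def test_curve_shape_contract():
    """Logistic curves are slow at the extremes and fast in the middle."""
    lin = make_dynamics("original", "fast", 2880.0)
    log = make_dynamics("alternative", "fast", 2880.0)
    eps = 1e-4
    # increase rate at the lower bound: logistic strictly below linear
    rate_log = (groom_increase(log.lower_bound, eps, log) - log.lower_bound) / eps
    assert rate_log < lin.a
    # decrease rate: fastest around the midpoint, slow near the top
    rate_mid = (0.5 - idle_decay(0.5, eps, log)) / eps
    rate_high = (0.9 - idle_decay(0.9, eps, log)) / eps
    assert rate_mid > rate_high


# -------------------------------------------------- numeric-integration oracle

def _derivative(v, p, mode):
    if mode == "increase":
        if p.increase_kind == "linear":
            return p.a if v < p.upper_bound else 0.0
        return p.k_inc * v * (1.0 - v) if v < p.upper_bound else 0.0
    if p.decrease_kind == "exponential":
        if p.lhw > 0:
            return -math.log(2) / p.lhw * v if v > p.lower_bound else 0.0
        return -p.lin_decay_rate if v > p.lower_bound else 0.0
    return -p.k_dec * v * (1.0 - v) if v > p.lower_bound else 0.0


def _integrate(v0, minutes, p, mode, dt=0.001):
    """Independent oracle: RK4 on the curve derivative at 1e-3-min steps."""
    n_steps = int(minutes / dt)
    rem = minutes - n_steps * dt
    v = v0
    for step in range(n_steps + 1):
        h = dt if step < n_steps else rem
        if h == 0.0:
            continue
        k1 = _derivative(v, p, mode)
        k2 = _derivative(v + 0.5 * h * k1, p, mode)
        k3 = _derivative(v + 0.5 * h * k2, p, mode)
        k4 = _derivative(v + h * k3, p, mode)
        v += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        v = min(max(v, p.lower_bound), p.upper_bound)
    return v


@pytest.mark.parametrize("name", ALL)
def test_analytic_updates_match_integration_oracle(name, rng):
    """Closed-form updates agree with step-wise integration of the rates."""
    p = make_dynamics(name, "fast", 720.0)
    for _ in range(12):
        v = rng.uniform(p.lower_bound, p.upper_bound)
        minutes = rng.uniform(0.0, 30.0)
        assert groom_increase(v, minutes, p) == pytest.approx(
            _integrate(v, minutes, p, "increase"), abs=1e-6)
        assert idle_decay(v, minutes, p) == pytest.approx(
            _integrate(v, minutes, p, "decrease"), abs=1e-6)


def test_tabulate_curves_shape():
    df = tabulate_curves(minutes=10, step=5.0, lhw_levels=(720.0,))
    assert set(df.columns) == {"dynamics", "linc", "lhw", "minute",
                               "like_increase", "like_decrease"}
    # 4 dynamics x 3 lincs x 1 lhw x 3 time points
    assert len(df) == 4 * 3 * 1 * 3
    # increase curves are monotone in time
    for _, g in df.groupby(["dynamics", "linc"]):
        assert (np.diff(g["like_increase"]) >= -1e-12).all()
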