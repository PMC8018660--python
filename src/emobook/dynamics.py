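"""Bookkeeping curves for the partner-specific LIKE attitude.

A LIKE value is one individual's emotional valuation of a specific group
member.  It rises while the individual is being groomed by that partner and
erodes during periods without grooming.  Four bookkeeping dynamics are
supported, the Cartesian product of two increase and two decrease curves:

================  ==========  ============
dynamics          increase    decrease
================  ==========  ============
original          linear      exponential
alternative       logistic    logistic
dynamics3         linear      logistic
dynamics4         logistic    exponential
================  ==========  ============

All four are calibrated against two speed contracts:

* LINC (LIKE-increase speed): uninterrupted grooming drives LIKE from its
  minimum to its maximum in exactly 10 / 30 / 60 minutes (fast /
  intermediate / slow).
* LHW (LIKE-history weight): exponential decay halves LIKE every ``lhw``
  minutes; logistic decay starting at the upper bound first crosses 0.5
  after exactly ``lhw`` minutes.

The logistic curves are clipped sigmoids on [0.01, 0.99]; the pure
linear/exponential (original) dynamics uses [0, 1].  ``LHW = 0`` is a
special very-fast-decay rule: with an exponential decrease it means linear
emptying of the full range in 50 minutes, and with a logistic decrease it
is mapped to ``LHW = 25``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DynamicsParams",
    "DYNAMICS_NAMES",
    "LINC_MINUTES",
    "LHW_ZERO_EMPTY_MINUTES",
    "make_dynamics",
    "groom_increase",
    "idle_decay",
    "time_to_reach",
    "tabulate_curves",
]

#: Minutes of uninterrupted grooming for the full minimum-to-maximum traversal.
LINC_MINUTES = {"fast": 10.0, "intermediate": 30.0, "slow": 60.0}

#: Minutes for the full range to empty under the LHW = 0 fast-decay rule.
LHW_ZERO_EMPTY_MINUTES = 50.0

#: (increase_kind, decrease_kind) per named dynamics.
DYNAMICS_NAMES = {
    "original": ("linear", "exponential"),
    "alternative": ("logistic", "logistic"),
    "dynamics3": ("linear", "logistic"),
    "dynamics4": ("logistic", "exponential"),
}

_LOGISTIC_LB = 0.01
_LOGISTIC_UB = 0.99
# logit(0.99) - logit(0.01) = 2 ln 99: sigmoid "travel distance" between the clips
_TRAVEL_LOGITS = 2.0 * math.log(99.0)


class ConfigurationError(ValueError):
    """Raised for unknown dynamics names, LINC levels or invalid settings."""


@dataclass(frozen=True)
class DynamicsParams:
    """Calibrated constants for one bookkeeping dynamics.

    Attributes
    ----------
    increase_kind, decrease_kind:
        ``"linear"``/``"logistic"`` and ``"exponential"``/``"logistic"``.
    linc_period:
        Minutes of uninterrupted grooming from minimum to maximum LIKE.
    lhw:
        Decay timescale in minutes (see module docstring for the two
        calibration meanings and the LHW = 0 special rule).
    lower_bound, upper_bound:
        Range of admissible LIKE values.
    a:
        Linear increase slope (LIKE per minute); 0 when increase is logistic.
    k_inc, k_dec:
        Logistic steepness per minute for increase/decrease; 0 when unused.
    lin_decay_rate:
        LIKE lost per minute under the LHW = 0 exponential-decrease special
        rule; 0 otherwise.
    """

    name: str
    increase_kind: str
    decrease_kind: str
    linc_period: float
    lhw: float
    lower_bound: float
    upper_bound: float
    a: float = 0.0
    k_inc: float = 0.0
    k_dec: float = 0.0
    lin_decay_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_bound < self.upper_bound <= 1.0:
            raise ConfigurationError("bounds must satisfy 0 <= lb < ub <= 1")
        if self.lhw < 0:
            raise ConfigurationError("lhw must be >= 0")
        if self.increase_kind == "linear" and self.a <= 0:
            raise ConfigurationError("linear increase needs slope a > 0")
        if self.increase_kind == "logistic" and self.k_inc <= 0:
            raise ConfigurationError("logistic increase needs k_inc > 0")
        if self.decrease_kind == "logistic" and self.k_dec <= 0:
            raise ConfigurationError("logistic decrease needs k_dec > 0")


def make_dynamics(name: str, linc: str, lhw: float) -> DynamicsParams:
    """Calibrate one of the four dynamics for a LINC level and an LHW.

    Parameters
    ----------
    name:
        ``original``, ``alternative``, ``dynamics3`` or ``dynamics4``.
    linc:
        ``fast`` (10 min), ``intermediate`` (30 min) or ``slow`` (60 min).
    lhw:
        Decay timescale in minutes; ``0`` selects the special fast-decay
        rule (linear 50-minute emptying for an exponential decrease, LHW=25
        for a logistic decrease).
    """
    try:
        inc_kind, dec_kind = DYNAMICS_NAMES[name]
    except KeyError:
        raise ConfigurationError(f"unknown dynamics name: {name!r}") from None
    try:
        period = LINC_MINUTES[linc]
    except KeyError:
        raise ConfigurationError(f"unknown LINC level: {linc!r}") from None
    if lhw < 0:
        raise ConfigurationError("lhw must be >= 0")

    if inc_kind == "linear" and dec_kind == "exponential":
        lb, ub = 0.0, 1.0  # pure original dynamics keeps the printed slope 1/period
    else:
        lb, ub = _LOGISTIC_LB, _LOGISTIC_UB

    a = (ub - lb) / period if inc_kind == "linear" else 0.0
    k_inc = _TRAVEL_LOGITS / period if inc_kind == "logistic" else 0.0

    lin_decay_rate = 0.0
    k_dec = 0.0
    if dec_kind == "exponential":
        if lhw == 0:
            lin_decay_rate = (ub - lb) / LHW_ZERO_EMPTY_MINUTES
    else:
        if lhw == 0:
            lhw = 25.0  # the grid's "0 or 25" pairing
        # decreasing sigmoid from ub=0.99 crosses 0.5 after ln(99)/k minutes
        k_dec = math.log(99.0) / lhw

    return DynamicsParams(
        name=name, increase_kind=inc_kind, decrease_kind=dec_kind,
        linc_period=period, lhw=lhw, lower_bound=lb, upper_bound=ub,
        a=a, k_inc=k_inc, k_dec=k_dec, lin_decay_rate=lin_decay_rate,
    )


def _check_value(value: float, p: DynamicsParams) -> None:
    if not p.lower_bound - 1e-12 <= value <= p.upper_bound + 1e-12:
        raise ValueError(f"LIKE value {value} outside [{p.lower_bound}, {p.upper_bound}]")


def groom_increase(like: float, minutes: float, params: DynamicsParams) -> float:
    """LIKE after ``minutes`` of uninterrupted received grooming.

    Linear: ``like + a*minutes``.  Logistic: the current value is inverted
    through the logit to an effective time on the increasing sigmoid, which
    is then advanced by ``minutes``.  Always clipped to the upper bound.
    """
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    _check_value(like, params)
    if minutes == 0:
        return like
    if params.increase_kind == "linear":
        out = like + params.a * minutes
    else:
        v = min(max(like, params.lower_bound), params.upper_bound)
        if v >= params.upper_bound:
            return params.upper_bound
        x0 = math.log(v / (1.0 - v)) / params.k_inc
        out = 1.0 / (1.0 + np.exp(-params.k_inc * (x0 + minutes)))
    return min(out, params.upper_bound)


def idle_decay(like: float, minutes: float, params: DynamicsParams) -> float:
    """LIKE after ``minutes`` without receiving grooming.

    Exponential: ``like * 0.5**(minutes/lhw)`` (LHW = 0: linear emptying at
    ``lin_decay_rate``).  Logistic: invert the decreasing sigmoid, advance,
    re-evaluate.  Always floored at the lower bound.  Both kinds satisfy the
    semigroup law ``decay(decay(L, t1), t2) == decay(L, t1 + t2)``.
    """
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    _check_value(like, params)
    if minutes == 0:
        return like
    if params.decrease_kind == "exponential":
        if params.lhw > 0:
            out = like * 0.5 ** (minutes / params.lhw)
        else:
            out = like - params.lin_decay_rate * minutes
    else:
        v = min(max(like, params.lower_bound), params.upper_bound)
        if v <= params.lower_bound:
            return params.lower_bound
        # decreasing sigmoid L(x) = 1 / (1 + e^{k x})
        x0 = math.log(1.0 / v - 1.0) / params.k_dec
        out = 1.0 / (1.0 + np.exp(params.k_dec * (x0 + minutes)))
    return max(out, params.lower_bound)


def time_to_reach(from_value: float, to_value: float, mode: str,
                  params: DynamicsParams) -> float:
    """Minutes for the increase/decay operator to map one value onto another.

    Closed-form inverse of :func:`groom_increase` (``mode="increase"``) and
    :func:`idle_decay` (``mode="decrease"``); the calibration-test utility.
    """
    _check_value(to_value, params)
    if from_value == to_value:
        raise ValueError("from_value and to_value must differ")
    if mode == "increase":
        if to_value < from_value:
            raise ValueError("increase cannot lower a LIKE value")
        if params.increase_kind == "linear":
            return (to_value - from_value) / params.a
        lo = max(from_value, params.lower_bound)
        hi = min(to_value, params.upper_bound)
        x0 = math.log(lo / (1.0 - lo)) / params.k_inc
        x1 = math.log(hi / (1.0 - hi)) / params.k_inc
        return x1 - x0
    if mode == "decrease":
        if to_value > from_value:
            raise ValueError("decay cannot raise a LIKE value")
        if params.decrease_kind == "exponential":
            if params.lhw > 0:
                if to_value <= 0:
                    raise ValueError("exponential decay never reaches 0 exactly")
                return params.lhw * math.log2(from_value / to_value)
            return (from_value - to_value) / params.lin_decay_rate
        hi = min(from_value, params.upper_bound)
        lo = max(to_value, params.lower_bound)
        x0 = math.log(1.0 / hi - 1.0) / params.k_dec
        x1 = math.log(1.0 / lo - 1.0) / params.k_dec
        return x1 - x0
    raise ValueError(f"unknown mode: {mode!r}")


def tabulate_curves(minutes: int = 720, step: float = 1.0,
                    lhw_levels=(0.0, 180.0, 720.0, 2880.0, 5400.0, 21600.0)):
    """LIKE(t) under uninterrupted grooming and under pure decay.

    Returns a :class:`pandas.DataFrame` with columns ``dynamics, linc, lhw,
    minute, like_increase, like_decrease`` for every named dynamics, LINC
    level and LHW level: the data behind curve-shape diagnostic plots.
    """
    import pandas as pd

    rows = []
    ts = np.arange(0.0, minutes + step / 2, step)
    for name in DYNAMICS_NAMES:
        for linc in LINC_MINUTES:
            for lhw in lhw_levels:
                p = make_dynamics(name, linc, lhw)
                for t in ts:
                    rows.append({
                        "dynamics": name, "linc": linc, "lhw": lhw, "minute": t,
                        "like_increase": groom_increase(p.lower_bound, t, p),
                        "like_decrease": idle_decay(p.upper_bound, t, p),
                    })
    return pd.DataFrame(rows)
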