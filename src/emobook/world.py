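"""Continuous toroidal 2-D world: wrapping, distances and visual perception.

The arena is a border-free 300 x 300 grid-unit torus; one grid unit
represents one metre and one time step one minute.  Only the active part of
the day is simulated: a day is 720 minutes and a year 350 days, so a
simulated year is 252000 minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["WorldConfig", "Position", "wrap", "torus_distance", "visible_others"]


@dataclass(frozen=True)
class WorldConfig:
    width: float = 300.0
    height: float = 300.0
    unit_length_m: float = 1.0
    day_minutes: int = 720
    year_days: int = 350
    #: how far an individual can see, grid units
    perception_radius: float = 50.0
    #: distance at which grooming is possible ("arm's reach"), grid units
    grooming_reach: float = 1.0
    #: movement per minute for walks / approach / leave / avoid, grid units
    step_length: float = 1.0

    @property
    def year_minutes(self) -> int:
        return self.day_minutes * self.year_days


@dataclass
class Position:
    x: float
    y: float
    heading: float = 0.0  # radians


def wrap(pos: Position, world: WorldConfig) -> Position:
    """Wrap coordinates into [0, width) x [0, height)."""
    return Position(pos.x % world.width, pos.y % world.height, pos.heading)


def _min_image(delta: float, extent: float) -> float:
    """Signed displacement under the minimal-image convention."""
    d = (delta + extent / 2.0) % extent - extent / 2.0
    return d


def torus_displacement(p: Position, q: Position, world: WorldConfig) -> tuple[float, float]:
    """Minimal-image displacement vector from ``p`` to ``q``."""
    return (_min_image(q.x - p.x, world.width), _min_image(q.y - p.y, world.height))


def torus_distance(p: Position, q: Position, world: WorldConfig) -> float:
    """Euclidean distance on the torus (minimal-image convention)."""
    dx, dy = torus_displacement(p, q, world)
    return math.hypot(dx, dy)


def visible_others(me, others: Iterable, world: WorldConfig,
                   full_view: bool = False) -> list:
    """Individuals ``me`` currently sees.

    An individual sees another if it is within the perception radius and
    its bearing lies within +-``myVIEW_ANGLE``/2 of the heading.  When a
    scan event fires (probability ``myPscan`` per activation, decided by the
    caller and passed as ``full_view``) the view angle is treated as 360
    degrees.  An individual never perceives itself.
    """
    seen = []
    half = math.radians(me.view_angle_deg) / 2.0
    if not full_view and half <= 0.0:
        return seen  # a zero-width view sees nothing
    for other in others:
        if other is me:
            continue
        dx, dy = torus_displacement(me.position, other.position, world)
        if math.hypot(dx, dy) > world.perception_radius:
            continue
        if not full_view:
            bearing = math.atan2(dy, dx)
            diff = (bearing - me.position.heading + math.pi) % (2 * math.pi) - math.pi
            if abs(diff) > half:
                continue
        seen.append(other)
    return seen
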