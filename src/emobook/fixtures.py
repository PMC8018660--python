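"""Synthetic dyadic snapshot generator for testing the analysis stage.

Emulates the shape of simulator output — a sequence of directed N x N
LIKE snapshot matrices — with controllable differentiation (a planted set
of high-LIKE dyads per individual) and controllable temporal persistence
(an AR(1) process per dyad), without running a simulation.  The planted
structure is returned alongside the snapshots so recovery tests can check
that :func:`emobook.analysis.categorize` and
:func:`emobook.analysis.stability_score` retrieve the planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FixturePlan", "generate_fixture_snapshots"]

_LB, _UB = 0.01, 0.99
_HIGH = 0.9
_LOW = 0.1


@dataclass
class FixturePlan:
    """Planted ground truth behind a generated snapshot sequence."""

    high_mask: np.ndarray      # (n, n) bool, True where a high dyad was planted
    persistence: float
    noise_sd: float
    n_high_per_individual: int


def generate_fixture_snapshots(n: int, n_high_per_individual: int,
                               persistence: float, noise_sd: float,
                               seed: int, n_snapshots: int = 5,
                               ) -> tuple[np.ndarray, FixturePlan]:
    """Five (by default) synthetic LIKE snapshots with known structure.

    Each individual gets ``n_high_per_individual`` directed dyads planted
    near the upper bound (0.9) and the rest near the lower bound (0.1).
    Subsequent snapshots follow a per-dyad AR(1) recursion around the range
    midpoint with persistence ``rho``::

        S[k+1] = mid + rho * (S[k] - mid) + eps,   eps ~ N(0, noise_sd)

    clipped to [0.01, 0.99].  ``rho = 1`` with zero noise freezes the
    planted pattern (stability 1); ``rho = 0`` makes consecutive snapshots
    independent (stability at the null level ~ 1/(N(N-1) - 1)).
    """
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= n_high_per_individual <= n - 1:
        raise ValueError("n_high_per_individual must be in [0, n-1]")
    rng = np.random.RandomState(seed)

    high_mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        partners = np.delete(np.arange(n), i)
        chosen = rng.choice(partners, size=n_high_per_individual, replace=False)
        high_mask[i, chosen] = True

    mid = 0.5 * (_LB + _UB)
    base = np.where(high_mask, _HIGH, _LOW).astype(float)
    snap = np.clip(base + rng.normal(0.0, noise_sd, size=(n, n)), _LB, _UB)
    snapshots = [snap]
    for _ in range(n_snapshots - 1):
        nxt = mid + persistence * (snapshots[-1] - mid) \
            + rng.normal(0.0, noise_sd, size=(n, n))
        snapshots.append(np.clip(nxt, _LB, _UB))
    out = np.stack(snapshots)
    for k in range(n_snapshots):
        np.fill_diagonal(out[k], np.nan)
    plan = FixturePlan(high_mask=high_mask, persistence=persistence,
                       noise_sd=noise_sd,
                       n_high_per_individual=n_high_per_individual)
    return out, plan
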