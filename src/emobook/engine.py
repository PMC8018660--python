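"""Run configuration, the simulation driver and run-level data capture.

A run consists of a stabilization period (``max(6000, 30*LHW)`` minutes,
longer for slower decay because LIKE attitudes take longer to settle)
followed by a 2-year recording period (504000 minutes at 720 min/day and
350 days/year).  During recording the engine captures five LIKE snapshots
separated by half a year, periodic LIKE samples for second-year averaging,
the directed grooming-minutes matrix and pairwise proximity rates.

A ``scale`` factor shrinks stabilization, recording and the snapshot /
LIKE-sampling spacing proportionally for desk-scale experiments; the
defaults reproduce the full protocol.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .agents import AttitudeMatrix, BehaviorConfig
from .dynamics import DynamicsParams, idle_decay, make_dynamics
from .world import WorldConfig

__all__ = [
    "RunConfig",
    "RunRecord",
    "stabilization_length",
    "run_simulation",
    "lazy_like",
]

RECORDING_MINUTES_FULL = 504000  # 2 years at 720 min/day * 350 days/year


def stabilization_length(lhw: float) -> float:
    """Unscaled stabilization minutes before recording: ``max(6000, 30*lhw)``."""
    if lhw < 0:
        raise ValueError("lhw must be >= 0")
    return max(6000.0, 30.0 * lhw)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    dynamics: str = "alternative"
    linc: str = "slow"
    lhw: float = 2880.0
    lps: float = 0.99
    seed: int = 1
    n_individuals: int = 20
    scale: float = 1.0
    behavior: BehaviorConfig | None = None
    world: WorldConfig | None = None
    like_sample_interval_full: float = 1440.0  # daily at full scale
    proximity_sample_interval: float = 10.0
    proximity_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if self.behavior is None:
            self.behavior = BehaviorConfig(lps=self.lps)
        else:
            self.behavior.lps = self.lps
        if self.world is None:
            self.world = WorldConfig()

    # -- derived schedule (all integral minutes) --------------------------
    @property
    def dynamics_params(self) -> DynamicsParams:
        return make_dynamics(self.dynamics, self.linc, self.lhw)

    @property
    def stabilization_minutes(self) -> int:
        return int(round(stabilization_length(self.lhw) * self.scale))

    @property
    def recording_minutes(self) -> int:
        quarter = int(round(RECORDING_MINUTES_FULL * self.scale / 4.0))
        return 4 * quarter  # keep the 5 snapshots on integral minutes

    @property
    def snapshot_times(self) -> np.ndarray:
        """Snapshot instants on the recording clock (0 = recording start)."""
        q = self.recording_minutes // 4
        return np.array([0, q, 2 * q, 3 * q, 4 * q], dtype=float)

    @property
    def like_sample_interval(self) -> int:
        return max(1, int(round(self.like_sample_interval_full * self.scale)))

    @property
    def like_sample_times(self) -> np.ndarray:
        step = self.like_sample_interval
        return np.arange(0, self.recording_minutes + 1, step, dtype=float)

    def manifest(self) -> dict:
        from . import __version__

        m = {
            "dynamics": self.dynamics, "linc": self.linc, "lhw": self.lhw,
            "lps": self.lps, "seed": self.seed,
            "n_individuals": self.n_individuals, "scale": self.scale,
            "stabilization_minutes": self.stabilization_minutes,
            "recording_minutes": self.recording_minutes,
            "snapshot_times": self.snapshot_times.tolist(),
            "like_sample_interval": self.like_sample_interval,
            "proximity_sample_interval": self.proximity_sample_interval,
            "proximity_radius": self.proximity_radius,
            "behavior": asdict(self.behavior),
            "world": asdict(self.world),
            "emobook_version": __version__,
        }
        return m


@dataclass
class RunRecord:
    """Outputs of one run."""

    manifest: dict
    snapshot_times: np.ndarray          # recording clock, minutes
    snapshots: np.ndarray               # (5, n, n), NaN diagonal
    like_sample_times: np.ndarray
    like_samples: np.ndarray            # (m, n, n)
    grooming_minutes: np.ndarray        # directed actor -> receiver totals
    proximity_rate: np.ndarray          # symmetric, fraction of samples
    counters: dict

    def to_dir(self, path: str | Path) -> Path:
        """Write CSV/JSON products (ids ordered by rank, 1 = highest)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ids = [str(i + 1) for i in range(self.snapshots.shape[1])]

        def _write(mat: np.ndarray, name: str) -> None:
            pd.DataFrame(mat, index=ids, columns=ids).to_csv(
                path / name, index_label="id")

        for k, t in enumerate(self.snapshot_times):
            _write(self.snapshots[k], f"like_snapshot_{int(t)}.csv")
        _write(self.grooming_minutes, "grooming_minutes.csv")
        _write(self.proximity_rate, "proximity_rate.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # NaN diagonal
            mean = np.nanmean(self.like_samples, axis=0)
        _write(mean, "like_mean_all_samples.csv")
        samples = self.like_samples.reshape(self.like_samples.shape[0], -1)
        pd.DataFrame(samples, index=self.like_sample_times).to_csv(
            path / "like_samples_flat.csv", index_label="minute")
        with open(path / "manifest.json", "w") as fh:
            json.dump({**self.manifest, "counters": self.counters}, fh, indent=2)
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "RunRecord":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        counters = manifest.pop("counters", {})
        snap_times = np.array(manifest["snapshot_times"], dtype=float)
        n = manifest["n_individuals"]
        snaps = np.stack([
            pd.read_csv(path / f"like_snapshot_{int(t)}.csv", index_col=0).to_numpy()
            for t in snap_times])
        flat = pd.read_csv(path / "like_samples_flat.csv", index_col=0)
        like_times = flat.index.to_numpy(dtype=float)
        like_samples = flat.to_numpy().reshape(len(like_times), n, n)
        groom = pd.read_csv(path / "grooming_minutes.csv", index_col=0).to_numpy()
        prox = pd.read_csv(path / "proximity_rate.csv", index_col=0).to_numpy()
        return cls(manifest=manifest, snapshot_times=snap_times, snapshots=snaps,
                   like_sample_times=like_times, like_samples=like_samples,
                   grooming_minutes=groom, proximity_rate=prox,
                   counters=counters)


def run_simulation(cfg: RunConfig) -> RunRecord:
    """Execute the event loop for one run; fully reproducible from (cfg, seed)."""
    p = cfg.dynamics_params
    b = cfg.behavior
    w = cfg.world
    n = cfg.n_individuals
    t_stab = float(cfg.stabilization_minutes)
    t_end = t_stab + cfg.recording_minutes
    snap_times = t_stab + cfg.snapshot_times
    like_times = t_stab + cfg.like_sample_times

    snapshots = np.empty((len(snap_times), n, n))
    like_samples = np.empty((len(like_times), n, n))
    groom_minutes = np.zeros((n, n))
    prox_counts = np.zeros((n, n), dtype=np.int64)
    counters = np.zeros(len(_kernel.COUNTER_NAMES), dtype=np.int64)
    spread_sum = np.zeros(1)

    _kernel.run_kernel(
        int(cfg.seed) % (2 ** 32), n,
        p.increase_kind == "linear", p.decrease_kind == "exponential",
        p.a, p.k_inc, p.k_dec, p.lhw, p.lower_bound, p.upper_bound,
        p.lin_decay_rate,
        b.lps, b.groom_continuation, b.satisfaction_gain,
        b.satisfaction_halflife, b.anxiety_gain_attack, b.anxiety_gain_signal,
        b.anxiety_halflife, b.arousal_baseline, b.arousal_halflife,
        b.arousal_bump, b.agonism_prob, b.flee_prob,
        b.affiliative_signal_prob, b.leave_prob, b.avoid_fear_threshold,
        b.avoid_distance, b.avoid_anxiety_threshold, b.cohesion_distance,
        b.fear_damping, b.pursuit_minutes, b.satiation_strength,
        b.anxiety_gain_proximity, b.anxiety_relief, b.pscan,
        np.radians(b.view_angle_deg) / 2.0,
        w.width, w.height, w.perception_radius, w.grooming_reach,
        w.step_length,
        t_stab, t_end, snap_times, like_times,
        float(cfg.proximity_sample_interval), float(cfg.proximity_radius),
        snapshots, like_samples, groom_minutes, prox_counts, counters,
        spread_sum)

    n_prox = int(counters[_kernel.C_PROX])
    prox_rate = prox_counts / n_prox if n_prox > 0 else prox_counts.astype(float)
    counter_map = dict(zip(_kernel.COUNTER_NAMES, (int(c) for c in counters)))
    counter_map["mean_pairwise_distance"] = (
        float(spread_sum[0] / n_prox) if n_prox > 0 else float("nan"))
    return RunRecord(
        manifest=cfg.manifest(),
        snapshot_times=cfg.snapshot_times,
        snapshots=snapshots,
        like_sample_times=cfg.like_sample_times,
        like_samples=like_samples,
        grooming_minutes=groom_minutes,
        proximity_rate=prox_rate,
        counters=counter_map,
    )


def lazy_like(dyad: tuple[int, int], now: float, store: AttitudeMatrix,
              dynamics: DynamicsParams) -> float:
    """Dyad's LIKE realized at ``now`` from its stored value and timestamp.

    Reading does not advance the timestamp; by the decay semigroup law this
    is equivalent to eager per-minute decay.
    """
    actor, partner = dyad
    gap = now - store.last_update[actor, partner]
    if gap < 0:
        raise RuntimeError("time reversal in LIKE read")
    return idle_decay(store.like[actor, partner], gap, dynamics)
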