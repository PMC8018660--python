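"""The factorial parameter grid, replicate management and sweep execution.

The study grid crosses 2 dynamics (original, alternative) x 3 LINC levels
x 6 LHW levels x 4 LPS levels = 144 cells, each run with 2 independent
replicates, plus an extra subset probing the two mixed dynamics
({dynamics3, dynamics4} x {fast, slow} x LHW 2880 x LPS 0.99, one run
each) to attribute differentiation effects to the increase or the decrease
curve separately.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .engine import RunConfig, run_simulation

__all__ = ["SweepSpec", "build_grid", "run_sweep", "derive_seed"]

logger = logging.getLogger("emobook.sweep")

GRID_DYNAMICS = ("original", "alternative")
GRID_LINC = ("fast", "intermediate", "slow")
GRID_LHW = (0.0, 180.0, 720.0, 2880.0, 5400.0, 21600.0)
GRID_LPS = (0.5, 0.9, 0.95, 0.99)
EXTRA_CELLS = tuple((dyn, linc, 2880.0, 0.99)
                    for dyn in ("dynamics3", "dynamics4")
                    for linc in ("fast", "slow"))


@dataclass(frozen=True)
class SweepSpec:
    dynamics: tuple = GRID_DYNAMICS
    linc: tuple = GRID_LINC
    lhw: tuple = GRID_LHW
    lps: tuple = GRID_LPS
    replicates: int = 2
    base_seed: int = 1
    extra_cells: tuple = EXTRA_CELLS
    n_individuals: int = 20
    scale: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.dynamics) * len(self.linc) * len(self.lhw) * len(self.lps)


def derive_seed(base_seed: int, index: int) -> int:
    """Reproducible per-run seed below 2**31, well-separated across cells."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def build_grid(spec: SweepSpec) -> list[RunConfig]:
    """Full factorial product x replicates, plus the extra cells run once.

    Ordering is deterministic (itertools product order, replicates
    innermost, extras appended) and per-run seeds derive from the base
    seed and the position in that ordering.
    """
    for axis in ("dynamics", "linc", "lhw", "lps"):
        if not getattr(spec, axis):
            raise ValueError(f"empty sweep axis: {axis}")
    configs = []
    idx = 0
    for dyn, linc, lhw, lps in product(spec.dynamics, spec.linc, spec.lhw, spec.lps):
        for _rep in range(spec.replicates):
            configs.append(RunConfig(
                dynamics=dyn, linc=linc, lhw=lhw, lps=lps,
                seed=derive_seed(spec.base_seed, idx),
                n_individuals=spec.n_individuals, scale=spec.scale))
            idx += 1
    for dyn, linc, lhw, lps in spec.extra_cells:
        configs.append(RunConfig(
            dynamics=dyn, linc=linc, lhw=lhw, lps=lps,
            seed=derive_seed(spec.base_seed, idx),
            n_individuals=spec.n_individuals, scale=spec.scale))
        idx += 1
    return configs


def _cell_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.manifest(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_sweep(grid: list[RunConfig], out_dir: str | Path,
              progress: bool = True) -> dict:
    """Execute a grid of runs, writing per-run products and a manifest.

    Idempotent: cells whose output directory already holds a manifest with
    a matching config hash are skipped on re-run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"n_runs": len(grid), "runs": []}
    for k, cfg in enumerate(grid):
        h = _cell_hash(cfg)
        run_dir = out_dir / (f"run_{k:04d}_{cfg.dynamics}_{cfg.linc}"
                             f"_lhw{int(cfg.lhw)}_lps{cfg.lps}_s{cfg.seed}")
        entry = {"index": k, "hash": h, "dir": run_dir.name,
                 "dynamics": cfg.dynamics, "linc": cfg.linc, "lhw": cfg.lhw,
                 "lps": cfg.lps, "seed": cfg.seed, "scale": cfg.scale}
        done = run_dir / "manifest.json"
        if done.exists():
            with open(done) as fh:
                if json.load(fh).get("config_hash") == h:
                    entry["status"] = "cached"
                    manifest["runs"].append(entry)
                    continue
        t0 = time.time()
        record = run_simulation(cfg)
        record.manifest["config_hash"] = h
        record.to_dir(run_dir)
        entry["status"] = "completed"
        entry["seconds"] = round(time.time() - t0, 2)
        manifest["runs"].append(entry)
        with open(out_dir / "sweep_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)  # keep partial progress on disk
        if progress:
            logger.info("run %d/%d (%s) done in %.1fs", k + 1, len(grid),
                        run_dir.name, entry["seconds"])
    with open(out_dir / "sweep_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
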