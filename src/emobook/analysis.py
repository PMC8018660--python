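"""Relationship-quality categorization and temporal-stability statistics.

Differentiation is quantified by splitting the 380 directed dyadic LIKE
values (averaged over the second recording year) into high (LIKE >= 0.75),
intermediate (0.25 < LIKE < 0.75) and low (LIKE <= 0.25) categories.
Stability is the mean of the four squared Pearson correlations between the
dyad vectors of consecutive snapshots taken half a simulated year apart.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CategorySummary",
    "StabilityResult",
    "HIGH_THRESHOLD",
    "LOW_THRESHOLD",
    "offdiag",
    "second_year_mean",
    "categorize",
    "transition_r2",
    "stability_score",
    "read_matrix_csv",
    "write_matrix_csv",
    "plot_level_matrix",
]

HIGH_THRESHOLD = 0.75
LOW_THRESHOLD = 0.25


@dataclass
class CategorySummary:
    """Dyad counts and per-category mean LIKE (NaN for empty categories)."""

    n_high: int
    n_intermediate: int
    n_low: int
    mean_like_high: float
    mean_like_intermediate: float
    mean_like_low: float

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_intermediate + self.n_low


@dataclass
class StabilityResult:
    """Consecutive-snapshot R-squared values and their mean."""

    snapshot_times: list
    transition_r2: list
    mean_r2: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def offdiag(matrix: np.ndarray) -> np.ndarray:
    """The N*(N-1) off-diagonal (directed-dyad) values, row-major order."""
    matrix = np.asarray(matrix, dtype=float)
    mask = ~np.eye(matrix.shape[0], dtype=bool)
    return matrix[mask]


def second_year_mean(samples: np.ndarray, times: np.ndarray,
                     recording_minutes: float) -> np.ndarray:
    """Per-dyad mean over the samples from the second half of recording.

    ``times`` are on the recording clock; the window is
    ``[recording_minutes/2, recording_minutes]`` inclusive (252000-504000
    at full scale, proportional in scaled-down mode).
    """
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = (times >= recording_minutes / 2.0) & (times <= recording_minutes)
    if not sel.any():
        raise ValueError("no samples fall inside the second-year window")
    return samples[sel].mean(axis=0)


def categorize(matrix: np.ndarray) -> CategorySummary:
    """Split a mean-LIKE matrix into high / intermediate / low dyads.

    Boundary convention: value >= 0.75 is high, value <= 0.25 is low,
    strictly between is intermediate.
    """
    vals = offdiag(matrix)
    if np.isnan(vals).any():
        raise ValueError("off-diagonal LIKE values must be defined")
    high = vals >= HIGH_THRESHOLD
    low = vals <= LOW_THRESHOLD
    mid = ~high & ~low

    def _mean(sel: np.ndarray) -> float:
        return float(vals[sel].mean()) if sel.any() else float("nan")

    return CategorySummary(
        n_high=int(high.sum()), n_intermediate=int(mid.sum()),
        n_low=int(low.sum()),
        mean_like_high=_mean(high), mean_like_intermediate=_mean(mid),
        mean_like_low=_mean(low),
    )


def transition_r2(snap_a: np.ndarray, snap_b: np.ndarray) -> float:
    """Squared Pearson correlation over all directed dyads of two snapshots.

    Returns NaN (undefined) when either dyad vector has zero variance,
    e.g. in the all-low or all-high regimes.
    """
    snap_a = np.asarray(snap_a, dtype=float)
    snap_b = np.asarray(snap_b, dtype=float)
    if snap_a.shape != snap_b.shape:
        raise ValueError("snapshot shapes differ")
    va = offdiag(snap_a)
    vb = offdiag(snap_b)
    if va.size < 3:
        raise ValueError("need at least 3 directed dyads")
    # a snapshot pinned at one value (all-low / all-high regimes) has no
    # variance; guard with a tolerance against float summation residue
    if np.ptp(va) < 1e-9 or np.ptp(vb) < 1e-9:
        return float("nan")
    r = np.corrcoef(va, vb)[0, 1]
    return float(r * r)


def stability_score(snapshots: np.ndarray,
                    snapshot_times=None) -> StabilityResult:
    """Mean consecutive-transition R-squared over a snapshot sequence.

    With the default five snapshots this is the average of four transition
    values.  Undefined transitions (zero-variance snapshots) are excluded
    from the mean with a warning.
    """
    snapshots = np.asarray(snapshots, dtype=float)
    if snapshots.shape[0] < 2:
        raise ValueError("need at least 2 snapshots")
    if snapshot_times is None:
        snapshot_times = list(range(snapshots.shape[0]))
    r2s = [transition_r2(snapshots[k], snapshots[k + 1])
           for k in range(snapshots.shape[0] - 1)]
    defined = [v for v in r2s if not np.isnan(v)]
    if len(defined) < len(r2s):
        warnings.warn("zero-variance snapshot(s): undefined transitions "
                      "excluded from the mean R-squared")
    mean = float(np.mean(defined)) if defined else float("nan")
    return StabilityResult(snapshot_times=list(np.asarray(snapshot_times).tolist()),
                           transition_r2=[float(v) for v in r2s], mean_r2=mean)


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Dyadic matrix as CSV with id header row/column (rank order, 1 = top)."""
    ids = [str(i + 1) for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, index_label="id")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def plot_level_matrix(matrix: np.ndarray, path: str | Path,
                      title: str = "") -> None:
    """Grayscale level plot of a dyadic matrix (0.99 black, 0.01 white).

    Individuals are ordered from low ranking (top/left) to high ranking
    (bottom/right), matching the standard presentation of these matrices.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flipped = matrix[::-1, ::-1]  # rank 20 first on both axes
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(flipped, cmap="gray_r", vmin=0.01, vmax=0.99)
    ax.set_xlabel("partner (low -> high rank)")
    ax.set_ylabel("actor (low -> high rank)")
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
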