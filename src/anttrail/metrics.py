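"""Trail-following metrics: the 5 mm on-trail rule, the distance walked
on the trail (the assay's response variable y), and occupancy heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ArenaConfig
from .geometry import TrailLine, point_segment_distance
from .trajectory import Trajectory

ON_TRAIL_THRESHOLD_MM = 5.0


@dataclass
class OnTrailSeries:
    """Per-sample on-trail classification for one trajectory."""

    flags: np.ndarray  # bool, aligned with the trajectory
    threshold_mm: float = ON_TRAIL_THRESHOLD_MM


@dataclass(frozen=True)
class TrailMetrics:
    """Per-ant summary of trail following.

    on_trail_mm is the response variable y: the distance walked while
    the body centre stayed within the 5 mm band around the trail line.
    """

    total_path_mm: float
    on_trail_mm: float
    on_trail_fraction: float
    duration_s: float


def on_trail_series(
    traj: Trajectory,
    trail: TrailLine,
    threshold_mm: float = ON_TRAIL_THRESHOLD_MM,
) -> OnTrailSeries:
    """Classify each sample: on-trail iff valid and strictly closer than
    ``threshold_mm`` to the closed trail segment (a distance of exactly
    5 mm is off-trail)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    flags = np.zeros(len(traj), dtype=bool)
    v = traj.valid
    if v.any():
        d = point_segment_distance(traj.positions_mm[v], trail)
        flags[v] = d < threshold_mm
    return OnTrailSeries(flags=flags, threshold_mm=threshold_mm)


def trail_distance(
    traj: Trajectory,
    flags: OnTrailSeries,
    step_rule: str = "both",
) -> TrailMetrics:
    """Accumulate path length and on-trail walked distance.

    Steps are taken between consecutive samples when both endpoints are
    valid; steps spanning invalid samples contribute nothing. A step
    counts toward y when, under the default conservative rule, *both*
    endpoints are flagged on-trail (``step_rule="either"`` credits
    band-crossing steps instead).
    """
    f = np.asarray(flags.flags, dtype=bool)
    if len(f) != len(traj):
        raise ValueError("on-trail flags misaligned with trajectory")
    if step_rule not in ("both", "either"):
        raise ValueError("step_rule must be 'both' or 'either'")
    v = traj.valid
    steps = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
    ok = v[:-1] & v[1:]
    total = float(steps[ok].sum()) if ok.any() else 0.0
    if step_rule == "both":
        on = ok & f[:-1] & f[1:]
    else:
        on = ok & (f[:-1] | f[1:])
    on_trail = float(steps[on].sum()) if on.any() else 0.0
    n_valid = int(v.sum())
    frac = float(f.sum() / n_valid) if n_valid else 0.0
    duration = float(traj.t_s[-1] - traj.t_s[0]) if len(traj) > 1 else 0.0
    return TrailMetrics(
        total_path_mm=total,
        on_trail_mm=on_trail,
        on_trail_fraction=frac,
        duration_s=duration,
    )


def compute_metrics(
    traj: Trajectory,
    trail: TrailLine,
    threshold_mm: float = ON_TRAIL_THRESHOLD_MM,
    step_rule: str = "both",
) -> TrailMetrics:
    """Convenience: classification + accumulation in one call."""
    return trail_distance(traj, on_trail_series(traj, trail, threshold_mm), step_rule)


@dataclass
class Heatmap:
    """Accumulated occupancy grid over the arena for a group of ants.

    ``counts[r, c]`` is the number of valid trajectory samples falling
    in that cell; ``probability()`` renders counts as the spatial
    passage probability.
    """

    counts: np.ndarray
    cell_mm: float
    n_ants: int

    def probability(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")

    def save_png(self, path: str | Path, title: str | None = None) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(self.probability(), cmap="inferno", origin="upper", aspect="equal")
        fig.colorbar(im, ax=ax, label="passage probability")
        ax.set_xlabel(f"x ({self.cell_mm:g} mm cells)")
        ax.set_ylabel(f"y ({self.cell_mm:g} mm cells)")
        if title:
            ax.set_title(title)
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def accumulate_heatmap(
    trajectories: list[Trajectory],
    arena: ArenaConfig,
    cell_mm: float = 2.0,
) -> Heatmap:
    """Accumulate all valid samples of a group into one occupancy grid.

    Samples on a cell edge go to the higher-index cell; positions on
    the far arena border fall into the last cell.
    """
    if cell_mm <= 0:
        raise ValueError("cell_mm must be positive")
    n_rows = int(np.ceil(arena.height_mm / cell_mm))
    n_cols = int(np.ceil(arena.width_mm / cell_mm))
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    for traj in trajectories:
        v = traj.valid
        if not v.any():
            continue
        cols = np.clip(np.floor(traj.x_mm[v] / cell_mm).astype(int), 0, n_cols - 1)
        rows = np.clip(np.floor(traj.y_mm[v] / cell_mm).astype(int), 0, n_rows - 1)
        np.add.at(counts, (rows, cols), 1)
    return Heatmap(counts=counts, cell_mm=cell_mm, n_ants=len(trajectories))
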