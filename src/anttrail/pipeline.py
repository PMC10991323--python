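"""End-to-end orchestration: videos -> trajectories -> metrics ->
heatmaps -> statistics, driven by a single YAML config, plus the
synthetic fixture generator used by the demo and the test suite."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ArenaConfig, ConfigError
from .geometry import TrailLine
from .metrics import accumulate_heatmap, compute_metrics
from .stats import dunnett_vs_control, one_way_anova, pairwise_t_table
from .synthetic import (
    GroupData,
    GroupDesign,
    RenderParams,
    WalkParams,
    group_label,
    render_frames,
    simulate_trajectory,
)
from .tracking import SegmentationParams, TrackingError, track_video
from .trajectory import Trajectory
from .video import VideoFrames, bin_video, read_frames, write_frames

log = logging.getLogger("anttrail")


@dataclass(frozen=True)
class AntRecord:
    ant_id: str
    video: str
    preparation: str
    concentration: str

    @property
    def group(self) -> str:
        return group_label(self.preparation, self.concentration)


@dataclass
class RunConfig:
    """Everything one experiment run needs, serialisable to YAML."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    trail: TrailLine | None = None
    spatial_factor: int = 4
    temporal_factor: int = 4
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    threshold_mm: float = 5.0
    heatmap_cell_mm: float = 2.0
    experiment: list[AntRecord] = field(default_factory=list)
    control_label: str = "blank@-"
    output_dir: str = "anttrail_out"
    seed: int = 0
    analysis_window_s: float = 180.0
    step_rule: str = "both"

    def __post_init__(self) -> None:
        if self.trail is None:
            self.trail = self.arena.default_trail()
        if not self.trail.inside(self.arena.width_mm, self.arena.height_mm):
            raise ConfigError("trail line outside the arena")

    def to_dict(self) -> dict:
        return {
            "arena": dataclasses.asdict(self.arena),
            "trail": {"p1_mm": list(self.trail.p1_mm), "p2_mm": list(self.trail.p2_mm)},
            "binning": {"spatial": self.spatial_factor, "temporal": self.temporal_factor},
            "segmentation": dataclasses.asdict(self.segmentation),
            "threshold_mm": self.threshold_mm,
            "heatmap_cell_mm": self.heatmap_cell_mm,
            "control_label": self.control_label,
            "experiment": [dataclasses.asdict(a) for a in self.experiment],
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "analysis_window_s": self.analysis_window_s,
            "step_rule": self.step_rule,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        binning = d.get("binning", {})
        trail = d.get("trail")
        return cls(
            arena=ArenaConfig(**d.get("arena", {})),
            trail=TrailLine(tuple(trail["p1_mm"]), tuple(trail["p2_mm"])) if trail else None,
            spatial_factor=int(binning.get("spatial", 4)),
            temporal_factor=int(binning.get("temporal", 4)),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            threshold_mm=float(d.get("threshold_mm", 5.0)),
            heatmap_cell_mm=float(d.get("heatmap_cell_mm", 2.0)),
            experiment=[AntRecord(**a) for a in d.get("experiment", [])],
            control_label=d.get("control_label", "blank@-"),
            output_dir=d.get("output_dir", "anttrail_out"),
            seed=int(d.get("seed", 0)),
            analysis_window_s=float(d.get("analysis_window_s", 180.0)),
            step_rule=d.get("step_rule", "both"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def clip_to_window(traj: Trajectory, window_s: float) -> Trajectory:
    """Restrict a trajectory to the analysis window starting at its
    first valid detection (the moment the ant enters the arena)."""
    if not traj.valid.any():
        return traj
    start = traj.t_s[np.flatnonzero(traj.valid)[0]]
    keep = (traj.t_s >= start) & (traj.t_s <= start + window_s)
    return Trajectory(
        t_s=traj.t_s[keep],
        x_mm=traj.x_mm[keep],
        y_mm=traj.y_mm[keep],
        valid=traj.valid[keep],
        frame_period_ms=traj.frame_period_ms,
        interpolated=traj.interpolated[keep],
    )


@dataclass
class RunReport:
    metrics: pd.DataFrame
    group_data: GroupData | None
    anova: object | None
    dunnett: object | None
    heatmaps: dict
    failures: list[dict]
    output_dir: Path


def process_ant(record: AntRecord, cfg: RunConfig) -> tuple[Trajectory, dict]:
    """Single-ant chain: read -> bin -> track -> clip to window."""
    video = read_frames(record.video, frame_rate_hz=cfg.arena.frame_rate_hz)
    binned = bin_video(
        video, cfg.spatial_factor, cfg.temporal_factor, px_per_mm=cfg.arena.px_per_mm
    )
    traj, detections = track_video(binned, cfg.segmentation)
    traj = clip_to_window(traj, cfg.analysis_window_s)
    diag = {
        "n_frames": video.n_frames,
        "n_binned": binned.n_frames,
        "detection_rate": float(np.mean([d.valid for d in detections])),
        "n_interpolated": int(traj.interpolated.sum()),
    }
    return traj, diag


def run_experiment(cfg: RunConfig) -> RunReport:
    """Run the full analysis for every ant in the experiment table.

    Per-ant failures are logged and skipped; the run aborts only if an
    entire group ends up empty. Outputs (per-ant trajectories and
    metrics, per-group heatmaps, the statistics tables and a manifest)
    are written under ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    (out / "heatmaps").mkdir(exist_ok=True)

    rows, failures, diagnostics = [], [], {}
    group_trajs: dict[str, list[Trajectory]] = {}
    for record in cfg.experiment:
        try:
            traj, diag = process_ant(record, cfg)
        except (OSError, ValueError, TrackingError) as exc:
            log.warning("ant %s failed: %s", record.ant_id, exc)
            failures.append({"ant_id": record.ant_id, "error": str(exc)})
            continue
        diagnostics[record.ant_id] = diag
        traj.to_csv(out / "trajectories" / f"{record.ant_id}.csv")
        m = compute_metrics(traj, cfg.trail, cfg.threshold_mm, cfg.step_rule)
        rows.append(
            {
                "ant_id": record.ant_id,
                "preparation": record.preparation,
                "concentration": record.concentration,
                "group": record.group,
                "y_mm": m.on_trail_mm,
                "total_path_mm": m.total_path_mm,
                "on_trail_fraction": m.on_trail_fraction,
            }
        )
        group_trajs.setdefault(record.group, []).append(traj)

    metrics_df = pd.DataFrame(rows)
    expected_groups = {a.group for a in cfg.experiment}
    empty = expected_groups - set(metrics_df.get("group", pd.Series(dtype=str)))
    if empty:
        raise RuntimeError(f"whole group(s) empty after per-ant failures: {sorted(empty)}")
    metrics_df.to_csv(out / "metrics.csv", index=False)

    heatmaps = {}
    for label, trajs in group_trajs.items():
        hm = accumulate_heatmap(trajs, cfg.arena, cfg.heatmap_cell_mm)
        safe = label.replace("/", "_")
        hm.save_csv(out / "heatmaps" / f"{safe}.csv")
        hm.save_png(out / "heatmaps" / f"{safe}.png", title=label)
        heatmaps[label] = hm

    group_data = anova = dunnett = None
    if cfg.control_label in set(metrics_df["group"]) and metrics_df["group"].nunique() >= 2:
        group_data = GroupData(data=metrics_df, control_label=cfg.control_label)
        anova = one_way_anova(group_data)
        dunnett = dunnett_vs_control(group_data, seed=cfg.seed)
        dunnett.to_frame().to_csv(out / "dunnett.csv", index=False)
        with open(out / "anova.txt", "w") as fh:
            fh.write(
                f"one-way ANOVA on ln(y+1): F({anova.df1},{anova.df2}) = "
                f"{anova.F:.2f}, p = {anova.p:.4g}\n"
            )
        preps = [p for p in metrics_df["preparation"].unique() if
                 metrics_df.loc[metrics_df["preparation"] == p, "concentration"].nunique() > 1]
        if len(preps) == 2:
            pairwise_t_table(group_data, (preps[0], preps[1])).to_csv(
                out / "ttests.csv", index=False
            )

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "n_ants": len(rows),
        "failures": failures,
        "diagnostics": diagnostics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunReport(
        metrics=metrics_df,
        group_data=group_data,
        anova=anova,
        dunnett=dunnett,
        heatmaps=heatmaps,
        failures=failures,
        output_dir=out,
    )


def attraction_for_shift(shift: float, base: float = 0.15) -> float:
    """Map a design ln-scale effect to a walk trail-attraction rate.

    Plumbing for fixtures only: shifted groups get proportionally
    stronger heading bias so tracked distances separate by group.
    """
    return base + shift


def make_fixtures(
    cfg: RunConfig,
    design: GroupDesign,
    render: RenderParams | None = None,
    walk: WalkParams | None = None,
    overwrite: bool = False,
) -> RunConfig:
    """Write seeded synthetic videos + ground-truth CSVs for a design.

    One video directory (PNG sequence) and one truth trajectory CSV per
    ant; returns a copy of ``cfg`` whose experiment table points at the
    generated videos, ready for :func:`run_experiment`.
    """
    out = Path(cfg.output_dir) / "fixtures"
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"fixture directory {out} not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    render = render or RenderParams()
    base_walk = walk or WalkParams()
    records = []
    ant = 0
    for gi, (prep, conc) in enumerate(design.groups):
        shift = design.effect_profile.get((prep, conc), 0.0)
        for k in range(design.n_per_group):
            ant += 1
            ant_id = f"ant{ant:04d}"
            wp = dataclasses.replace(
                base_walk,
                trail_attraction=attraction_for_shift(shift),
                seed=(design.seed * 100_003 + gi * 1_009 + k) % (2**31),
            )
            traj = simulate_trajectory(wp, cfg.arena, cfg.trail)
            frames = render_frames(traj, cfg.arena, render, cfg.trail, noise_seed=wp.seed)
            vid_dir = out / ant_id
            write_frames(frames, vid_dir)
            traj.to_csv(out / f"{ant_id}_truth.csv")
            records.append(
                AntRecord(
                    ant_id=ant_id,
                    video=str(vid_dir),
                    preparation=prep,
                    concentration=conc,
                )
            )
    new_cfg = dataclasses.replace(cfg, experiment=records, control_label=group_label(*design.control))
    new_cfg.to_yaml(out / "run_config.yaml")
    return new_cfg
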