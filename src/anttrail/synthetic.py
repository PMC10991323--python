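"""Ground-truthed synthetic data for every stage of the assay pipeline.

Three generators, all seeded and deterministic:

* :func:`simulate_trajectory` — a correlated random walk with an
  adjustable heading bias toward the trail line, reflecting at the
  arena walls. With zero attraction the walk explores the arena
  diffusely; with strong attraction it produces the tight line-following
  seen in trail-pheromone assays.
* :func:`render_frames` — grayscale frames of a dark ant-sized ellipse
  moving over a light paper background crossed by a grey trail line.
* :func:`simulate_group_distances` — per-ant on-trail walking distances
  y for a multi-group design, drawn so that ln(y + 1) is normal; this
  makes the parametric assumptions of the statistics stage true by
  construction.

The walk is a test harness, not a locomotion model of any ant species:
its speed and turning defaults are assumptions chosen to produce
plausible-looking arena coverage, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArenaConfig
from .geometry import GeometryError, TrailLine, point_segment_distance
from .trajectory import Trajectory
from .video import VideoFrames

ON_TRAIL_THRESHOLD_MM = 5.0


@dataclass(frozen=True)
class WalkParams:
    """Correlated-random-walk parameters.

    mean_speed_mm_s
        Walking speed while moving. Default 20 mm/s.
    turn_concentration
        Directional persistence kappa (1/rad^2/s); per-step turning
        noise has sd sqrt(dt / kappa). kappa = 0 draws a fresh uniform
        heading every step.
    trail_attraction
        Relaxation rate (1/s) of the heading toward the bearing of the
        nearest trail-line point; 0 disables the bias.
    pause_prob
        Per-step probability of standing still.
    """

    mean_speed_mm_s: float = 20.0
    turn_concentration: float = 5.0
    trail_attraction: float = 0.0
    pause_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed_mm_s < 0:
            raise ValueError("mean_speed_mm_s must be >= 0")
        if self.turn_concentration < 0:
            raise ValueError("turn_concentration must be >= 0")
        if self.trail_attraction < 0:
            raise ValueError("trail_attraction must be >= 0")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be a probability")


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered arena frames (8-bit grey levels)."""

    ant_length_mm: float = 5.0
    ant_intensity: float = 40.0
    background_intensity: float = 220.0
    line_intensity: float = 150.0
    line_halfwidth_mm: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.ant_intensity < self.background_intensity:
            raise ValueError("ant must be darker than the background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def simulate_trajectory(
    walk: WalkParams,
    arena: ArenaConfig,
    trail: TrailLine,
    start_heading_rad: float | None = None,
) -> Trajectory:
    """Simulate one ant walk, sampled at the arena frame rate.

    The ant starts at the midpoint of the left short wall (where the
    entry tube meets the arena), heading inward. Each step the heading
    relaxes toward the bearing of the nearest trail-line point at rate
    ``trail_attraction`` and receives wrapped-normal turning noise;
    walls reflect specularly. Ground-truth on-trail labels (< 5 mm to
    the segment) are stored on the returned trajectory.
    """
    if not trail.inside(arena.width_mm, arena.height_mm):
        raise GeometryError("trail line lies outside the arena")
    rng = np.random.default_rng(walk.seed)
    dt = 1.0 / arena.frame_rate_hz
    n = arena.n_frames
    w, h = arena.width_mm, arena.height_mm

    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([min(2.0, w / 2), h / 2.0])
    theta = 0.0 if start_heading_rad is None else float(start_heading_rad)

    p1 = np.asarray(trail.p1_mm)
    seg = np.asarray(trail.p2_mm) - p1
    seg_len2 = seg @ seg
    sigma = np.sqrt(dt / walk.turn_concentration) if walk.turn_concentration > 0 else None

    for i in range(n):
        x[i], y[i] = pos
        # heading bias toward the nearest point of the trail segment
        if walk.trail_attraction > 0:
            t = np.clip(((pos - p1) @ seg) / seg_len2, 0.0, 1.0)
            to_line = p1 + t * seg - pos
            dist = np.hypot(*to_line)
            if dist > 1e-9:
                bearing = np.arctan2(to_line[1], to_line[0])
                theta += np.clip(walk.trail_attraction * dt, 0.0, 1.0) * _wrap_angle(
                    bearing - theta
                )
        if sigma is None:
            theta = rng.uniform(-np.pi, np.pi)
        else:
            theta = _wrap_angle(theta + sigma * rng.standard_normal())
        if rng.random() >= walk.pause_prob:
            pos = pos + walk.mean_speed_mm_s * dt * np.array([np.cos(theta), np.sin(theta)])
            # specular wall reflection (repeat in case a corner is clipped)
            for _ in range(4):
                moved = False
                if pos[0] < 0 or pos[0] > w:
                    pos[0] = -pos[0] if pos[0] < 0 else 2 * w - pos[0]
                    theta = _wrap_angle(np.pi - theta)
                    moved = True
                if pos[1] < 0 or pos[1] > h:
                    pos[1] = -pos[1] if pos[1] < 0 else 2 * h - pos[1]
                    theta = _wrap_angle(-theta)
                    moved = True
                if not moved:
                    break

    dist = point_segment_distance(np.column_stack([x, y]), trail)
    return Trajectory(
        t_s=np.arange(n) * dt,
        x_mm=x,
        y_mm=y,
        valid=np.ones(n, dtype=bool),
        frame_period_ms=1000.0 * dt,
        on_trail_true=dist < ON_TRAIL_THRESHOLD_MM,
    )


def arena_template(arena: ArenaConfig, trail: TrailLine, rp: RenderParams) -> np.ndarray:
    """Background-plus-line frame: uniform paper with the grey trail band."""
    h, w = arena.height_px, arena.width_px
    rows, cols = np.mgrid[0:h, 0:w]
    xm = (cols + 0.5) / arena.px_per_mm
    ym = (rows + 0.5) / arena.px_per_mm
    d = point_segment_distance(np.column_stack([xm.ravel(), ym.ravel()]), trail)
    template = np.full((h, w), rp.background_intensity, dtype=float)
    template.ravel()[d < rp.line_halfwidth_mm] = rp.line_intensity
    return template


def _stamp_ant(
    frame: np.ndarray,
    cx_px: float,
    cy_px: float,
    heading: float,
    a_px: float,
    b_px: float,
    intensity: float,
    supersample: int = 3,
) -> None:
    """Alpha-blend an anti-aliased ellipse into ``frame`` in place."""
    h, w = frame.shape
    r = int(np.ceil(a_px)) + 2
    r0, r1 = max(0, int(cy_px) - r), min(h, int(cy_px) + r + 1)
    c0, c1 = max(0, int(cx_px) - r), min(w, int(cx_px) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    rows = np.arange(r0, r1)[:, None] + off[None, :]  # subpixel rows
    cols = np.arange(c0, c1)[:, None] + off[None, :]
    dy = rows.reshape(-1, 1, s, 1) - cy_px
    dx = cols.reshape(1, -1, 1, s) - cx_px
    ca, sa = np.cos(heading), np.sin(heading)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    alpha = inside.mean(axis=(2, 3))
    patch = frame[r0:r1, c0:c1]
    patch *= 1.0 - alpha
    patch += alpha * intensity


def render_frames(
    traj: Trajectory,
    arena: ArenaConfig,
    rp: RenderParams | None = None,
    trail: TrailLine | None = None,
    noise_seed: int = 0,
) -> VideoFrames:
    """Render one grayscale frame per trajectory sample.

    The ant is a dark anti-aliased ellipse centred on the true position
    and oriented along the direction of motion; invalid samples render
    the bare background-plus-line template. The ellipse is symmetric
    about its centre, so its intensity-weighted centroid equals the true
    position up to the pixel sampling.
    """
    rp = rp or RenderParams()
    trail = trail or arena.default_trail()
    xs, ys = traj.x_mm, traj.y_mm
    v = traj.valid
    if np.any((xs[v] < 0) | (xs[v] > arena.width_mm) | (ys[v] < 0) | (ys[v] > arena.height_mm)):
        raise GeometryError("trajectory positions outside the arena")
    template = arena_template(arena, trail, rp)
    a_px = 0.5 * rp.ant_length_mm * arena.px_per_mm
    b_px = a_px / 2.5
    rng = np.random.default_rng(noise_seed)

    # headings from motion direction; carry the last heading through pauses
    headings = np.zeros(len(traj))
    last = 0.0
    for i in range(len(traj)):
        if i + 1 < len(traj) and v[i] and v[i + 1]:
            dx, dy = xs[i + 1] - xs[i], ys[i + 1] - ys[i]
            if abs(dx) > 1e-12 or abs(dy) > 1e-12:
                last = np.arctan2(dy, dx)
        headings[i] = last

    frames = np.empty((len(traj), template.shape[0], template.shape[1]), dtype=np.uint8)
    for i in range(len(traj)):
        frame = template.copy()
        if v[i]:
            cx = xs[i] * arena.px_per_mm - 0.5
            cy = ys[i] * arena.px_per_mm - 0.5
            _stamp_ant(frame, cx, cy, headings[i], a_px, b_px, rp.ant_intensity)
        if rp.noise_sd > 0:
            frame += rng.normal(0.0, rp.noise_sd, size=frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return VideoFrames(frames=frames, frame_rate_hz=arena.frame_rate_hz)


# ---------------------------------------------------------------------------
# group-level walking-distance simulation


@dataclass(frozen=True)
class GroupDesign:
    """A multi-group assay design for simulated walking distances.

    groups
        Ordered ``(preparation, concentration)`` label pairs; exactly
        one must equal ``control``.
    effect_profile
        Mapping from group label pair to the expected shift of the
        ln(y + 1) group mean relative to control (missing groups shift 0).
    control_ln_mean
        Control-group mean of ln(y + 1); the default corresponds to a
        median on-trail distance of roughly 55 mm in 3 min.
    dispersion
        Common within-group sd of ln(y + 1). The default (0.75) places
        the canonical 1.5-ln-unit high-dose effect at ~99% per-comparison
        Dunnett power for n = 15, matching the clear-cut significance
        pattern a strong trail pheromone produces at high doses.
    nonresponder_prob
        Probability that an ant never leaves the entry tube; such ants
        are excluded from the data (tallied in ``GroupData.excluded``).
    """

    groups: tuple[tuple[str, str], ...]
    n_per_group: int = 15
    effect_profile: dict[tuple[str, str], float] = field(default_factory=dict)
    control: tuple[str, str] = ("blank", "-")
    control_ln_mean: float = 4.0
    dispersion: float = 0.75
    nonresponder_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if list(self.groups).count(self.control) != 1:
            raise ValueError("control group must be present exactly once")
        if not 0.0 <= self.nonresponder_prob <= 1.0:
            raise ValueError("nonresponder_prob must be a probability")


def group_label(preparation: str, concentration: str) -> str:
    return f"{preparation}@{concentration}"


@dataclass
class GroupData:
    """Per-ant walking distances keyed by preparation x concentration.

    ``data`` columns: ant_id, preparation, concentration, group, y_mm.
    """

    data: pd.DataFrame
    control_label: str
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"ant_id", "preparation", "concentration", "group", "y_mm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GroupData missing columns: {sorted(missing)}")
        if (self.data["y_mm"] < 0).any():
            raise ValueError("y_mm must be non-negative")
        if self.control_label not in set(self.data["group"]):
            raise ValueError(f"control group {self.control_label!r} absent from data")

    @property
    def labels(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def values(self, label: str) -> np.ndarray:
        sub = self.data.loc[self.data["group"] == label, "y_mm"]
        if sub.empty:
            raise KeyError(f"unknown group label {label!r}")
        return sub.to_numpy(float)


def simulate_group_distances(design: GroupDesign) -> GroupData:
    """Draw per-ant on-trail distances for every group in the design.

    ln(y + 1) is normal with mean ``control_ln_mean + shift`` and the
    common dispersion; y is clipped at 0 (with the default means the
    clip probability is below 1e-4, so normality holds in practice).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    excluded: dict[str, int] = {}
    ant = 0
    for prep, conc in design.groups:
        label = group_label(prep, conc)
        shift = design.effect_profile.get((prep, conc), 0.0)
        n_out = 0
        for _ in range(design.n_per_group):
            ant += 1
            if design.nonresponder_prob > 0 and rng.random() < design.nonresponder_prob:
                n_out += 1
                continue
            ln_y1 = design.control_ln_mean + shift + design.dispersion * rng.standard_normal()
            rows.append(
                {
                    "ant_id": f"ant{ant:04d}",
                    "preparation": prep,
                    "concentration": conc,
                    "group": label,
                    "y_mm": max(0.0, float(np.expm1(ln_y1))),
                }
            )
        if n_out:
            excluded[label] = n_out
    return GroupData(
        data=pd.DataFrame(rows),
        control_label=group_label(*design.control),
        excluded=excluded,
    )


CONCENTRATION_LADDER = ("1e-3", "1e-2", "1e-1", "1e0", "1e1")


def default_design(
    n_per_group: int = 15,
    seed: int = 0,
    high_shift: float = 1.5,
    shifted_concentrations: tuple[str, ...] = ("1e0", "1e1"),
    dispersion: float = 0.75,
) -> GroupDesign:
    """The 13-group assay design: two compounds across the concentration
    ladder, a gland-extract positive group, and solvent/blank controls.

    ``high_shift`` is applied (on the ln scale) to the compounds at the
    listed concentrations and to the extract group, mirroring a
    dose-response in which only high doses recruit ants to the line.
    """
    groups: list[tuple[str, str]] = [("blank", "-"), ("hexane", "-")]
    profile: dict[tuple[str, str], float] = {}
    for prep in ("2-tridecanol", "2-dodecanol"):
        for conc in CONCENTRATION_LADDER:
            groups.append((prep, conc))
            if conc in shifted_concentrations:
                profile[(prep, conc)] = high_shift
    groups.append(("tibia-extract", "-"))
    profile[("tibia-extract", "-")] = high_shift
    return GroupDesign(
        groups=tuple(groups),
        n_per_group=n_per_group,
        effect_profile=profile,
        control=("blank", "-"),
        dispersion=dispersion,
        seed=seed,
    )
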