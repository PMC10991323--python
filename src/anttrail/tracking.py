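"""Single-ant detection and trajectory assembly.

The ant is found by background subtraction: the static scene (paper,
trail line, box) is estimated as a per-pixel temporal median, and in
each frame the darkest sufficiently large connected blob of the
difference image is taken as the ant. Because the trail line belongs to
the static scene it cancels in the subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .trajectory import Trajectory
from .video import BinnedVideo


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationParams:
    """Detection thresholds, in binned-pixel and intensity units.

    threshold_offset
        Minimum darkening (background minus frame) for a pixel to seed
        the ant blob; intensities are on the original 8-bit scale, which
        block-mean binning preserves.
    min_area_px, max_area_px
        Accepted blob area range, in binned pixels.
    max_gap_frames
        Longest run of missed detections bridged by linear
        interpolation (default 3 binned frames, about half a second).
    """

    threshold_offset: float = 30.0
    min_area_px: int = 2
    max_area_px: int = 10_000
    max_gap_frames: int = 3

    def __post_init__(self) -> None:
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must be <= max_area_px")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass(frozen=True)
class Detection:
    """One frame's segmentation result (centroid in arena mm)."""

    frame_index: int
    centroid_mm: tuple[float, float] | None
    area_px: int
    valid: bool


def estimate_background(video: BinnedVideo, max_sample: int = 200) -> np.ndarray:
    """Per-pixel temporal median of the stack.

    A single moving ant occupies any pixel in a small minority of
    frames, so the median recovers the ant-free scene. Stacks longer
    than ``max_sample`` frames are subsampled evenly (at least 100
    frames) to bound memory and time.
    """
    n = video.n_frames
    if n < 3:
        raise TrackingError("need at least 3 frames to estimate a background")
    if n > max_sample:
        idx = np.linspace(0, n - 1, max(100, max_sample)).round().astype(int)
        stack = video.frames[np.unique(idx)]
    else:
        stack = video.frames
    return np.median(stack, axis=0)


def segment_ant(
    frame: np.ndarray,
    background: np.ndarray,
    params: SegmentationParams,
    mm_per_px: float,
    frame_index: int = 0,
    exclusion_mask: np.ndarray | None = None,
) -> Detection:
    """Detect the ant in one binned frame.

    The difference image ``d = background - frame`` is thresholded at
    ``threshold_offset``; 8-connected components with area inside the
    accepted range are candidates, and the largest (ties broken by
    summed difference intensity) wins. Its intensity-weighted centroid,
    with weights d, is returned in arena millimetres. No candidate
    yields an invalid detection.

    ``exclusion_mask`` (optional, True = ignore) drops pixels such as a
    freshly drawn trail band from candidate seeds.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise TrackingError("frame and background dimensions differ")
    d = background - frame
    mask = d > params.threshold_offset
    if exclusion_mask is not None:
        mask &= ~exclusion_mask
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return Detection(frame_index, None, 0, False)
    areas = np.bincount(labels.ravel())[1:]
    candidates = np.flatnonzero(
        (areas >= params.min_area_px) & (areas <= params.max_area_px)
    )
    if candidates.size == 0:
        return Detection(frame_index, None, 0, False)
    best, best_key = -1, (-1, -np.inf)
    for lab in candidates + 1:
        key = (areas[lab - 1], d[labels == lab].sum())
        if key > best_key:
            best, best_key = lab, key
    sel = labels == best
    w = d[sel]
    rows, cols = np.nonzero(sel)
    r = float((rows * w).sum() / w.sum())
    c = float((cols * w).sum() / w.sum())
    x_mm = (c + 0.5) * mm_per_px
    y_mm = (r + 0.5) * mm_per_px
    return Detection(frame_index, (x_mm, y_mm), int(areas[best - 1]), True)


def detect_all(
    video: BinnedVideo,
    params: SegmentationParams | None = None,
    background: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> list[Detection]:
    """Run :func:`segment_ant` on every frame of a binned stack."""
    params = params or SegmentationParams()
    if background is None:
        background = estimate_background(video)
    return [
        segment_ant(video.frames[i], background, params, video.mm_per_px, i, exclusion_mask)
        for i in range(video.n_frames)
    ]


def build_trajectory(
    detections: list[Detection],
    params: SegmentationParams | None = None,
    frame_period_ms: float | None = None,
) -> Trajectory:
    """Assemble detections into a gap-tolerant trajectory.

    Runs of up to ``max_gap_frames`` consecutive misses flanked by valid
    detections are filled by linear interpolation and marked as
    interpolated; longer runs — and leading/trailing misses — stay
    invalid and contribute no walked distance.
    """
    params = params or SegmentationParams()
    if not detections:
        raise TrackingError("no detections supplied")
    if any(
        b.frame_index <= a.frame_index for a, b in zip(detections, detections[1:])
    ):
        raise TrackingError("detections must be ordered by frame index")
    n = len(detections)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, det in enumerate(detections):
        if det.valid and det.centroid_mm is not None:
            x[i], y[i] = det.centroid_mm
            valid[i] = True
    if not valid.any():
        raise TrackingError("zero valid detections: empty trajectory")

    interpolated = np.zeros(n, dtype=bool)
    valid_idx = np.flatnonzero(valid)
    for a, b in zip(valid_idx, valid_idx[1:]):
        gap = b - a - 1
        if 0 < gap <= params.max_gap_frames:
            frac = np.arange(1, gap + 1) / (gap + 1)
            x[a + 1 : b] = x[a] + frac * (x[b] - x[a])
            y[a + 1 : b] = y[a] + frac * (y[b] - y[a])
            valid[a + 1 : b] = True
            interpolated[a + 1 : b] = True

    period = frame_period_ms if frame_period_ms is not None else 160.0
    t = np.array([d.frame_index for d in detections], dtype=float) * period / 1000.0
    return Trajectory(
        t_s=t,
        x_mm=x,
        y_mm=y,
        valid=valid,
        frame_period_ms=period,
        interpolated=interpolated,
    )


def track_video(
    video: BinnedVideo,
    params: SegmentationParams | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> tuple[Trajectory, list[Detection]]:
    """Background estimation + per-frame segmentation + assembly."""
    params = params or SegmentationParams()
    detections = detect_all(video, params, exclusion_mask=exclusion_mask)
    traj = build_trajectory(detections, params, frame_period_ms=video.frame_period_ms)
    return traj, detections
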