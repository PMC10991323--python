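"""Video I/O and the spatio-temporal binning used to compress assay videos.

Recordings (720 x 1280 px, 25 frames/s) are compressed by averaging
4 x 4 pixel blocks and runs of 4 consecutive frames before tracking,
which brings the pixel pitch to roughly a millimetre and the frame
period to 160 ms while preserving the intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import ConfigError

_SEQUENCE_EXTS = (".png", ".tif", ".tiff")

# ITU-R BT.601 luminance weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class VideoReadError(IOError):
    """Raised when a video source cannot be read."""


@dataclass
class VideoFrames:
    """An ordered grayscale frame stack with acquisition metadata."""

    frames: np.ndarray  # (n, h, w)
    frame_rate_hz: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class BinnedVideo:
    """A spatio-temporally binned stack with updated calibration.

    Each binned pixel is the arithmetic mean of a
    ``spatial_factor x spatial_factor`` block averaged over
    ``temporal_factor`` consecutive frames, so intensities stay on the
    original scale and segmentation thresholds are resolution-independent.
    """

    frames: np.ndarray  # (n, h, w) float
    spatial_factor: int
    temporal_factor: int
    mm_per_px: float
    frame_period_ms: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def pixel_to_mm(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """Map binned pixel-centre (row, col) to arena (x_mm, y_mm)."""
        x = (np.asarray(cols, dtype=float) + 0.5) * self.mm_per_px
        y = (np.asarray(rows, dtype=float) + 0.5) * self.mm_per_px
        return x, y


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return (frame[..., :3].astype(float) @ _LUMA).astype(frame.dtype)
    raise VideoReadError(f"unsupported frame shape {frame.shape}")


def read_frames(source: str | Path, frame_rate_hz: float = 25.0) -> VideoFrames:
    """Read a grayscale frame stack.

    ``source`` may be a directory of numbered PNG/TIFF frames (sorted by
    name; the lossless interchange format used throughout) or a video
    container readable by imageio. Colour input is converted to
    luminance.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(p for p in source.iterdir() if p.suffix.lower() in _SEQUENCE_EXTS)
        if not paths:
            raise VideoReadError(f"no PNG/TIFF frames found in {source}")
        frames = np.stack([_to_gray(iio.imread(p)) for p in paths])
    elif source.exists():
        try:
            raw = iio.imread(source, index=None)
        except Exception as exc:  # pragma: no cover - plugin-dependent
            raise VideoReadError(f"cannot read video container {source}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([_to_gray(f) for f in raw])
    else:
        raise VideoReadError(f"video source does not exist: {source}")
    if frames.shape[0] == 0:
        raise VideoReadError(f"zero frames in {source}")
    bit_depth = 16 if frames.dtype == np.uint16 else 8
    return VideoFrames(frames=frames, frame_rate_hz=frame_rate_hz, bit_depth=bit_depth)


def write_frames(video: VideoFrames, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a stack as a numbered PNG sequence (lossless round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(video.n_frames)))
    paths = []
    for i, frame in enumerate(video.frames):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def bin_video(
    video: VideoFrames,
    spatial_factor: int = 4,
    temporal_factor: int = 4,
    px_per_mm: float = 8.0,
) -> BinnedVideo:
    """Compress a stack by block-mean binning in space and time.

    Trailing frames, rows and columns that do not fill a whole bin are
    dropped (floor semantics), so every output value is an unweighted
    mean of a full ``temporal x spatial x spatial`` block.

    Parameters
    ----------
    spatial_factor, temporal_factor
        Bin sizes; the assay default is 4 and 4, giving a 160 ms frame
        period at 25 frames/s.
    px_per_mm
        Pre-binning calibration, used to set ``mm_per_px`` of the output.
    """
    if spatial_factor < 1 or temporal_factor < 1:
        raise ValueError("binning factors must be >= 1")
    f = np.asarray(video.frames, dtype=float)
    n, h, w = f.shape
    nt = n // temporal_factor
    nh = h // spatial_factor
    nw = w // spatial_factor
    if nt == 0 or nh == 0 or nw == 0:
        raise ValueError("stack smaller than one bin")
    f = f[: nt * temporal_factor, : nh * spatial_factor, : nw * spatial_factor]
    f = f.reshape(nt, temporal_factor, nh, spatial_factor, nw, spatial_factor)
    binned = f.mean(axis=(1, 3, 5))
    return BinnedVideo(
        frames=binned,
        spatial_factor=spatial_factor,
        temporal_factor=temporal_factor,
        mm_per_px=spatial_factor / px_per_mm,
        frame_period_ms=1000.0 * temporal_factor / video.frame_rate_hz,
    )


def check_calibration(arena_width_px: int, arena_height_px: int, video: VideoFrames) -> None:
    """Raise if the frame size disagrees with the configured arena."""
    if (video.height_px, video.width_px) != (arena_height_px, arena_width_px):
        raise ConfigError(
            f"frame size {video.height_px}x{video.width_px} does not match "
            f"arena calibration {arena_height_px}x{arena_width_px}"
        )
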