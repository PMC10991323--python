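"""Arena and recording configuration."""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import TrailLine


class ConfigError(ValueError):
    """Raised for inconsistent or invalid configuration."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and recording parameters of the behavioural arena.

    The assay films a paper sheet crossed lengthwise by a grey trail
    line; positions are expressed in arena millimetres (origin top-left,
    x rightward, y downward). Pixels are square: frame dimensions are
    ``round(mm * px_per_mm)``.

    Parameters
    ----------
    width_mm, height_mm
        Arena extent in mm. Defaults give the recorded 16:9 view of the
        160 mm-wide assay sheet.
    px_per_mm
        Camera calibration. The default (8 px/mm) yields 720 x 1280
        frames; after 4 x 4 binning the pixel pitch is 0.5 mm.
    frame_rate_hz
        Acquisition rate (25 frames/s).
    duration_s
        Recording length (180 s, the 3-minute assay window).
    """

    width_mm: float = 160.0
    height_mm: float = 90.0
    px_per_mm: float = 8.0
    frame_rate_hz: float = 25.0
    duration_s: float = 180.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "px_per_mm", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.duration_s < 0:
            raise ConfigError("duration_s must be non-negative")

    @property
    def width_px(self) -> int:
        return int(round(self.width_mm * self.px_per_mm))

    @property
    def height_px(self) -> int:
        return int(round(self.height_mm * self.px_per_mm))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def default_trail(self, margin_mm: float = 5.0) -> TrailLine:
        """Lengthwise trail line through the arena midline."""
        y = self.height_mm / 2.0
        return TrailLine((margin_mm, y), (self.width_mm - margin_mm, y))
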