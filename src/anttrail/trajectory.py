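"""The trajectory container: time-ordered ant body-centre positions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Time-ordered ant centroid positions in arena millimetres.

    Invalid samples (no detection, unbridged gaps) carry NaN positions
    and ``valid = False``; they contribute nothing to any distance.

    Attributes
    ----------
    t_s : (n,) float array
        Sample times, strictly increasing with uniform spacing.
    x_mm, y_mm : (n,) float arrays
        Body-centre position; NaN where invalid.
    valid : (n,) bool array
        Whether the sample holds a usable position.
    frame_period_ms : float
        Sampling period (160 ms after 4-frame temporal binning at 25 Hz).
    interpolated : (n,) bool array
        True where a position was filled by gap interpolation.
    on_trail_true : optional (n,) bool array
        Ground-truth on-trail labels (synthetic trajectories only).
    """

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray
    frame_period_ms: float
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    on_trail_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_s)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.valid) == n):
            raise ValueError("trajectory arrays must share length")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions_mm(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions (NaN where invalid)."""
        return np.column_stack([self.x_mm, self.y_mm])

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "t_s": self.t_s,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "valid": self.valid.astype(int),
                "interpolated": self.interpolated.astype(int),
            }
        )
        if self.on_trail_true is not None:
            df["on_trail_true"] = np.asarray(self.on_trail_true, dtype=int)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        if len(t) > 1:
            period_ms = float(np.median(np.diff(t)) * 1000.0)
        else:
            period_ms = float("nan")
        return cls(
            t_s=t,
            x_mm=df["x_mm"].to_numpy(float),
            y_mm=df["y_mm"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            frame_period_ms=period_ms,
            interpolated=df.get("interpolated", pd.Series(np.zeros(len(t)))).to_numpy(bool),
            on_trail_true=(
                df["on_trail_true"].to_numpy(bool) if "on_trail_true" in df else None
            ),
        )
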