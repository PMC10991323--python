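"""Arena geometry: the trail line and point-to-segment distances.

All coordinates are arena millimetres with the origin at the arena's
top-left corner, x increasing rightward and y downward (matching image
row/column order after calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate or out-of-bounds geometric configurations."""


@dataclass(frozen=True)
class TrailLine:
    """The marked line segment onto which test solutions are applied.

    All trail-following distances are measured against this segment.

    Parameters
    ----------
    p1_mm, p2_mm
        Segment endpoints in arena millimetres, as ``(x, y)`` pairs.
    """

    p1_mm: tuple[float, float]
    p2_mm: tuple[float, float]

    def __post_init__(self) -> None:
        p1 = np.asarray(self.p1_mm, dtype=float)
        p2 = np.asarray(self.p2_mm, dtype=float)
        if p1.shape != (2,) or p2.shape != (2,):
            raise GeometryError("trail endpoints must be (x, y) pairs")
        if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
            raise GeometryError("trail endpoints must be finite")
        if np.allclose(p1, p2):
            raise GeometryError("degenerate trail line: p1 == p2")

    @property
    def length_mm(self) -> float:
        return float(np.hypot(*(np.subtract(self.p2_mm, self.p1_mm))))

    def inside(self, width_mm: float, height_mm: float) -> bool:
        """Whether both endpoints lie inside a ``width x height`` arena."""
        for x, y in (self.p1_mm, self.p2_mm):
            if not (0.0 <= x <= width_mm and 0.0 <= y <= height_mm):
                return False
        return True


def point_segment_distance(q, trail: TrailLine) -> np.ndarray | float:
    """Euclidean distance from point(s) ``q`` to the closed segment.

    The segment is endpoint-capped: beyond either end the distance is to
    that endpoint, so the 5 mm on-trail band is a stadium, not an
    infinite strip.

    Parameters
    ----------
    q
        ``(x, y)`` in mm, or an ``(n, 2)`` array of points.
    trail
        The trail line segment.

    Returns
    -------
    Scalar distance for a single point, else an ``(n,)`` array.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 1
    pts = np.atleast_2d(q)
    if not np.isfinite(pts).all():
        raise GeometryError("non-finite query point")
    p1 = np.asarray(trail.p1_mm, dtype=float)
    d = np.asarray(trail.p2_mm, dtype=float) - p1
    # Projection parameter clamped to the closed segment.
    t = np.clip(((pts - p1) @ d) / (d @ d), 0.0, 1.0)
    closest = p1 + t[:, None] * d
    dist = np.hypot(*(pts - closest).T)
    return float(dist[0]) if scalar else dist
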