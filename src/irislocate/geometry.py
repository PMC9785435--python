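"""Basic geometric types shared across the pipeline.

Coordinate convention: 0-based pixel coordinates, ``x`` is the column and
``y`` the row; circle parameters are continuous (sub-pixel) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates: center ``(cx, cy)``, radius ``r > 0``."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")

    def center_distance(self, other: "Circle") -> float:
        return math.hypot(self.cx - other.cx, self.cy - other.cy)

    def to_dict(self) -> dict:
        return {"cx": float(self.cx), "cy": float(self.cy), "r": float(self.r)}

    @classmethod
    def from_dict(cls, d: dict) -> "Circle":
        return cls(float(d["cx"]), float(d["cy"]), float(d["r"]))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: ``(x, y)`` top-left corner, ``w`` columns, ``h`` rows."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def padded(self, frac: float) -> "BoundingBox":
        """Grow the box by ``frac`` of its size on every side."""
        px, py = self.w * frac, self.h * frac
        return BoundingBox(self.x - px, self.y - py, self.w + 2 * px, self.h + 2 * py)

    def clipped(self, height: int, width: int) -> "BoundingBox":
        x0 = max(0.0, self.x)
        y0 = max(0.0, self.y)
        x1 = min(float(width), self.x + self.w)
        y1 = min(float(height), self.y + self.h)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box does not intersect the image")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)

    def to_dict(self) -> dict:
        return {"x": float(self.x), "y": float(self.y), "w": float(self.w), "h": float(self.h)}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(float(d["x"]), float(d["y"]), float(d["w"]), float(d["h"]))


def circle_bbox(circle: Circle, axis_ratio: float = 1.0) -> BoundingBox:
    """Integer-aligned box tightly enclosing a circle (or the horizontally
    compressed ellipse obtained by scaling the x semi-axis by ``axis_ratio``).

    The box is the integer hull with one pixel of slack — side ``⌈2r⌉ + 1`` —
    mimicking a detector's output, which always regresses a box at least as
    large as the boundary it encloses.
    """
    a = circle.r * axis_ratio
    w = math.ceil(2 * a) + 1
    h = math.ceil(2 * circle.r) + 1
    return BoundingBox(math.floor(circle.cx - a), math.floor(circle.cy - circle.r), w, h)
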