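"""Core raster containers shared across the pipeline.

An :class:`AlignedFrame` is the unit of input everywhere: one colour raster
and one depth raster that have already been registered onto the same pixel
grid, plus the capture timestamp.  Depth is stored in integer millimetres
from the sensor, with 0 reserved for "no measurement" (pixels that had no
corresponding 3-D coordinate during registration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: depth value marking pixels with no valid range measurement
DEPTH_MISSING = 0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, row-major, origin top-left, half-open."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("Rect must have positive size")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.top + (self.height - 1) / 2.0,
                self.left + (self.width - 1) / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.bottom), slice(self.left, self.right))

    def contains_point(self, row: float, col: float) -> bool:
        return (self.top <= row < self.bottom) and (self.left <= col < self.right)

    def contains_rect(self, other: "Rect") -> bool:
        return (self.top <= other.top and other.bottom <= self.bottom
                and self.left <= other.left and other.right <= self.right)

    def inside(self, shape: tuple[int, int]) -> bool:
        return (self.top >= 0 and self.left >= 0
                and self.bottom <= shape[0] and self.right <= shape[1])

    def mirrored_horizontally(self, image_width: int) -> "Rect":
        return Rect(self.top, image_width - self.right, self.height, self.width)


@dataclass(frozen=True)
class AlignedFrame:
    """A registered colour/depth pair.

    Attributes
    ----------
    colour:
        ``(H, W, 3)`` uint8 sRGB raster.
    depth:
        ``(H, W)`` uint16 raster, millimetres from the sensor along its
        optical axis; ``0`` means missing.
    timestamp_s:
        Seconds from the start of the current test stage.
    """

    colour: np.ndarray
    depth: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if self.colour.ndim != 3 or self.colour.shape[2] != 3:
            raise ValueError("colour raster must be (H, W, 3)")
        if self.colour.dtype != np.uint8:
            raise ValueError("colour raster must be uint8 sRGB")
        if self.depth.shape != self.colour.shape[:2]:
            raise ValueError("colour and depth rasters must share pixel dimensions")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.colour.shape[:2]
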