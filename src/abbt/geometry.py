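"""Compartment identification from depth data and ROI extraction.

The box is found by thresholding height above the desk plane: everything
lower than the threshold (desk, box floor, loose cubes) is discarded,
leaving the raised rim and central partition.  The two compartment
interiors are then the enclosed holes of that structure.  Whichever
compartment contains (near) zero raised pixels is the empty one, and its
interior rectangle defines the colour ROI processed by the counting
algorithm.

The default height threshold is 60 mm above the desk: comfortably below
the 100 mm rim and partition, comfortably above the desk, the box floor
and a single loose 25 mm cube.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .frames import DEPTH_MISSING, AlignedFrame, Rect


class GeometryError(RuntimeError):
    """The box structure could not be resolved from the depth data."""


class CompartmentStateError(GeometryError):
    """The test cannot start: neither or both compartments are empty.

    Carries the detected ``left`` and ``right`` :class:`CompartmentInfo`
    so a caller can still inspect (or override) the situation.
    """

    def __init__(self, message: str, left: "CompartmentInfo",
                 right: "CompartmentInfo") -> None:
        super().__init__(message)
        self.left = left
        self.right = right


@dataclass(frozen=True)
class GeometryConfig:
    """Depth-processing parameters (lengths in millimetres).

    ``desk_depth_mm`` / ``floor_depth_mm`` are the known sensor distances of
    the desk plane and the compartment floor (the sensor mount is fixed, so
    these never change between frames).  ``height_threshold_mm`` selects the
    raised box structure; ``occupancy_height_mm`` is the height above the
    compartment floor at which a pixel counts as a cube when checking
    emptiness, and ``emptiness_area_px`` the raised-pixel area below which a
    compartment is declared empty (about half a cube face).
    """

    desk_depth_mm: float = 800.0
    floor_depth_mm: float = 790.0
    height_threshold_mm: float = 60.0
    occupancy_height_mm: float = 12.0
    emptiness_area_px: float = 400.0
    min_region_area_px: int = 200
    morphology_radius_px: int = 1

    def __post_init__(self) -> None:
        if self.height_threshold_mm <= 0:
            raise ValueError("height_threshold_mm must be positive")
        if self.min_region_area_px < 1:
            raise ValueError("min_region_area_px must be >= 1")
        if self.floor_depth_mm > self.desk_depth_mm:
            raise ValueError("box floor cannot be below the desk plane")


@dataclass(frozen=True)
class CompartmentInfo:
    """One detected box side: pixel rectangle, centroid and emptiness flag."""

    side: str  # "left" | "right"
    rect: Rect
    centroid: tuple[float, float]
    is_empty: bool

    def to_dict(self) -> dict:
        return {"side": self.side, "is_empty": self.is_empty,
                "centroid": list(self.centroid),
                "rect": {"top": self.rect.top, "left": self.rect.left,
                         "height": self.rect.height, "width": self.rect.width}}


@dataclass(frozen=True)
class RegistrationMap:
    """Maps every colour pixel to a source depth pixel (or to nothing).

    ``rows``/``cols`` have the colour image shape and hold indices into the
    depth raster; ``-1`` marks colour pixels with no depth correspondence.
    """

    rows: np.ndarray
    cols: np.ndarray

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "RegistrationMap":
        r, c = np.mgrid[0:shape[0], 0:shape[1]]
        return cls(r.astype(np.int64), c.astype(np.int64))

    @classmethod
    def scaling(cls, depth_shape: tuple[int, int],
                colour_shape: tuple[int, int]) -> "RegistrationMap":
        """Nearest-neighbour map from a smaller depth grid onto the colour
        grid (the two sensors of an RGB-D camera have different resolutions)."""
        r = np.minimum((np.arange(colour_shape[0]) * depth_shape[0])
                       // colour_shape[0], depth_shape[0] - 1)
        c = np.minimum((np.arange(colour_shape[1]) * depth_shape[1])
                       // colour_shape[1], depth_shape[1] - 1)
        rr, cc = np.meshgrid(r, c, indexing="ij")
        return cls(rr.astype(np.int64), cc.astype(np.int64))


def align_depth_to_colour(colour: np.ndarray, depth: np.ndarray,
                          registration_map: RegistrationMap | None = None,
                          timestamp_s: float = 0.0) -> AlignedFrame:
    """Resample the depth raster onto the colour pixel grid.

    Colour pixels whose map entry is ``-1`` (no 3-D correspondence) get the
    missing-depth sentinel and are excluded from all later thresholding.
    """
    colour = np.asarray(colour)
    depth = np.asarray(depth)
    if registration_map is None:
        if depth.shape != colour.shape[:2]:
            raise GeometryError("no registration map and shapes differ")
        return AlignedFrame(colour, depth.astype(np.uint16), timestamp_s)
    rows, cols = registration_map.rows, registration_map.cols
    if rows.shape != colour.shape[:2] or cols.shape != colour.shape[:2]:
        raise GeometryError("registration map has wrong dimensions")
    valid = ((rows >= 0) & (rows < depth.shape[0])
             & (cols >= 0) & (cols < depth.shape[1]))
    out = np.full(colour.shape[:2], DEPTH_MISSING, dtype=np.uint16)
    out[valid] = depth[rows[valid], cols[valid]]
    return AlignedFrame(colour, out, timestamp_s)


def threshold_height(frame: AlignedFrame, config: GeometryConfig) -> np.ndarray:
    """Binary mask of pixels higher than ``height_threshold_mm`` above the
    desk plane.  Missing depth is never raised."""
    depth = frame.depth.astype(np.float64)
    height = config.desk_depth_mm - depth
    return (height > config.height_threshold_mm) & (frame.depth != DEPTH_MISSING)


@dataclass(frozen=True)
class LabelledRegion:
    """One connected raised region: area, centroid and bounding rectangle."""

    label: int
    area: int
    centroid: tuple[float, float]
    rect: Rect
    mask_crop: np.ndarray  # boolean raster of the region within ``rect``


def clean_and_label(mask: np.ndarray,
                    config: GeometryConfig) -> list[LabelledRegion]:
    """Morphological opening, 8-connected labelling and small-region removal."""
    cleaned = mask.astype(bool)
    if config.morphology_radius_px > 0:
        footprint = morphology.disk(config.morphology_radius_px)
        cleaned = morphology.opening(cleaned, footprint)
    labels = measure.label(cleaned, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area < config.min_region_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        regions.append(LabelledRegion(
            label=rp.label, area=int(rp.area),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            rect=Rect(r0, c0, r1 - r0, c1 - c0),
            mask_crop=rp.image.copy()))
    return regions


def _compartment_holes(box: LabelledRegion) -> list[Rect]:
    """Interior holes of the raised box structure, largest first, as
    image-coordinate rectangles."""
    filled = ndimage.binary_fill_holes(box.mask_crop)
    holes = filled & ~box.mask_crop
    labels = measure.label(holes, connectivity=1)
    rects = []
    for rp in sorted(measure.regionprops(labels), key=lambda r: -r.area):
        r0, c0, r1, c1 = rp.bbox
        rects.append(Rect(box.rect.top + r0, box.rect.left + c0,
                          r1 - r0, c1 - c0))
    return rects


def occupancy_area(frame: AlignedFrame, rect: Rect,
                   config: GeometryConfig) -> int:
    """Number of pixels inside ``rect`` raised above the compartment floor."""
    depth = frame.depth[rect.slices].astype(np.float64)
    raised = ((config.floor_depth_mm - depth > config.occupancy_height_mm)
              & (frame.depth[rect.slices] != DEPTH_MISSING))
    return int(raised.sum())


def identify_empty_compartment(
        frame: AlignedFrame, regions: Sequence[LabelledRegion],
        config: GeometryConfig) -> tuple[CompartmentInfo, CompartmentInfo]:
    """Locate both compartments and decide which one is empty.

    Returns ``(left, right)`` with exactly one ``is_empty`` flag set.
    Raises :class:`CompartmentStateError` when neither or both compartments
    are empty (the test cannot start), and :class:`GeometryError` when the
    box structure itself cannot be resolved.
    """
    if not regions:
        raise GeometryError("no raised regions: box not visible")
    box = max(regions, key=lambda r: r.area)
    holes = _compartment_holes(box)
    holes = [h for h in holes if h.height * h.width >= config.min_region_area_px]
    if len(holes) < 2:
        raise GeometryError("could not resolve two compartment interiors")
    a, b = sorted(holes[:2], key=lambda r: r.centroid[1])
    infos = []
    for side, rect in (("left", a), ("right", b)):
        area = occupancy_area(frame, rect, config)
        infos.append(CompartmentInfo(side=side, rect=rect,
                                     centroid=rect.centroid,
                                     is_empty=area < config.emptiness_area_px))
    left, right = infos
    if left.is_empty and right.is_empty:
        raise CompartmentStateError(
            "cannot start test: both compartments are empty", left, right)
    if not left.is_empty and not right.is_empty:
        raise CompartmentStateError(
            "cannot start test: both compartments are occupied; "
            "remove the remaining cubes", left, right)
    return left, right


def extract_roi(frame: AlignedFrame, compartment: CompartmentInfo) -> np.ndarray:
    """Colour pixels of a compartment interior (the counting ROI)."""
    if not compartment.rect.inside(frame.shape):
        raise GeometryError("compartment rectangle lies outside the frame")
    return frame.colour[compartment.rect.slices]
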