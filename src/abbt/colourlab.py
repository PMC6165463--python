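"""CIELab conversion, colour-marker calibration and NN pixel classification.

The counting algorithm works in the CIELab colour space because the cube
colours (red, green, blue, yellow) sit at the extremes of its two opponent
chromatic axes, a* (green-red) and b* (blue-yellow), while ambient-light
changes move pixels mostly along the separate lightness axis L*.  Each of
the five classes (the four cube colours plus the beech box background) is
represented by a single calibrated marker -- its mean (L*, a*, b*) -- and
every ROI pixel is assigned the label of the nearest marker by Euclidean
distance in the (a*, b*) plane alone.  L* is deliberately ignored, which is
what makes the classification insensitive to illumination.

Label convention: background=0, red=1, blue=2, yellow=3, green=4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature, morphology
from skimage.color import rgb2lab

from .frames import AlignedFrame, Rect
from . import geometry

LABEL_NAMES = {0: "background", 1: "red", 2: "blue", 3: "yellow", 4: "green"}
NAME_LABELS = {name: label for label, name in LABEL_NAMES.items()}
CUBE_LABELS = (1, 2, 3, 4)


class CalibrationError(RuntimeError):
    """A colour marker could not be calibrated."""


def srgb_to_cielab(raster: np.ndarray) -> np.ndarray:
    """Per-pixel sRGB -> CIELab (D65 white point, 2 degree observer).

    Accepts an 8-bit ``(H, W, 3)`` raster and returns float64 ``(H, W, 3)``
    with channels (L*, a*, b*).
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3 or raster.dtype != np.uint8:
        raise ValueError("expected an (H, W, 3) uint8 sRGB raster")
    return rgb2lab(raster)


@dataclass(frozen=True)
class ColourMarker:
    """One calibrated class reference: mean L*, a*, b* and, for the cube
    colours, the reference pixel area of a single cube face."""

    label: int
    name: str
    L_mean: float
    a_mean: float
    b_mean: float
    single_cube_area_px: float | None = None

    def __post_init__(self) -> None:
        if LABEL_NAMES.get(self.label) != self.name:
            raise ValueError(f"label {self.label} does not match name {self.name!r}")
        if self.label in CUBE_LABELS:
            if not (self.single_cube_area_px and self.single_cube_area_px > 0):
                raise ValueError("cube markers need single_cube_area_px > 0")


class MarkerSet:
    """The complete, ordered set of the five colour markers."""

    def __init__(self, markers: Sequence[ColourMarker]) -> None:
        by_label = {m.label: m for m in markers}
        if sorted(by_label) != sorted(LABEL_NAMES):
            raise ValueError("a complete marker set has exactly labels 0-4")
        self.markers = tuple(by_label[label] for label in sorted(by_label))
        self.a = np.array([m.a_mean for m in self.markers])
        self.b = np.array([m.b_mean for m in self.markers])

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, label: int) -> ColourMarker:
        return self.markers[label]

    def single_cube_area(self, label: int) -> float:
        area = self.markers[label].single_cube_area_px
        if area is None:
            raise ValueError(f"label {label} has no reference cube area")
        return area

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {"label": m.label, "name": m.name, "L_mean": m.L_mean,
             "a_mean": m.a_mean, "b_mean": m.b_mean,
             "single_cube_area_px": m.single_cube_area_px}
            for m in self.markers]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MarkerSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls([ColourMarker(**entry) for entry in json.loads(text)])


@dataclass(frozen=True)
class CalibrationConfig:
    """Parameters of the Canny-based cube-boundary extraction.

    Edges are detected on the chromatic channels (a*, b*), where every cube
    colour contrasts strongly with the beech floor; luminance contrast alone
    can be near zero (yellow on beech).  Thresholds are absolute gradient
    magnitudes on channels normalised to [0, 1].
    """

    canny_sigma: float = 1.0
    canny_low: float = 0.02
    canny_high: float = 0.05
    min_region_area_px: int = 80
    boundary_margin_px: int = 1


def _cube_interiors(roi: np.ndarray, config: CalibrationConfig) -> np.ndarray:
    """Label image of closed cube interiors found inside a colour ROI.

    Canny edges delimit the cube boundaries; filling the closed contours and
    stripping the boundary band leaves the interior pixels whose colour is
    averaged into the marker.
    """
    lab = srgb_to_cielab(roi)
    edges = np.zeros(roi.shape[:2], dtype=bool)
    for channel in (1, 2):
        normalised = (lab[..., channel] + 128.0) / 255.0
        edges |= feature.canny(normalised, sigma=config.canny_sigma,
                               low_threshold=config.canny_low,
                               high_threshold=config.canny_high)
    closed = morphology.closing(edges, morphology.disk(1))
    filled = ndimage.binary_fill_holes(closed)
    interiors = filled & ~morphology.dilation(
        closed, morphology.disk(config.boundary_margin_px))
    interiors = morphology.remove_small_objects(
        interiors, max_size=config.min_region_area_px - 1)
    return ndimage.label(interiors)[0]


def calibrate_markers(
        calibration_images: Mapping[str, AlignedFrame],
        background_samples: Sequence[tuple[int, int]],
        geometry_config: geometry.GeometryConfig | None = None,
        calibration_config: CalibrationConfig | None = None) -> MarkerSet:
    """Build the complete five-marker set from per-colour calibration frames.

    Each frame must show several cubes of one colour inside one compartment.
    Per colour: the occupied compartment's ROI is extracted, Canny edges
    delimit the cube boundaries, and the CIELab values of all interior
    pixels are averaged into the marker.  The background marker is the mean
    CIELab value at the given (row, col) box-floor positions, averaged
    across all calibration frames.

    The reference single-cube area is then measured in a second pass by
    classifying each calibration ROI with the freshly built markers and
    averaging the resulting region areas -- the same measurement the counter
    applies at run time, so the area ratio of a single cube is centred on 1.
    """
    geo = geometry_config or geometry.GeometryConfig()
    cal = calibration_config or CalibrationConfig()
    missing = set(NAME_LABELS) - {"background"} - set(calibration_images)
    if missing:
        raise CalibrationError(f"missing calibration images for {sorted(missing)}")

    markers: list[ColourMarker] = []
    rois: dict[str, np.ndarray] = {}
    bg_values: list[np.ndarray] = []
    for name, frame in calibration_images.items():
        regions = geometry.clean_and_label(
            geometry.threshold_height(frame, geo), geo)
        try:
            left, right = geometry.identify_empty_compartment(frame, regions, geo)
        except geometry.CompartmentStateError as exc:
            raise CalibrationError(
                f"calibration frame for {name!r}: {exc}") from exc
        occupied = right if left.is_empty else left
        roi = geometry.extract_roi(frame, occupied)

        labels = _cube_interiors(roi, cal)
        n = labels.max()
        if n == 0:
            raise CalibrationError(
                f"no closed cube boundary found for colour {name!r}")
        lab = srgb_to_cielab(roi)
        interior = labels > 0
        L, a, b = (float(lab[..., ch][interior].mean()) for ch in range(3))
        areas = np.bincount(labels.ravel())[1:]
        markers.append(ColourMarker(
            label=NAME_LABELS[name], name=name, L_mean=L, a_mean=a, b_mean=b,
            single_cube_area_px=float(areas.mean())))
        rois[name] = roi

        lab_full = srgb_to_cielab(frame.colour)
        for row, col in background_samples:
            bg_values.append(lab_full[row, col])

    if not bg_values:
        raise CalibrationError("no background sample positions given")
    bg = np.mean(bg_values, axis=0)
    markers.append(ColourMarker(label=0, name="background",
                                L_mean=float(bg[0]), a_mean=float(bg[1]),
                                b_mean=float(bg[2])))
    provisional = MarkerSet(markers)

    # second pass: reference areas from the classified label map, i.e. the
    # same measurement count_colour_regions applies to every test frame
    refined: list[ColourMarker] = []
    for m in provisional:
        if m.label not in CUBE_LABELS:
            refined.append(m)
            continue
        label_map = nn_classify(srgb_to_cielab(rois[m.name]), provisional)
        regions = ndimage.label(label_map == m.label,
                                structure=np.ones((3, 3)))[0]
        areas = np.bincount(regions.ravel())[1:]
        areas = areas[areas >= 0.5 * m.single_cube_area_px]
        area = float(areas.mean()) if areas.size else m.single_cube_area_px
        refined.append(ColourMarker(label=m.label, name=m.name,
                                    L_mean=m.L_mean, a_mean=m.a_mean,
                                    b_mean=m.b_mean, single_cube_area_px=area))
    return MarkerSet(refined)


def background_positions_from_rect(
        rect: Rect, inset_frac: float = 0.08,
        patch_half: int = 2) -> list[tuple[int, int]]:
    """Box-floor sample positions: small patches at the four mid-edge points
    of a compartment interior, inset from the walls."""
    dr = max(1, int(rect.height * inset_frac))
    dc = max(1, int(rect.width * inset_frac))
    cr, cc = (rect.top + rect.bottom) // 2, (rect.left + rect.right) // 2
    anchors = [(rect.top + dr, cc), (rect.bottom - 1 - dr, cc),
               (cr, rect.left + dc), (cr, rect.right - 1 - dc)]
    positions = []
    for r, c in anchors:
        for i in range(-patch_half, patch_half + 1):
            for j in range(-patch_half, patch_half + 1):
                positions.append((r + i, c + j))
    return positions


def nn_classify(lab_roi: np.ndarray, markers: MarkerSet) -> np.ndarray:
    """Label every pixel with its nearest marker in the (a*, b*) plane.

    The distance is Euclidean on (a*, b*) only; L* plays no part, so the
    output is invariant to any uniform lightness shift.  Exact ties go to
    the lowest label integer.  Returns a uint8 label raster with values in
    {0..4}.
    """
    lab_roi = np.asarray(lab_roi, dtype=np.float64)
    if lab_roi.ndim != 3 or lab_roi.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) Lab raster")
    da = lab_roi[..., 1][..., None] - markers.a  # (H, W, 5)
    db = lab_roi[..., 2][..., None] - markers.b
    d2 = da * da + db * db  # squared distance: monotone in the distance
    # argmin returns the first (lowest-label) index on exact ties
    return np.argmin(d2, axis=-1).astype(np.uint8)
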