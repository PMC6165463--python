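"""Synthetic RGB-D scenes of a Box and Blocks Test (BBT) setup.

The renderer stands in for a ceiling-mounted RGB-D sensor looking straight
down at a two-compartment BBT box from 80 cm.  It produces registered
colour/depth frame pairs with closed-form ground truth, which is what every
downstream stage (compartment detection, colour calibration, counting) is
tested against.

The projection is orthographic top-down with a single mm-per-pixel scale:
a perspective camera would add nothing that can be checked analytically.
The default scale maps one 290 mm compartment interior to 330x330 pixels,
the region-of-interest size the pipeline is designed around.

Illumination is modelled as a multiplicative gain: a global scalar, an
optional smooth linear gradient across the image (ambient light falling off
towards one side), and an optional per-cube gain used by the calibration
scenes, where the tone of a cube deliberately depends on the compartment
zone it sits in.  Pixel noise is additive Gaussian in sRGB, clipped to
[0, 255].
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import AlignedFrame, Rect

CUBE_COLOURS = ("red", "blue", "yellow", "green")
PALETTE_KEYS = frozenset(CUBE_COLOURS) | {"background"}

#: plausible lacquered-wood / painted-cube sRGB defaults; the physical test
#: box is beech-coloured and the cubes saturated primaries.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "red": (196, 30, 30),
    "blue": (25, 60, 160),
    "yellow": (240, 200, 40),
    "green": (36, 130, 64),
    "background": (214, 178, 130),
}

#: per-zone illumination gains for the five calibration cube positions
#: (four corners then centre) -- deliberately non-homogeneous.
CALIBRATION_ZONE_GAINS = (0.88, 1.12, 0.94, 1.06, 1.00)


class SceneError(ValueError):
    """Invalid scene configuration or cube placement."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, palette and imaging parameters of a synthetic scene.

    All lengths are millimetres.  ``image_size`` is (height, width) in
    pixels; ``px_per_mm`` is the orthographic scale.  Depth rasters give
    distance *from the sensor*, so taller objects have smaller values.
    """

    image_size: tuple[int, int] = (420, 760)
    sensor_height_mm: float = 800.0
    box_floor_depth_mm: float = 790.0
    rim_height_mm: float = 100.0
    partition_height_mm: float = 100.0
    cube_side_mm: float = 25.0
    compartment_side_mm: float = 290.0
    wall_thickness_mm: float = 15.0
    px_per_mm: float = 330.0 / 290.0
    palette: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))
    desk_rgb: tuple[int, int, int] = (120, 120, 120)
    wall_rgb: tuple[int, int, int] = (186, 152, 110)
    hand_rgb: tuple[int, int, int] = (224, 172, 140)
    illumination_gain: float = 1.0
    illumination_gradient: tuple[float, float] | None = None
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lengths = (self.sensor_height_mm, self.box_floor_depth_mm,
                   self.rim_height_mm, self.partition_height_mm,
                   self.cube_side_mm, self.compartment_side_mm,
                   self.wall_thickness_mm, self.px_per_mm)
        if any(v <= 0 for v in lengths):
            raise SceneError("all lengths must be strictly positive")
        if not (self.cube_side_mm < self.rim_height_mm < self.sensor_height_mm):
            raise SceneError("require cube_side < rim_height < sensor_height")
        if self.box_floor_depth_mm > self.sensor_height_mm:
            raise SceneError("box floor cannot be below the desk plane")
        if set(self.palette) != PALETTE_KEYS:
            raise SceneError(
                f"palette must contain exactly {sorted(PALETTE_KEYS)}")
        if self.noise_sd < 0 or self.illumination_gain <= 0:
            raise SceneError("noise_sd must be >= 0 and illumination_gain > 0")
        if not self.box_rect.inside(self.image_size):
            raise SceneError("box does not fit inside the image")

    # -- derived layout -------------------------------------------------

    @property
    def cube_side_px(self) -> int:
        return max(1, round(self.cube_side_mm * self.px_per_mm))

    @property
    def cube_area_px(self) -> float:
        """Nominal projected area of one cube face, in pixels."""
        return float(self.cube_side_px ** 2)

    @property
    def _compartment_px(self) -> int:
        return round(self.compartment_side_mm * self.px_per_mm)

    @property
    def _wall_px(self) -> int:
        return max(1, round(self.wall_thickness_mm * self.px_per_mm))

    @property
    def box_rect(self) -> Rect:
        comp, wall = self._compartment_px, self._wall_px
        h, w = comp + 2 * wall, 2 * comp + 3 * wall
        top = (self.image_size[0] - h) // 2
        left = (self.image_size[1] - w) // 2
        return Rect(top, left, h, w)

    def compartment_rect(self, side: str) -> Rect:
        """Interior (floor) rectangle of the ``left`` or ``right`` compartment."""
        comp, wall = self._compartment_px, self._wall_px
        box = self.box_rect
        if side == "left":
            return Rect(box.top + wall, box.left + wall, comp, comp)
        if side == "right":
            return Rect(box.top + wall, box.left + 2 * wall + comp, comp, comp)
        raise ValueError("side must be 'left' or 'right'")

    @property
    def partition_rect(self) -> Rect:
        comp, wall = self._compartment_px, self._wall_px
        box = self.box_rect
        return Rect(box.top + wall, box.left + wall + comp, comp, wall)

    @property
    def desk_depth_mm(self) -> float:
        return self.sensor_height_mm


@dataclass(frozen=True)
class CubePlacement:
    """One cube: colour, centre pixel, stacking layer and appearance time.

    ``layer`` 1 rests on the compartment floor; layer ``k >= 2`` requires a
    supporting cube at layer ``k - 1`` under its centre.  ``gain`` is a
    per-cube illumination factor used by the calibration scenes.
    """

    colour: str
    position: tuple[int, int]  # (row, col) of cube centre
    layer: int = 1
    appear_time_s: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.colour not in CUBE_COLOURS:
            raise SceneError(f"unknown cube colour {self.colour!r}")
        if self.layer < 1:
            raise SceneError("layer must be >= 1")
        if self.appear_time_s < 0:
            raise SceneError("appear_time_s must be >= 0")
        if self.gain <= 0:
            raise SceneError("gain must be > 0")

    def footprint(self, config: SceneConfig) -> Rect:
        side = config.cube_side_px
        r, c = self.position
        return Rect(r - side // 2, c - side // 2, side, side)


@dataclass(frozen=True)
class HandOcclusion:
    """A skin-coloured elliptical blob transiting the scene (a hand)."""

    centre: tuple[int, int]
    radii: tuple[int, int] = (60, 40)
    start_s: float = 0.0
    duration_s: float = 1.0
    height_mm: float = 60.0

    def active_at(self, t: float) -> bool:
        return self.start_s <= t < self.start_s + self.duration_s


def _validate_placements(config: SceneConfig,
                         placements: Sequence[CubePlacement]) -> None:
    interiors = [config.compartment_rect("left"), config.compartment_rect("right")]
    for p in placements:
        fp = p.footprint(config)
        if not any(r.contains_rect(fp) for r in interiors):
            raise SceneError(
                f"cube at {p.position} does not lie inside a compartment interior")
    # same-layer overlap of different colours is physically impossible
    by_layer: dict[int, list[CubePlacement]] = {}
    for p in placements:
        by_layer.setdefault(p.layer, []).append(p)
    side = config.cube_side_px
    for layer, group in by_layer.items():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if (abs(a.position[0] - b.position[0]) < side
                        and abs(a.position[1] - b.position[1]) < side
                        and a.colour != b.colour):
                    raise SceneError(
                        f"overlapping cubes of different colours at layer {layer}")
    # stacking needs support below the centre
    for p in placements:
        if p.layer == 1:
            continue
        supported = any(
            q.layer == p.layer - 1 and q.appear_time_s <= p.appear_time_s
            and q.footprint(config).contains_point(*p.position)
            for q in placements)
        if not supported:
            raise SceneError(
                f"cube at {p.position} layer {p.layer} has no supporting cube")


from functools import lru_cache


@lru_cache(maxsize=8)
def _gain_field_cached(h: int, w: int, lo: float, hi: float,
                       seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1E1D)))
    theta = rng.uniform(0, 2 * math.pi)
    rows, cols = np.mgrid[0:h, 0:w]
    proj = rows * math.sin(theta) + cols * math.cos(theta)
    proj = (proj - proj.min()) / max(np.ptp(proj), 1e-12)
    field_ = lo + (hi - lo) * proj
    field_.setflags(write=False)
    return field_


def _gain_field(config: SceneConfig) -> np.ndarray | None:
    """Smooth linear illumination field (fixed per scene seed), or None."""
    if config.illumination_gradient is None:
        return None
    lo, hi = config.illumination_gradient
    if lo <= 0 or hi <= 0:
        raise SceneError("illumination gradient bounds must be positive")
    h, w = config.image_size
    return _gain_field_cached(h, w, float(lo), float(hi), config.rng_seed)


def _static_key(config: SceneConfig) -> tuple:
    palette = tuple(sorted((k, tuple(v)) for k, v in config.palette.items()))
    return (config.image_size, config.sensor_height_mm,
            config.box_floor_depth_mm, config.rim_height_mm,
            config.partition_height_mm, config.compartment_side_mm,
            config.wall_thickness_mm, config.px_per_mm, palette,
            config.desk_rgb, config.wall_rgb)


@lru_cache(maxsize=8)
def _static_scene(key: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Cube-free box scene (colour float32, depth float32) for a config."""
    config: SceneConfig = _STATIC_CONFIGS[key]
    h, w = config.image_size
    colour = np.empty((h, w, 3), dtype=np.float32)
    colour[:] = config.desk_rgb
    depth = np.full((h, w), config.sensor_height_mm, dtype=np.float32)

    box = config.box_rect
    colour[box.slices] = config.wall_rgb
    depth[box.slices] = config.desk_depth_mm - config.rim_height_mm
    for side in ("left", "right"):
        rect = config.compartment_rect(side)
        colour[rect.slices] = config.palette["background"]
        depth[rect.slices] = config.box_floor_depth_mm
    part = config.partition_rect
    colour[part.slices] = config.wall_rgb
    depth[part.slices] = config.desk_depth_mm - config.partition_height_mm
    colour.setflags(write=False)
    depth.setflags(write=False)
    return colour, depth


_STATIC_CONFIGS: dict[tuple, SceneConfig] = {}


def render_scene(config: SceneConfig,
                 placements: Sequence[CubePlacement],
                 *,
                 occlusions: Sequence[HandOcclusion] = (),
                 timestamp_s: float = 0.0,
                 noise_seed: int | tuple | None = None) -> AlignedFrame:
    """Render one registered colour/depth frame.

    Deterministic given the configuration (and ``noise_seed``, which
    defaults to ``config.rng_seed``).  Each cube paints a square of its
    palette colour and raises the depth surface by ``layer * cube_side_mm``
    above the box floor.
    """
    _validate_placements(config, placements)
    key = _static_key(config)
    _STATIC_CONFIGS.setdefault(key, config)
    static_colour, static_depth = _static_scene(key)
    colour = static_colour.copy()
    depth = static_depth.copy()

    for p in sorted(placements, key=lambda q: q.layer):
        fp = p.footprint(config)
        colour[fp.slices] = np.multiply(config.palette[p.colour], p.gain)
        depth[fp.slices] = config.box_floor_depth_mm - p.layer * config.cube_side_mm

    for occ in occlusions:
        rr, cc = np.mgrid[0:config.image_size[0], 0:config.image_size[1]]
        a, b = occ.radii
        mask = (((rr - occ.centre[0]) / a) ** 2
                + ((cc - occ.centre[1]) / b) ** 2) <= 1.0
        colour[mask] = config.hand_rgb
        depth[mask] = config.box_floor_depth_mm - occ.height_mm

    field_ = _gain_field(config)
    gain = config.illumination_gain if field_ is None \
        else config.illumination_gain * field_[..., None]
    colour *= gain

    if config.noise_sd > 0:
        seed = config.rng_seed if noise_seed is None else noise_seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        colour += rng.standard_normal(colour.shape,
                                      dtype=np.float32) * config.noise_sd

    colour_u8 = np.clip(np.rint(colour), 0, 255).astype(np.uint8)
    depth_u16 = np.clip(np.rint(depth), 1, 65535).astype(np.uint16)
    return AlignedFrame(colour_u8, depth_u16, timestamp_s)


class FrameSequence(Sequence[AlignedFrame]):
    """Lazily rendered, timestamped frame sequence with ground truth.

    Frames are rendered on demand (random access is cheap and deterministic:
    the per-frame noise stream is seeded from ``(rng_seed, frame_index)``),
    so long sessions never hold all rasters in memory.
    """

    def __init__(self, config: SceneConfig, script: Sequence[CubePlacement],
                 fps: float, duration_s: float,
                 occlusions: Sequence[HandOcclusion] = ()) -> None:
        if fps <= 0:
            raise SceneError("fps must be > 0")
        if duration_s <= 0:
            raise SceneError("duration_s must be > 0")
        for p in script:
            if not (0 <= p.appear_time_s <= duration_s):
                raise SceneError("appear_time_s must lie within [0, duration_s]")
        _validate_placements(config, script)
        self.config = config
        self.script = list(script)
        self.fps = float(fps)
        self.duration_s = float(duration_s)
        self.occlusions = list(occlusions)
        self._n = int(round(fps * duration_s))

    def __len__(self) -> int:
        return self._n

    def timestamp(self, index: int) -> float:
        return index / self.fps

    def visible_at(self, index: int) -> list[CubePlacement]:
        t = self.timestamp(index)
        return [p for p in self.script if p.appear_time_s <= t]

    def truth_counts(self, index: int) -> dict[str, int]:
        """True per-colour cube count in frame ``index``."""
        counts = {c: 0 for c in CUBE_COLOURS}
        for p in self.visible_at(index):
            counts[p.colour] += 1
        return counts

    def __getitem__(self, index: int) -> AlignedFrame:
        if isinstance(index, slice):
            return [self[i] for i in range(*index.indices(self._n))]
        if index < 0:
            index += self._n
        if not 0 <= index < self._n:
            raise IndexError(index)
        t = self.timestamp(index)
        occ = [o for o in self.occlusions if o.active_at(t)]
        return render_scene(self.config, self.visible_at(index),
                            occlusions=occ, timestamp_s=t,
                            noise_seed=(self.config.rng_seed, index))


def render_session(config: SceneConfig, script: Sequence[CubePlacement],
                   fps: float = 4.0, duration_s: float = 60.0,
                   occlusions: Sequence[HandOcclusion] = ()) -> FrameSequence:
    """Timed frame sequence: frame at time ``t`` contains exactly the cubes
    with ``appear_time_s <= t``; timestamps evenly spaced at ``1/fps``."""
    return FrameSequence(config, script, fps, duration_s, occlusions)


def calibration_positions(config: SceneConfig, side: str = "left") -> list[tuple[int, int]]:
    """Four corners and centre of a compartment interior, with a margin."""
    rect = config.compartment_rect(side)
    m = config.cube_side_px  # one cube side in from the walls
    top, bot = rect.top + m, rect.bottom - 1 - m
    lft, rgt = rect.left + m, rect.right - 1 - m
    cr, cc = (rect.top + rect.bottom) // 2, (rect.left + rect.right) // 2
    return [(top, lft), (top, rgt), (bot, lft), (bot, rgt), (cr, cc)]


def make_calibration_images(config: SceneConfig,
                            side: str = "left") -> dict[str, AlignedFrame]:
    """One frame per cube colour: five cubes of that colour at the corners
    and centre of one compartment, each zone under a different illumination
    gain so the tone is not homogeneous across the compartment."""
    images = {}
    for i, colour in enumerate(CUBE_COLOURS):
        placements = [
            CubePlacement(colour, pos, gain=g)
            for pos, g in zip(calibration_positions(config, side),
                              CALIBRATION_ZONE_GAINS)
        ]
        images[colour] = render_scene(config, placements,
                                      noise_seed=(config.rng_seed, 0xCA1, i))
    return images


def random_session_script(config: SceneConfig, n_cubes: int,
                          rng: np.random.Generator, *,
                          side: str = "right",
                          start_s: float = 1.0,
                          min_spacing_s: float = 1.2,
                          jitter_s: float = 0.3,
                          duration_s: float = 60.0) -> list[CubePlacement]:
    """Scripted stage: ``n_cubes`` non-touching, non-stacked cubes appearing
    one at a time at >= ``min_spacing_s`` intervals in one compartment.

    Positions come from a jittered grid so cubes never touch; colours are
    drawn uniformly from the four cube colours.
    """
    rect = config.compartment_rect(side)
    side_px = config.cube_side_px
    pitch = side_px + 14  # >= 14 px clearance between neighbouring cubes
    margin = 4
    n_rows = (rect.height - 2 * margin) // pitch
    n_cols = (rect.width - 2 * margin) // pitch
    if n_cubes > n_rows * n_cols:
        raise SceneError(f"cannot place {n_cubes} non-touching cubes")
    cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
    rng.shuffle(cells)
    jitter_px = max(0, (pitch - side_px) // 2 - 2)

    t = start_s
    placements = []
    for k in range(n_cubes):
        i, j = cells[k]
        r = rect.top + margin + i * pitch + pitch // 2
        c = rect.left + margin + j * pitch + pitch // 2
        if jitter_px:
            r += int(rng.integers(-jitter_px, jitter_px + 1))
            c += int(rng.integers(-jitter_px, jitter_px + 1))
        colour = CUBE_COLOURS[int(rng.integers(len(CUBE_COLOURS)))]
        placements.append(CubePlacement(colour, (r, c), appear_time_s=round(t, 3)))
        t += min_spacing_s + float(rng.uniform(0, jitter_s))
    if placements and placements[-1].appear_time_s > duration_s:
        raise SceneError("script does not fit in the stage duration")
    return placements


# -- disk round-trip ----------------------------------------------------

def write_session(frames: FrameSequence, out_dir: str | Path) -> Path:
    """Write a session to disk: 8-bit RGB + 16-bit depth PNG pairs, a CSV
    manifest (frame_index, timestamp_s, paths) and the ground-truth script."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(frames)):
        frame = frames[i]
        cpath = f"frames/colour_{i:04d}.png"
        dpath = f"frames/depth_{i:04d}.png"
        iio.imwrite(out / cpath, frame.colour)
        iio.imwrite(out / dpath, frame.depth)
        rows.append({"frame_index": i, "timestamp_s": frame.timestamp_s,
                     "colour_path": cpath, "depth_path": dpath})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    truth = pd.DataFrame(
        [{"colour": p.colour, "row": p.position[0], "col": p.position[1],
          "layer": p.layer, "appear_time_s": p.appear_time_s}
         for p in frames.script])
    truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def read_session(session_dir: str | Path):
    """Yield :class:`AlignedFrame` objects from a written session."""
    import imageio.v3 as iio

    root = Path(session_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    for row in manifest.itertuples():
        colour = np.asarray(iio.imread(root / row.colour_path))
        depth = np.asarray(iio.imread(root / row.depth_path)).astype(np.uint16)
        yield AlignedFrame(colour, depth, float(row.timestamp_s))


def session_config(seed: int, *, noise_sd: float = 4.0,
                   illumination_gradient: tuple[float, float] | None = (0.85, 1.15),
                   **overrides) -> SceneConfig:
    """Convenience constructor for the standard synthetic study conditions:
    moderate sRGB noise (sd 4) and a per-zone illumination gradient spanning
    0.85-1.15, seeded."""
    return SceneConfig(noise_sd=noise_sd,
                       illumination_gradient=illumination_gradient,
                       rng_seed=int(seed), **overrides)
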