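"""Per-frame cube counting and the monotone global counter.

Each frame's label map is reduced to per-colour cube counts: connected
regions of a cube colour are measured, tiny regions (below half a reference
cube face) are dropped as noise, and every surviving region contributes
``round(area / single_cube_area)`` cubes (at least one), so touching groups
are resolved by area.  Frame counts then feed a running per-colour maximum:
the global counter only ever increments, which makes it robust to frames
where a hand transiently occludes already-counted cubes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .colourlab import CUBE_LABELS, LABEL_NAMES, MarkerSet

#: a detected region smaller than this fraction of a single cube face is noise
NOISE_AREA_FRACTION = 0.5


@dataclass(frozen=True)
class DetectionEvent:
    """One newly counted cube: colour label (1-4), stage time, frame index."""

    colour: int
    timestamp_s: float
    frame_index: int

    def __post_init__(self) -> None:
        if self.colour not in CUBE_LABELS:
            raise ValueError("colour must be a cube label 1-4")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be >= 0")

    @property
    def colour_name(self) -> str:
        return LABEL_NAMES[self.colour]


def count_colour_regions(label_map: np.ndarray,
                         markers: MarkerSet) -> dict[int, int]:
    """Per-colour cube count of one label map.

    Segregated cubes appear as single regions; grouped cubes are counted by
    dividing the group area by that colour's average single-cube area
    (round half up, minimum one per surviving region).
    """
    counts: dict[int, int] = {}
    for label in CUBE_LABELS:
        single = markers.single_cube_area(label)
        regions = measure.label(label_map == label, connectivity=2)
        areas = np.bincount(regions.ravel())[1:]
        n = 0
        for area in areas:
            if area < NOISE_AREA_FRACTION * single:
                continue
            n += max(1, math.floor(area / single + 0.5))
        counts[label] = n
    return counts


@dataclass
class CounterState:
    """Running per-colour maxima, the detection events they generated, and
    the derived global count."""

    per_colour_max: dict[int, int] = field(
        default_factory=lambda: {label: 0 for label in CUBE_LABELS})
    events: list[DetectionEvent] = field(default_factory=list)

    @property
    def global_count(self) -> int:
        return len(self.events)

    def counts_by_colour(self) -> dict[int, int]:
        return dict(self.per_colour_max)


def update_counter(state: CounterState, frame_counts: dict[int, int],
                   timestamp_s: float, frame_index: int) -> CounterState:
    """Fold one frame's counts into the monotone counter.

    A colour whose frame count exceeds its running maximum emits one
    :class:`DetectionEvent` per newly seen cube, stamped with this frame's
    time; counts at or below the maximum (e.g. during hand occlusion)
    change nothing.  The state is updated in place and returned.
    """
    for label in CUBE_LABELS:
        seen = frame_counts.get(label, 0)
        prev = state.per_colour_max[label]
        if seen > prev:
            state.events.extend(
                DetectionEvent(label, timestamp_s, frame_index)
                for _ in range(seen - prev))
            state.per_colour_max[label] = seen
    return state


def write_event_log(state: CounterState, path: str | Path) -> None:
    """Event log CSV: frame_index, timestamp_s, colour_name, cumulative_count."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "timestamp_s", "colour_name",
                         "cumulative_count"])
        for i, ev in enumerate(state.events, start=1):
            writer.writerow([ev.frame_index, ev.timestamp_s, ev.colour_name, i])
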