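"""Score validation and stage outcomes.

Two detections less than a second apart almost always mean the subject
moved more than one cube in a single grasp; test rules score that as one
cube.  ``validate_events`` therefore collapses any event arriving within
the validation window after the last *kept* event.  The validated stream
defines the stage score NC, the average displacement velocity Vavg (the
slope of the least-squares line through the origin relating cumulative
count to detection time), and the partial times PT between consecutive
detections (mean and population standard deviation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .counter import CounterState, DetectionEvent
from .colourlab import CUBE_LABELS

STAGES = ("training", "dominant", "non_dominant")

#: collapse window for multi-cube grasps, seconds
VALIDATION_WINDOW_S = 1.0


def validate_events(events: Sequence[DetectionEvent],
                    window_s: float = VALIDATION_WINDOW_S) -> list[DetectionEvent]:
    """Drop events closer than ``window_s`` to the last kept event.

    Scanning in time order: the first event is kept; every subsequent event
    whose timestamp is less than ``window_s`` after the last kept one is
    discarded (the extra cubes of a multi-cube grasp count as one).
    """
    kept: list[DetectionEvent] = []
    last = -np.inf
    for ev in sorted(events, key=lambda e: e.timestamp_s):
        if ev.timestamp_s - last < window_s:
            continue
        kept.append(ev)
        last = ev.timestamp_s
    return kept


@dataclass(frozen=True)
class OutcomeFit:
    """Least-squares line through the origin: slope B = sum(xy) / sum(x^2)."""

    slope_B: float
    residuals: np.ndarray
    intercept_beta0: float = 0.0


def fit_through_origin(times: Sequence[float],
                       cumulative_counts: Sequence[float]) -> OutcomeFit:
    """Through-origin simple linear regression of count on time.

    x is the detection time, y the cumulative cube count; the slope is the
    average displacement velocity in cubes per second.
    """
    x = np.asarray(times, dtype=np.float64)
    y = np.asarray(cumulative_counts, dtype=np.float64)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("times and counts must be equally long and non-empty")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("slope undefined: all time instants are zero")
    slope = float(np.dot(x, y)) / sxx
    return OutcomeFit(slope_B=slope, residuals=y - slope * x)


def partial_times(events: Sequence[DetectionEvent]
                  ) -> tuple[list[float], float | None, float | None]:
    """Intervals between consecutive validated detections.

    Returns ``(PT list, mean, population standard deviation)``; with fewer
    than two events the list is empty and the statistics are None.
    """
    ts = sorted(ev.timestamp_s for ev in events)
    if len(ts) < 2:
        return [], None, None
    pt = list(np.diff(ts))
    return pt, float(np.mean(pt)), float(np.std(pt))


@dataclass(frozen=True)
class StageResult:
    """Validated outcome of one test stage."""

    stage: str
    NC: int
    Vavg: float
    PT_mean: float | None
    PT_sd: float | None
    events: list[DetectionEvent] = field(default_factory=list)
    per_colour_counts: dict[int, int] = field(default_factory=dict)
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.NC != len(self.events):
            raise ValueError("NC must equal the number of validated events")
        if self.Vavg < 0:
            raise ValueError("Vavg must be >= 0")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage, "NC": self.NC, "Vavg": self.Vavg,
            "PT_mean": self.PT_mean, "PT_sd": self.PT_sd,
            "duration_s": self.duration_s,
            "per_colour_counts": {str(k): v
                                  for k, v in self.per_colour_counts.items()},
            "events": [{"colour": ev.colour, "timestamp_s": ev.timestamp_s,
                        "frame_index": ev.frame_index} for ev in self.events],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "StageResult":
        return cls(
            stage=payload["stage"], NC=payload["NC"], Vavg=payload["Vavg"],
            PT_mean=payload["PT_mean"], PT_sd=payload["PT_sd"],
            duration_s=payload.get("duration_s", 60.0),
            per_colour_counts={int(k): v
                               for k, v in payload["per_colour_counts"].items()},
            events=[DetectionEvent(**ev) for ev in payload["events"]])

    @classmethod
    def from_json(cls, source: str | Path) -> "StageResult":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        return cls.from_dict(json.loads(text))


def results_to_csv(results: Sequence[StageResult], path: str | Path,
                   participant: str = "anonymous", session: int = 1) -> None:
    """One CSV row per stage: participant, session, stage, NC, Vavg, PT."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant", "session", "stage", "NC", "Vavg",
                         "PT_mean", "PT_sd"])
        for r in results:
            writer.writerow([participant, session, r.stage, r.NC,
                             f"{r.Vavg:.6g}",
                             "" if r.PT_mean is None else f"{r.PT_mean:.6g}",
                             "" if r.PT_sd is None else f"{r.PT_sd:.6g}"])


def stage_report(state: CounterState, stage: str,
                 duration_s: float,
                 window_s: float = VALIDATION_WINDOW_S) -> StageResult:
    """Validate a stage's event stream and assemble its outcome set.

    NC is the validated event count; Vavg the through-origin slope fitted to
    the (detection time, cumulative count) pairs (0 by convention for an
    empty stage); PT statistics are None with fewer than two events.
    """
    validated = validate_events(state.events, window_s)
    per_colour = {label: 0 for label in CUBE_LABELS}
    for ev in validated:
        per_colour[ev.colour] += 1
    times = [ev.timestamp_s for ev in validated]
    if validated and any(t > 0 for t in times):
        counts = list(range(1, len(validated) + 1))
        vavg = fit_through_origin(times, counts).slope_B
    else:
        vavg = 0.0  # empty stage (or detections only at t=0): no velocity
    _, pt_mean, pt_sd = partial_times(validated)
    return StageResult(stage=stage, NC=len(validated), Vavg=vavg,
                       PT_mean=pt_mean, PT_sd=pt_sd, events=validated,
                       per_colour_counts=per_colour, duration_s=duration_s)
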