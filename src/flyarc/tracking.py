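"""Activity, motion-event, and sleep scoring from 1 Hz positional data.

Positions come either from a CSV of per-second centroids or from image
stacks via reference-subtraction blob detection (:func:`detect_fly`).
Displacements below half a fly body length (FBL) are treated as
immobility; sleep is any immobility period strictly exceeding 5 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import NoObject, ParameterError

__all__ = [
    "PositionTrace",
    "MotionEvent",
    "ActivitySeries",
    "SleepBout",
    "FlyDetection",
    "detect_fly",
    "estimate_fbl",
    "displacement_series",
    "score_sleep",
    "score_sleep_grooming",
    "sleep_seconds",
    "per_minute_sleep_fraction",
]

DEFAULT_MIN_SLEEP_S = 300
DEFAULT_FBL_FRACTION = 0.5


@dataclass
class PositionTrace:
    """Per-second fly centroid positions at uniform 1 Hz sampling."""

    fly_id: int
    x: np.ndarray
    y: np.ndarray
    tracked: np.ndarray          # bool per second
    fbl_px: float

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.tracked)):
            raise ParameterError("x, y, tracked must have equal length")
        if self.fbl_px <= 0:
            raise ParameterError("fbl_px must be > 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MotionEvent:
    start_s: int
    end_s: int                   # inclusive last second of movement
    distance_px: float
    duration_s: int
    speed_px_per_s: float


@dataclass
class ActivitySeries:
    """Filtered per-second displacement plus derived motion events.

    ``displacement_px[t]`` is the (FBL-filtered) Euclidean distance moved
    between seconds t-1 and t; index 0 is defined as 0.  Motion events
    are maximal runs of nonzero filtered displacement; event speed is
    total distance over uninterrupted duration.
    """

    fly_id: int
    displacement_px: np.ndarray
    motion_events: list[MotionEvent] = field(default_factory=list)
    fbl_px: float = 16.0

    def __len__(self) -> int:
        return len(self.displacement_px)


@dataclass(frozen=True)
class SleepBout:
    start_s: int
    end_s: int                   # exclusive
    duration_s: int


@dataclass(frozen=True)
class FlyDetection:
    centroid_xy: tuple[float, float]
    area_px2: float
    outline: np.ndarray          # (k, 2) polygon vertices as (row, col)
    length_px: float             # major axis of the detected blob


def detect_fly(frame: np.ndarray, reference: np.ndarray,
               object_threshold: float) -> FlyDetection:
    """Detect the fly in a frame by reference subtraction and edge following.

    After subtracting the reference frame, the brightest residual pixel
    seeds the detection; if it falls below ``object_threshold`` the
    second is untracked (:class:`NoObject`).  The connected thresholded
    region around the seed is outlined as a closed polygon whose centroid
    and area summarize the object.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape or frame.ndim != 2:
        raise ParameterError("frame and reference must be equal-shape 2-D images")
    diff = frame - reference
    seed = np.unravel_index(np.argmax(diff), diff.shape)
    if diff[seed] < object_threshold:
        raise NoObject("no pixel above object threshold")
    mask = diff >= object_threshold
    labels = measure.label(mask, connectivity=2)
    blob = labels == labels[seed]
    props = measure.regionprops(blob.astype(np.uint8))[0]
    contours = measure.find_contours(blob.astype(float), 0.5)
    outline = max(contours, key=len) if contours else np.empty((0, 2))
    r, c = props.centroid
    return FlyDetection(
        centroid_xy=(c, r),
        area_px2=float(props.area),
        outline=outline,
        length_px=float(props.axis_major_length),
    )


def estimate_fbl(detections: list[FlyDetection]) -> float:
    """FBL estimate: median major-axis length of the detected object."""
    if not detections:
        raise ParameterError("no detections to estimate FBL from")
    return float(np.median([d.length_px for d in detections]))


def displacement_series(trace: PositionTrace,
                        fbl_fraction: float = DEFAULT_FBL_FRACTION) -> ActivitySeries:
    """Per-second filtered displacement and motion events from a trace.

    Untracked seconds are reset to the last known location (zero
    displacement); displacements below ``fbl_fraction * FBL`` are set to
    zero (sub-FBL wobble is not locomotion).  The filter is idempotent:
    re-filtering the output changes nothing.
    """
    n = len(trace)
    x = np.array(trace.x, dtype=float)
    y = np.array(trace.y, dtype=float)
    tracked = np.asarray(trace.tracked, dtype=bool)
    if not tracked.any():
        warnings.warn(f"fly {trace.fly_id}: no tracked seconds; all-zero series")
        return ActivitySeries(trace.fly_id, np.zeros(n), [], trace.fbl_px)

    first = int(np.flatnonzero(tracked)[0])
    x[:first], y[:first] = x[first], y[first]
    # carry forward last known position through dropouts
    idx = np.where(tracked, np.arange(n), -1)
    np.maximum.accumulate(idx, out=idx)
    idx[idx < 0] = first
    x, y = x[idx], y[idx]

    disp = np.zeros(n)
    disp[1:] = np.hypot(np.diff(x), np.diff(y))
    disp[disp < fbl_fraction * trace.fbl_px] = 0.0

    events = []
    for s, e in _runs(disp > 0):
        dist = float(disp[s:e].sum())
        dur = e - s
        events.append(MotionEvent(s, e - 1, dist, dur, dist / dur))
    return ActivitySeries(trace.fly_id, disp, events, trace.fbl_px)


def _runs(mask: np.ndarray):
    """Yield (start, end) half-open index ranges of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    yield from zip(starts, ends)


def score_sleep(series: ActivitySeries,
                min_duration_s: int = DEFAULT_MIN_SLEEP_S) -> list[SleepBout]:
    """Sleep bouts: maximal immobility runs strictly exceeding 5 min.

    A run of exactly ``min_duration_s`` seconds is not sleep; runs
    truncated by the recording boundary still count if their observed
    duration exceeds the criterion.
    """
    bouts = []
    for s, e in _runs(series.displacement_px == 0.0):
        if e - s > min_duration_s:
            bouts.append(SleepBout(s, e, e - s))
    return bouts


def score_sleep_grooming(series: ActivitySeries, grooming: np.ndarray,
                         min_duration_s: int = DEFAULT_MIN_SLEEP_S) -> list[SleepBout]:
    """Grooming-aware sleep: immobility AND no grooming, > 5 min.

    ``grooming`` is a per-second binary annotation (1 = grooming) aligned
    to the series; grooming seconds interrupt candidate sleep even when
    the centroid is immobile.
    """
    g = np.asarray(grooming)
    if len(g) != len(series):
        raise ParameterError(
            f"grooming length {len(g)} != series length {len(series)}"
        )
    quiet = (series.displacement_px == 0.0) & (g == 0)
    return [SleepBout(s, e, e - s) for s, e in _runs(quiet) if e - s > min_duration_s]


def sleep_seconds(bouts: list[SleepBout], n_seconds: int) -> np.ndarray:
    """Binary per-second sleep state from a bout list."""
    out = np.zeros(n_seconds, dtype=np.uint8)
    for b in bouts:
        out[b.start_s:b.end_s] = 1
    return out


def per_minute_sleep_fraction(sleep_state_s: np.ndarray) -> np.ndarray:
    """Fraction of each whole minute spent asleep."""
    s = np.asarray(sleep_state_s, dtype=float)
    n_min = len(s) // 60
    return s[: n_min * 60].reshape(n_min, 60).mean(axis=1)
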