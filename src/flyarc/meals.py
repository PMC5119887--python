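"""Meal detection from delta-pixel series, with noise and drift correction.

Noise is estimated by iterative filtration: values more than 4.0 s.d.
above the running mean of the retained set are discarded until none
remain (feeding spikes are the distal tail; what is left is measurement
noise plus evaporation drift).  Frames whose delta exceeds the noise
mean by 3.5 s.d. are feeding frames; consecutive feeding frames merge
into one meal time-stamped at the latter bout frame, so bouts followed
by at least one minute of non-feeding are meals.  Each meal is then
corrected for evaporation/luminance drift and converted to a volume and
per-nutrient masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .meniscus import MeniscusTrace

__all__ = [
    "NoiseModel",
    "MealEvent",
    "Diet",
    "estimate_noise",
    "call_meals",
    "meal_frame_mask",
    "correct_meals",
    "to_volume_and_nutrients",
]


@dataclass(frozen=True)
class NoiseModel:
    """Moments of the iteratively filtered delta-pixel noise set."""

    mean_px: float
    sd_px: float
    n_retained: int
    n_iterations: int


@dataclass(frozen=True)
class MealEvent:
    """One evaporation-corrected ingestion event.

    ``time_min`` is the minute of the latter frame of the feeding bout;
    ``raw_px`` the summed delta over the bout; ``corrected_px`` the
    drift-corrected displacement; ``volume_ul = corrected_px *
    volume_per_px``; nutrient masses are volume times diet concentration
    in ug/ul.
    """

    fly_id: int
    time_min: int
    frame_start: int
    frame_end: int               # inclusive
    raw_px: float
    corrected_px: float | None = None
    volume_ul: float | None = None
    nutrients_ug: dict[str, float] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frame_end - self.frame_start + 1

    @property
    def time_s(self) -> int:
        return self.time_min * 60


@dataclass(frozen=True)
class Diet:
    """Diet composition as % w/v per component (1% w/v = 10 ug/ul)."""

    components: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 or not np.isfinite(v) for v in self.components.values()):
            raise ParameterError("diet concentrations must be finite and >= 0")

    def ug_per_ul(self, component: str) -> float:
        return 10.0 * self.components[component]


def estimate_noise(delta: np.ndarray, flagged: np.ndarray | None = None,
                   sd_multiplier: float = 4.0, min_retained: int = 10,
                   max_iterations: int = 100) -> NoiseModel:
    """Iterative filtration of distal delta values.

    Repeatedly removes values more than ``sd_multiplier`` sample s.d.
    above the retained-set mean until no value qualifies, fewer than
    ``min_retained`` values remain, or ``max_iterations`` passes —
    removal-only, so termination is guaranteed.  A constant series
    returns (value, 0) after a single pass.
    """
    delta = np.asarray(delta, dtype=float)
    if flagged is not None:
        delta = delta[~np.asarray(flagged, dtype=bool)]
    delta = delta[np.isfinite(delta)]
    if len(delta) < min_retained:
        raise ParameterError(
            f"need >= {min_retained} finite delta values, got {len(delta)}"
        )

    retained = delta
    iterations = 0
    while iterations < max_iterations:
        iterations += 1
        mean = float(retained.mean())
        sd = float(retained.std(ddof=1)) if len(retained) > 1 else 0.0
        keep = retained <= mean + sd_multiplier * sd
        if keep.all() or keep.sum() < min_retained:
            break
        retained = retained[keep]
    return NoiseModel(mean_px=mean, sd_px=sd, n_retained=len(retained),
                      n_iterations=iterations)


def call_meals(trace: MeniscusTrace, noise: NoiseModel,
               threshold_multiplier: float = 3.5) -> list[MealEvent]:
    """Select meals: delta frames above noise mean + 3.5 s.d., merged.

    Maximal runs of consecutive supra-threshold frames form one meal
    with ``raw_px`` the summed delta and the time stamp of the latter
    bout frame.  Flagged (dropout) frames are never feeding frames.  An
    empty result is valid.
    """
    threshold = noise.mean_px + threshold_multiplier * noise.sd_px
    is_meal = (trace.delta_px > threshold) & ~trace.flagged
    events = []
    idx = np.flatnonzero(is_meal)
    if len(idx) == 0:
        return events
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(idx[starts], idx[ends]):
        events.append(MealEvent(
            fly_id=trace.capillary_id,
            time_min=int(trace.minutes[e]),
            frame_start=int(s),
            frame_end=int(e),
            raw_px=float(trace.delta_px[s:e + 1].sum()),
        ))
    return events


def meal_frame_mask(meals: list[MealEvent], n_frames: int) -> np.ndarray:
    """Boolean mask of frames belonging to any feeding bout."""
    mask = np.zeros(n_frames, dtype=bool)
    for m in meals:
        mask[m.frame_start:m.frame_end + 1] = True
    return mask


def correct_meals(meals: list[MealEvent], delta: np.ndarray,
                  flagged: np.ndarray | None = None,
                  mode: str = "per_frame") -> list[MealEvent]:
    """Subtract the average non-feeding delta (drift) from each meal.

    ``per_frame`` (default) subtracts the per-frame mean of all
    non-feeding, non-flagged deltas times the bout length, so the
    correction scales with bout duration and constant evaporation drift
    cancels without bias; ``per_event`` subtracts that mean once per
    meal.  Corrected displacement is floored at 0.
    """
    if mode not in ("per_frame", "per_event"):
        raise ParameterError("mode must be 'per_frame' or 'per_event'")
    delta = np.asarray(delta, dtype=float)
    keep = ~meal_frame_mask(meals, len(delta))
    if flagged is not None:
        keep &= ~np.asarray(flagged, dtype=bool)
    keep[0] = False  # delta[0] is defined as 0, not an observation
    drift = float(delta[keep].mean()) if keep.any() else 0.0
    out = []
    for m in meals:
        n = m.n_frames if mode == "per_frame" else 1
        out.append(replace(m, corrected_px=max(0.0, m.raw_px - drift * n)))
    return out


def to_volume_and_nutrients(meals: list[MealEvent], volume_per_px: float,
                            diet: Diet) -> list[MealEvent]:
    """Convert corrected displacements to volumes and nutrient masses."""
    if volume_per_px <= 0:
        raise ParameterError("volume_per_px must be > 0")
    out = []
    for m in meals:
        px = m.corrected_px if m.corrected_px is not None else m.raw_px
        volume = px * volume_per_px
        nutrients = {c: volume * diet.ug_per_ul(c) for c in diet.components}
        out.append(replace(m, volume_ul=volume, nutrients_ug=nutrients))
    return out
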