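"""Arousal-threshold scoring from vibrational stimulus trains.

Once per hour a train of vibrations of increasing intensity (0.8-3.2 g
in 0.6 g steps; each stimulus 200 ms pulses with 800 ms gaps, 15 s
between intensities) probes inactive flies.  The arousal threshold is
the first intensity whose 15 s post-window contains movement, provided
the fly was inactive at stimulus onset with at least the required prior
inactivity.  Binning thresholds by prior inactivity traces sleep depth;
comparing pre- vs post-meal windows (with inactivity controlled) tests
whether feeding deepens the transition into sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .tracking import ActivitySeries

__all__ = [
    "StimulusSchedule",
    "ArousalEvent",
    "build_schedule",
    "assign_arousal",
    "events_frame",
    "threshold_by_inactivity",
    "prepost_meal_threshold",
]

INTER_STIM_TRAIN_S = 15
PULSE_ON_MS = 200
PULSE_OFF_MS = 800


@dataclass(frozen=True)
class StimulusSchedule:
    """Hourly trains of strictly increasing vibration intensities (g)."""

    train_times_s: np.ndarray
    intensities_g: tuple[float, ...]
    inter_stim_s: int = INTER_STIM_TRAIN_S

    def __post_init__(self) -> None:
        ints = np.asarray(self.intensities_g)
        if len(ints) == 0 or np.any(np.diff(ints) <= 0):
            raise ParameterError("intensities must be strictly increasing")

    def stimulus_times(self, train_time_s: int) -> np.ndarray:
        return train_time_s + np.arange(len(self.intensities_g)) * self.inter_stim_s


@dataclass(frozen=True)
class ArousalEvent:
    fly_id: int
    train_time_s: int
    prior_inactivity_s: int
    responded: bool
    response_intensity_g: float | None = None


def build_schedule(start_s: int, end_s: int, intensity_min_g: float = 0.8,
                   intensity_max_g: float = 3.2, step_g: float = 0.6,
                   period_s: int = 3600) -> StimulusSchedule:
    """Hourly schedule; defaults give the 5-step 0.8..3.2 g train."""
    if step_g <= 0:
        raise ParameterError("step_g must be > 0")
    if intensity_max_g < intensity_min_g:
        raise ParameterError("intensity_max_g must be >= intensity_min_g")
    n_steps = int(np.floor((intensity_max_g - intensity_min_g) / step_g + 1e-9)) + 1
    intensities = tuple(round(intensity_min_g + i * step_g, 10)
                        for i in range(n_steps))
    trains = np.arange(start_s, end_s, period_s, dtype=int)
    return StimulusSchedule(train_times_s=trains, intensities_g=intensities)


def assign_arousal(series: ActivitySeries, schedule: StimulusSchedule,
                   min_inactivity_s: int = 1, fly_id: int | None = None,
                   ) -> list[ArousalEvent]:
    """Score each train against the three arousal criteria.

    For a fly (1) inactive at train onset with (2) prior inactivity of
    at least ``min_inactivity_s``, the intensities are walked in order;
    the first whose 15 s post-window contains a nonzero filtered
    displacement is the response intensity, and the walk stops there —
    once aroused, later intensities are uninformative.  Flies active at
    train onset produce no event; non-responding trains are recorded
    with ``responded=False``.
    """
    disp = series.displacement_px
    n = len(disp)
    fid = series.fly_id if fly_id is None else fly_id
    events = []
    for t0 in schedule.train_times_s:
        t0 = int(t0)
        if t0 >= n or disp[t0] != 0.0:
            continue
        run_start = t0
        while run_start > 0 and disp[run_start - 1] == 0.0:
            run_start -= 1
        prior = t0 - run_start
        if prior < min_inactivity_s:
            continue
        response = None
        for j, g in enumerate(schedule.intensities_g):
            ts = t0 + j * schedule.inter_stim_s
            if ts >= n:
                break
            if j > 0 and disp[ts] != 0.0:
                break  # already moving at this stimulus: train over
            window = disp[ts + 1: min(n, ts + schedule.inter_stim_s + 1)]
            if np.any(window > 0):
                response = float(g)
                break
        events.append(ArousalEvent(fly_id=fid, train_time_s=t0,
                                   prior_inactivity_s=int(prior),
                                   responded=response is not None,
                                   response_intensity_g=response))
    return events


def events_frame(events: list[ArousalEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"fly_id": e.fly_id, "train_time_s": e.train_time_s,
         "prior_inactivity_s": e.prior_inactivity_s,
         "responded": e.responded,
         "response_intensity_g": e.response_intensity_g}
        for e in events
    ])


def threshold_by_inactivity(events: list[ArousalEvent], bin_width_s: int = 300,
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean response intensity per prior-inactivity bin + quadratic trend.

    Only responded events enter; empty bins are omitted.  Returns the
    per-bin table and the coefficients (highest power first) of the
    second-order polynomial least-squares trend over bin centers.
    """
    resp = [e for e in events if e.responded]
    if not resp:
        raise ParameterError("no responded events")
    inact = np.array([e.prior_inactivity_s for e in resp])
    g = np.array([e.response_intensity_g for e in resp])
    idx = inact // bin_width_s
    rows = []
    for i in np.unique(idx):
        sel = idx == i
        rows.append({
            "inactivity_low_s": int(i * bin_width_s),
            "inactivity_high_s": int((i + 1) * bin_width_s),
            "n": int(sel.sum()),
            "mean_threshold_g": float(g[sel].mean()),
            "sem_threshold_g": float(g[sel].std(ddof=1) / np.sqrt(sel.sum()))
            if sel.sum() > 1 else np.nan,
        })
    table = pd.DataFrame(rows)
    centers = 0.5 * (table["inactivity_low_s"] + table["inactivity_high_s"])
    deg = min(2, len(table) - 1)
    coeffs = np.polyfit(centers, table["mean_threshold_g"], deg)
    return table, coeffs


def prepost_meal_threshold(events: list[ArousalEvent], meal_times: dict[int, np.ndarray],
                           window_edges_min: tuple[int, ...] = (0, 20, 40, 60),
                           inactivity_range_s: tuple[int, int] = (1, 300),
                           psleep_by_window: dict[tuple[str, int], float] | None = None,
                           ) -> pd.DataFrame:
    """Pre/post-meal arousal-threshold comparison in relative-time windows.

    Each responded event (prior inactivity within ``inactivity_range_s``,
    controlling for sleep depth) is assigned to its nearest meal and the
    relative window it falls in (default 0-20/20-40/40-60 min pre and
    post).  Per window: n, mean and s.e.m. threshold; each pre/post pair
    gets a two-sided Mann-Whitney p-value.  If ``psleep_by_window`` maps
    ("pre"|"post", window start) to that window's P_sleep, the Pearson
    correlation between window P_sleep and mean threshold across the six
    windows is attached as attrs ``psleep_threshold_r``/``_p``.
    """
    lo, hi = inactivity_range_s
    edges = np.asarray(window_edges_min) * 60
    assigned: dict[tuple[str, int], list[float]] = {}
    for e in events:
        if not e.responded or not (lo <= e.prior_inactivity_s <= hi):
            continue
        times = np.asarray(meal_times.get(e.fly_id, []), dtype=int)
        if len(times) == 0:
            continue
        rel = e.train_time_s - times[np.argmin(np.abs(times - e.train_time_s))]
        side = "post" if rel > 0 else "pre"
        a = abs(rel)
        for w0, w1 in zip(edges[:-1], edges[1:]):
            if w0 < a <= w1 or (a == 0 and w0 == 0):
                key = (side, int(w0 // 60))
                assigned.setdefault(key, []).append(e.response_intensity_g)
                break
    rows = []
    for w0, w1 in zip(window_edges_min[:-1], window_edges_min[1:]):
        pre = assigned.get(("pre", w0), [])
        post = assigned.get(("post", w0), [])
        if pre and post and (np.ptp(pre) > 0 or np.ptp(post) > 0):
            _, p = stats.mannwhitneyu(post, pre, alternative="two-sided")
        else:
            p = np.nan
        for side, vals in (("pre", pre), ("post", post)):
            rows.append({
                "side": side, "window_start_min": w0, "window_end_min": w1,
                "n": len(vals),
                "mean_threshold_g": float(np.mean(vals)) if vals else np.nan,
                "sem_threshold_g": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else np.nan,
                "mannwhitney_p": float(p) if p == p else np.nan,
            })
    table = pd.DataFrame(rows)
    if psleep_by_window:
        ps, th = [], []
        for row in table.itertuples(index=False):
            key = (row.side, row.window_start_min)
            if key in psleep_by_window and np.isfinite(row.mean_threshold_g):
                ps.append(psleep_by_window[key])
                th.append(row.mean_threshold_g)
        if len(ps) >= 3 and np.ptp(ps) > 0 and np.ptp(th) > 0:
            r, p = stats.pearsonr(ps, th)
            table.attrs["psleep_threshold_r"] = float(r)
            table.attrs["psleep_threshold_p"] = float(p)
    return table
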