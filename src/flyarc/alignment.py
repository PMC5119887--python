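"""Peri-meal statistics: P_sleep, dP_sleep, initiation, position, speed.

Everything here works on an :class:`AlignedSleepMatrix`: one row per
meal, one column per relative minute k in {-W..-1, +1..+W} (the minute
containing the meal is excluded), cell = fraction of that minute spent
asleep, with a validity mask for bins falling outside the recording or
inside masked epochs (e.g. daily food changes).

P_sleep(k) is the column mean over unmasked cells; dP_sleep(k) =
P_sleep(+k) - P_sleep(-k); the 20-min per-meal form is the mean over
+1..+20 minus the mean over -20..-1, computed only for meals whose full
span is unmasked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ParameterError
from .tracking import ActivitySeries, PositionTrace, SleepBout

__all__ = [
    "AlignedSleepMatrix",
    "DeltaPsleepSummary",
    "align_to_meals",
    "psleep_curve",
    "delta_psleep",
    "sleep_initiation_prob",
    "position_kinetics",
    "delta_speed_motion",
    "paired_prepost_test",
    "zt_bin_labels",
]


@dataclass
class AlignedSleepMatrix:
    """Meals x relative-minute sleep-fraction matrix.

    ``values[i, j]`` is the fraction of relative minute ``rel_minutes[j]``
    that meal i's fly spent asleep; ``valid[i, j]`` is False where the
    bin fell outside the recording or inside a masked epoch.  Masked
    cells are excluded from every statistic.
    """

    meals: pd.DataFrame          # fly_id, time_s, minute, volume_ul, ...
    rel_minutes: np.ndarray      # (-W..-1, 1..W)
    values: np.ndarray           # (n_meals, 2W) in [0, 1]
    valid: np.ndarray            # bool, same shape

    @property
    def window(self) -> int:
        return int(self.rel_minutes.max())

    def column(self, k: int) -> int:
        j = np.flatnonzero(self.rel_minutes == k)
        if len(j) != 1:
            raise ParameterError(f"relative minute {k} not in matrix")
        return int(j[0])

    def block(self, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = [self.column(int(k)) for k in ks]
        return self.values[:, cols], self.valid[:, cols]


@dataclass
class DeltaPsleepSummary:
    """Per-meal 20-min dP_sleep plus the per-bin curve with s.e.m."""

    span_min: int
    per_meal: np.ndarray         # NaN where the span was not fully unmasked
    n_excluded: int
    bins: np.ndarray             # k = 1..W
    per_bin: np.ndarray          # dP(k) = P(+k) - P(-k)
    per_bin_sem: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_meal))


def rel_minute_axis(window: int) -> np.ndarray:
    return np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])


def align_to_meals(sleep_fraction_min: dict[int, np.ndarray] | np.ndarray,
                   meals: pd.DataFrame, window: int = 60,
                   masked_minutes: dict[int, np.ndarray] | None = None,
                   ) -> AlignedSleepMatrix:
    """Build the meals x relative-minute sleep matrix.

    ``sleep_fraction_min`` maps fly_id to a per-minute sleep-fraction
    series (or is an array indexed by fly_id).  Bins truncated by the
    recording boundary, or falling in a fly's ``masked_minutes``, are
    masked.  A meal whose own minute lies outside its fly's series is
    rejected.
    """
    rel = rel_minute_axis(window)
    n = len(meals)
    values = np.zeros((n, len(rel)))
    valid = np.zeros((n, len(rel)), dtype=bool)
    for i, row in enumerate(meals.itertuples(index=False)):
        series = np.asarray(sleep_fraction_min[int(row.fly_id)], dtype=float)
        m0 = int(row.time_s) // 60
        if not 0 <= m0 < len(series):
            raise ParameterError(
                f"meal at minute {m0} outside recording span for fly {row.fly_id}"
            )
        mask = None
        if masked_minutes is not None:
            mask = np.asarray(masked_minutes.get(int(row.fly_id), []), dtype=int)
        idx = m0 + rel
        inside = (idx >= 0) & (idx < len(series))
        values[i, inside] = series[idx[inside]]
        valid[i] = inside
        if mask is not None and len(mask):
            valid[i] &= ~np.isin(idx, mask)
    return AlignedSleepMatrix(meals=meals.reset_index(drop=True),
                              rel_minutes=rel, values=values, valid=valid)


def psleep_curve(matrix: AlignedSleepMatrix) -> pd.DataFrame:
    """Per-bin P_sleep mean and s.e.m. over unmasked meals.

    Bins with no unmasked meal are reported as missing (NaN mean, n=0).
    """
    n = matrix.valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0,
                        np.where(matrix.valid, matrix.values, 0.0).sum(axis=0)
                        / np.maximum(n, 1), np.nan)
        sq = np.where(matrix.valid, (matrix.values - mean) ** 2, 0.0).sum(axis=0)
        sem = np.where(n > 1, np.sqrt(sq / np.maximum(n - 1, 1))
                       / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"rel_minute": matrix.rel_minutes,
                         "psleep_mean": mean, "psleep_sem": sem, "n": n})


def delta_psleep(matrix: AlignedSleepMatrix, span_min: int = 20) -> DeltaPsleepSummary:
    """Per-meal and per-bin dP_sleep (post minus time-matched pre).

    The per-meal 20-min form uses only meals whose full +/-span is
    unmasked; excluded meals are counted.  The per-bin curve runs over
    the matrix's whole window.
    """
    W = matrix.window
    if span_min > W:
        raise ParameterError(f"span {span_min} exceeds window {W}")
    post, post_ok = matrix.block(np.arange(1, span_min + 1))
    pre, pre_ok = matrix.block(-np.arange(1, span_min + 1))
    full = post_ok.all(axis=1) & pre_ok.all(axis=1)
    per_meal = np.where(full, post.mean(axis=1) - pre.mean(axis=1), np.nan)

    bins = np.arange(1, W + 1)
    per_bin = np.empty(W)
    per_bin_sem = np.empty(W)
    for j, k in enumerate(bins):
        p, pok = matrix.block(np.array([k]))
        q, qok = matrix.block(np.array([-k]))
        ok = pok[:, 0] & qok[:, 0]
        d = p[ok, 0] - q[ok, 0]
        per_bin[j] = d.mean() if len(d) else np.nan
        per_bin_sem[j] = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan
    return DeltaPsleepSummary(span_min=span_min, per_meal=per_meal,
                              n_excluded=int((~full).sum()), bins=bins,
                              per_bin=per_bin, per_bin_sem=per_bin_sem)


def sleep_initiation_prob(bouts: dict[int, list[SleepBout]], meals: pd.DataFrame,
                          window: int = 60, span_min: int = 20) -> pd.DataFrame:
    """Probability of a sleep-bout start per relative minute around meals.

    Bin value = fraction of meals with at least one bout start in that
    minute.  Also reports pre/post bout frequency over ``span_min`` as
    attributes ``pre_rate``/``post_rate`` (bout starts per meal).
    """
    rel = rel_minute_axis(window)
    n = len(meals)
    counts = np.zeros(len(rel))
    pre_starts = post_starts = 0
    for row in meals.itertuples(index=False):
        start_minutes = {b.start_s // 60 for b in bouts.get(int(row.fly_id), [])}
        m0 = int(row.time_s) // 60
        hits = np.isin(m0 + rel, list(start_minutes))
        counts += hits
        pre_starts += int(hits[(rel < 0) & (rel >= -span_min)].sum())
        post_starts += int(hits[(rel > 0) & (rel <= span_min)].sum())
    out = pd.DataFrame({"rel_minute": rel,
                        "p_initiation": counts / n if n else counts})
    out.attrs["pre_rate"] = pre_starts / n if n else np.nan
    out.attrs["post_rate"] = post_starts / n if n else np.nan
    return out


def position_kinetics(traces: dict[int, PositionTrace], meals: pd.DataFrame,
                      window_min: int = 20, smooth_sigma_px: float = 0.0,
                      ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Peri-meal positional kymograph and occupancy heat maps.

    Returns ``(kymograph, heat_pre, heat_post)``.  The kymograph holds
    the mean (over meals) vertical position per relative minute plus the
    per-meal pre/post means; heat maps count seconds spent at each
    integer pixel coordinate in the ``window_min`` before/after meals,
    optionally Gaussian-smoothed.  Heat-map mass equals the number of
    observed seconds when unsmoothed.
    """
    rel = rel_minute_axis(window_min)
    rows = []
    shape = None
    for tr in traces.values():
        h = int(np.ceil(max(tr.y.max(), 1))) + 1
        w = int(np.ceil(max(tr.x.max(), 1))) + 1
        shape = (max(shape[0], h), max(shape[1], w)) if shape else (h, w)
    heat_pre = np.zeros(shape)
    heat_post = np.zeros(shape)
    ky = np.full((len(meals), len(rel)), np.nan)
    for i, row in enumerate(meals.itertuples(index=False)):
        tr = traces[int(row.fly_id)]
        t0 = int(row.time_s)
        for j, k in enumerate(rel):
            m0 = (t0 // 60 + k) * 60
            if 0 <= m0 and m0 + 60 <= len(tr):
                ky[i, j] = tr.y[m0:m0 + 60].mean()
        for sgn, heat in ((-1, heat_pre), (1, heat_post)):
            lo = t0 + 1 if sgn > 0 else max(0, t0 - window_min * 60)
            hi = min(len(tr), t0 + window_min * 60 + 1) if sgn > 0 else t0
            xs = np.clip(np.round(tr.x[lo:hi]).astype(int), 0, shape[1] - 1)
            ys = np.clip(np.round(tr.y[lo:hi]).astype(int), 0, shape[0] - 1)
            np.add.at(heat, (ys, xs), 1.0)
    if smooth_sigma_px > 0:
        heat_pre = ndimage.gaussian_filter(heat_pre, smooth_sigma_px)
        heat_post = ndimage.gaussian_filter(heat_post, smooth_sigma_px)
    kym = pd.DataFrame({"rel_minute": rel,
                        "mean_y": np.nanmean(ky, axis=0),
                        "sem_y": np.nanstd(ky, ddof=1, axis=0)
                        / np.sqrt(np.sum(~np.isnan(ky), axis=0))})
    pre_cols = rel < 0
    kym.attrs["per_meal_pre_y"] = np.nanmean(ky[:, pre_cols], axis=1)
    kym.attrs["per_meal_post_y"] = np.nanmean(ky[:, ~pre_cols], axis=1)
    return kym, heat_pre, heat_post


def delta_speed_motion(series: dict[int, ActivitySeries], meals: pd.DataFrame,
                       span_min: int = 20) -> pd.DataFrame:
    """Per-meal delta_speed and delta_motion over +/- span windows.

    delta_speed = mean motion-event speed post minus pre (events whose
    start falls in the window); meals lacking events on either side get
    NaN and are counted via the ``n_excluded_speed`` attribute.
    delta_motion = mean per-second filtered displacement post minus pre.
    """
    span = span_min * 60
    out = []
    excluded = 0
    for row in meals.itertuples(index=False):
        ser = series[int(row.fly_id)]
        t0 = int(row.time_s)
        pre_ev = [e.speed_px_per_s for e in ser.motion_events
                  if t0 - span <= e.start_s < t0]
        post_ev = [e.speed_px_per_s for e in ser.motion_events
                   if t0 < e.start_s <= t0 + span]
        if pre_ev and post_ev:
            dspeed = float(np.mean(post_ev) - np.mean(pre_ev))
        else:
            dspeed = np.nan
            excluded += 1
        pre = ser.displacement_px[max(0, t0 - span):t0]
        post = ser.displacement_px[t0 + 1:t0 + span + 1]
        dmotion = (float(post.mean() - pre.mean())
                   if len(pre) and len(post) else np.nan)
        out.append({"fly_id": row.fly_id, "time_s": t0,
                    "delta_speed": dspeed, "delta_motion": dmotion})
    df = pd.DataFrame(out)
    df.attrs["n_excluded_speed"] = excluded
    return df


def paired_prepost_test(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon convention); if every pair is
    tied the test carries no signal and (0.0, 1.0) is returned by
    convention.  Requires at least 6 pairs.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    if len(pre) < 6:
        raise ParameterError(f"need >= 6 pairs, got {len(pre)}")
    if np.all(pre == post):
        return 0.0, 1.0
    method = "exact" if len(pre) <= 25 else "auto"
    stat, p = stats.wilcoxon(post, pre, zero_method="wilcox",
                             alternative="two-sided", method=method)
    return float(stat), float(p)


def zt_bin_labels(meal_times_s: np.ndarray, zt0_offset_s: int = 0,
                  bin_hours: int = 4) -> np.ndarray:
    """Assign each meal to a Zeitgeber-time bin (default 4-h bins).

    ZT 0 is anchored at lights-on; ``zt0_offset_s`` is the recording
    second at which lights came on (may be negative if lights-on
    preceded the recording).  Labels are the bin's starting ZT hour.
    """
    zt_h = (((np.asarray(meal_times_s, dtype=float) - zt0_offset_s) / 3600.0)
            % 24.0)
    return (np.floor(zt_h / bin_hours) * bin_hours).astype(int)
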