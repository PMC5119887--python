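"""Ground-truthed synthetic experiments for the combined feeding/sleep assay.

The generator emulates the three raw data streams the analysis pipeline
consumes — capillary image stacks, 1 Hz fly centroid traces, and diet
tables — together with the ground truth needed to validate every stage:
true meal times/volumes/nutrient masses, the true per-second sleep state,
and the postprandial kernel actually injected into the sleep process.

Model in brief
--------------
Rest/activity is a discrete-time two-state Markov chain at 1-min
resolution.  The per-minute probability of entering rest is

    p_in(m) = baseline_sleep_entry_prob + sum over recent meals of
              [kernel_amplitude + volume_coefficient * volume
               + sum_c nutrient_coefficients[c] * mass_c]

for the ``kernel_duration_min`` minutes following each meal (boxcar
kernel; an exponentially decaying kernel with the same time constant is
also available), clipped to [0, 1].  Exit from rest is a constant
per-minute probability.  Meals occur only in active minutes (a fly must
wake to eat) as a thinned Bernoulli process, with log-normal volumes.

Sleep ground truth applies the standard immobility criterion to the rest
state: a second is asleep iff it lies in a rest run strictly longer than
5 min.  Rest runs of 5 min or less are quiet wakefulness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tracking import PositionTrace

__all__ = [
    "BehaviorParams",
    "CapillaryGeometry",
    "FlyTruth",
    "GroundTruthBehavior",
    "simulate_behavior",
    "simulate_concentration_series",
    "render_capillary_stack",
    "render_position_trace",
    "simulate_arousal_traces",
]

SECONDS_PER_MINUTE = 60


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the synthetic fly-behavior model.

    Defaults describe a realistic control fly on a standard liquid diet:
    ~40% of time at rest (entry 0.04/min, exit 0.06/min, i.e. ~17 min
    rest bouts), ~0.9 realized meals/h, log-normal meal volumes with
    median 0.02 ul (sigma 0.6; ~37% of meals fall in 0.02-0.04 ul), and
    a 30-min postprandial boxcar raising sleep-entry probability by 0.2.
    """

    n_flies: int = 30
    duration_s: int = 24 * 3600
    meal_rate_per_hour: float = 1.5          # candidate rate while active
    meal_volume_mu: float = math.log(0.02)   # log-ul
    meal_volume_sigma: float = 0.6
    baseline_sleep_entry_prob: float = 0.04  # per minute
    baseline_sleep_exit_prob: float = 0.06   # per minute
    kernel_amplitude: float = 0.2            # additive entry-prob boost
    kernel_duration_min: int = 30
    kernel_shape: str = "boxcar"             # "boxcar" | "exponential"
    volume_coefficient: float = 0.0          # entry-prob boost per ul
    nutrient_coefficients: Mapping[str, float] = field(default_factory=dict)
    diet: Mapping[str, float] = field(
        default_factory=lambda: {"sucrose": 2.5, "yeast_extract": 2.5}
    )  # % w/v per component
    grooming_rate_per_hour: float = 2.0
    grooming_bout_mean_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ParameterError("n_flies must be >= 1")
        if not (self.duration_s > 0 and self.duration_s % 60 == 0):
            raise ParameterError("duration_s must be a positive multiple of 60")
        for name in (
            "meal_rate_per_hour",
            "meal_volume_mu",
            "meal_volume_sigma",
            "baseline_sleep_entry_prob",
            "baseline_sleep_exit_prob",
            "kernel_amplitude",
            "volume_coefficient",
            "grooming_rate_per_hour",
            "grooming_bout_mean_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        for p in ("baseline_sleep_entry_prob", "baseline_sleep_exit_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ParameterError(f"{p} must lie in [0, 1]")
        if self.kernel_amplitude < -self.baseline_sleep_entry_prob:
            raise ParameterError(
                "kernel_amplitude may not drive the entry probability negative"
            )
        if self.kernel_duration_min < 1:
            raise ParameterError("kernel_duration_min must be >= 1")
        if self.kernel_shape not in ("boxcar", "exponential"):
            raise ParameterError("kernel_shape must be 'boxcar' or 'exponential'")
        if self.meal_rate_per_hour < 0 or self.grooming_rate_per_hour < 0:
            raise ParameterError("rates must be >= 0")
        if any(c < 0 or not np.isfinite(c) for c in self.diet.values()):
            raise ParameterError("diet concentrations must be finite and >= 0")

    @property
    def n_minutes(self) -> int:
        return self.duration_s // SECONDS_PER_MINUTE


@dataclass(frozen=True)
class CapillaryGeometry:
    """Rendering geometry for one capillary viewed side-on.

    ``volume_per_px`` defaults to 0.01 ul/px, the 10 nL-per-pixel scale of
    the 5 ul capillary setup the analysis is calibrated for.
    """

    capillary_length_px: int = 140
    volume_per_px: float = 0.01           # ul per pixel of band travel
    ref_mark_row: int = 12
    band_start_row: int = 30
    band_thickness_px: int = 4
    frame_shape: tuple[int, int] = (140, 16)  # rows, cols per capillary
    pixel_noise_sd: float = 4.0           # grayscale units (0-255 scale)
    evaporation_px_per_frame: float = 0.0
    foreground_level: float = 200.0
    background_level: float = 10.0

    def __post_init__(self) -> None:
        if self.volume_per_px <= 0:
            raise ParameterError("volume_per_px must be > 0")
        if not (0 <= self.ref_mark_row < self.frame_shape[0]):
            raise ParameterError("ref_mark_row outside frame")
        if self.band_start_row <= self.ref_mark_row:
            raise ParameterError("dye band must start below the reference mark")
        if self.band_thickness_px < 1:
            raise ParameterError("band_thickness_px must be >= 1")
        if self.pixel_noise_sd < 0 or self.evaporation_px_per_frame < 0:
            raise ParameterError("noise and evaporation must be >= 0")


@dataclass
class FlyTruth:
    """Ground truth for a single fly."""

    fly_id: int
    meals: pd.DataFrame            # time_s, minute, volume_ul, <comp>_ug ...
    rest_state_min: np.ndarray     # uint8 per minute; 1 = at rest
    sleep_state_s: np.ndarray      # uint8 per second; 1 = asleep (>5 min rule)
    grooming_s: np.ndarray         # uint8 per second
    entry_prob_min: np.ndarray     # realized p_in per minute (post-clip)
    diet: dict[str, float]         # % w/v per component


@dataclass
class GroundTruthBehavior:
    """Simulator output: per-fly ground truth plus the generating params."""

    params: BehaviorParams
    flies: list[FlyTruth]

    @property
    def meals(self) -> pd.DataFrame:
        """All meals across flies, one row per meal, with fly_id column."""
        frames = [f.meals for f in self.flies if len(f.meals)]
        if not frames:
            cols = ["fly_id", "time_s", "minute", "volume_ul"]
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)

    def sleep_matrix(self) -> np.ndarray:
        """(n_flies, n_seconds) uint8 sleep-state array."""
        return np.stack([f.sleep_state_s for f in self.flies])


def _kernel_boost(params: BehaviorParams, per_meal_boost: float) -> np.ndarray:
    """Per-minute entry-probability increments contributed by one meal."""
    d = params.kernel_duration_min
    if params.kernel_shape == "boxcar":
        return np.full(d, per_meal_boost)
    # exponential: time constant = kernel_duration_min, truncated at 4 tau
    j = np.arange(4 * d)
    return per_meal_boost * np.exp(-j / d)


def _meal_boost(params: BehaviorParams, volume: float, masses: dict) -> float:
    b = params.kernel_amplitude + params.volume_coefficient * volume
    for comp, coeff in params.nutrient_coefficients.items():
        b += coeff * masses.get(f"{comp}_ug", 0.0)
    return b


def sleep_from_rest(rest_state_min: np.ndarray, min_sleep_s: int = 300) -> np.ndarray:
    """Expand a per-minute rest state to per-second sleep.

    A second is asleep iff it belongs to a rest run strictly longer than
    ``min_sleep_s`` seconds (rest runs are whole minutes here, so the
    default rule admits runs of >= 6 consecutive rest minutes).
    """
    rest = np.asarray(rest_state_min, dtype=np.uint8)
    sleep_min = np.zeros_like(rest)
    n = len(rest)
    i = 0
    while i < n:
        if rest[i]:
            j = i
            while j < n and rest[j]:
                j += 1
            if (j - i) * SECONDS_PER_MINUTE > min_sleep_s:
                sleep_min[i:j] = 1
            i = j
        else:
            i += 1
    return np.repeat(sleep_min, SECONDS_PER_MINUTE)


def _simulate_fly(
    params: BehaviorParams, fly_id: int, rng: np.random.Generator, diet: dict
) -> FlyTruth:
    n_min = params.n_minutes
    p_meal = params.meal_rate_per_hour / 60.0
    p_out = params.baseline_sleep_exit_prob

    boost = np.zeros(n_min + 1)
    rest = np.zeros(n_min, dtype=np.uint8)
    entry_prob = np.zeros(n_min)
    meal_rows: list[dict] = []

    # Pre-draw per-minute uniforms; meal volumes drawn lazily to keep the
    # stream identical whether or not later minutes see meals.
    u_meal = rng.random(n_min)
    u_trans = rng.random(n_min)

    at_rest = False
    for m in range(n_min):
        rest[m] = at_rest
        if not at_rest and u_meal[m] < p_meal:
            volume = float(rng.lognormal(params.meal_volume_mu, params.meal_volume_sigma))
            second = int(m * SECONDS_PER_MINUTE + rng.integers(SECONDS_PER_MINUTE))
            masses = {f"{c}_ug": volume * 10.0 * pct for c, pct in diet.items()}
            meal_rows.append(
                {"fly_id": fly_id, "time_s": second, "minute": m, "volume_ul": volume,
                 **masses}
            )
            k = _kernel_boost(params, _meal_boost(params, volume, masses))
            end = min(n_min, m + len(k))
            boost[m:end] += k[: end - m]
        p_in = float(np.clip(params.baseline_sleep_entry_prob + boost[m], 0.0, 1.0))
        entry_prob[m] = p_in
        if at_rest:
            at_rest = not (u_trans[m] < p_out)
        else:
            at_rest = u_trans[m] < p_in

    meals = pd.DataFrame(meal_rows) if meal_rows else pd.DataFrame(
        columns=["fly_id", "time_s", "minute", "volume_ul"]
        + [f"{c}_ug" for c in diet]
    )
    sleep_s = sleep_from_rest(rest)

    # Grooming: bouts on active (non-rest) seconds only.
    grooming = np.zeros(params.duration_s, dtype=np.uint8)
    active_s = np.repeat(1 - rest, SECONDS_PER_MINUTE).astype(bool)
    n_bouts = rng.poisson(params.grooming_rate_per_hour * params.duration_s / 3600.0)
    if n_bouts and active_s.any():
        starts = rng.choice(np.flatnonzero(active_s), size=n_bouts, replace=True)
        durations = rng.geometric(1.0 / params.grooming_bout_mean_s, size=n_bouts)
        for s, d in zip(starts, durations):
            e = min(params.duration_s, s + int(d))
            seg = grooming[s:e]
            seg[active_s[s:e]] = 1
    meal_seconds = np.asarray([r["time_s"] for r in meal_rows], dtype=int)
    grooming[meal_seconds] = 0  # a fly does not groom mid-sip

    return FlyTruth(
        fly_id=fly_id,
        meals=meals,
        rest_state_min=rest,
        sleep_state_s=sleep_s,
        grooming_s=grooming,
        entry_prob_min=entry_prob,
        diet=dict(diet),
    )


def simulate_behavior(
    params: BehaviorParams, diets: Sequence[Mapping[str, float]] | None = None
) -> GroundTruthBehavior:
    """Simulate ground-truth behavior for ``params.n_flies`` flies.

    One RNG stream per fly, spawned from the master seed, so subsetting
    flies never perturbs the remaining streams.  ``diets`` optionally
    assigns a diet per fly (cycled); default is ``params.diet`` for all.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_flies)
    flies = []
    for i, child in enumerate(children):
        diet = dict(diets[i % len(diets)]) if diets else dict(params.diet)
        flies.append(_simulate_fly(params, i, np.random.default_rng(child), diet))
    return GroundTruthBehavior(params=params, flies=flies)


def simulate_concentration_series(
    base_params: BehaviorParams,
    component: str,
    concentrations: Sequence[float],
    flies_per_diet: int,
) -> GroundTruthBehavior:
    """Concentration-series design: groups of flies on graded diets.

    Each group of ``flies_per_diet`` flies receives ``base_params.diet``
    with ``component`` set to one value of ``concentrations``.
    """
    diets = []
    for conc in concentrations:
        d = dict(base_params.diet)
        d[component] = float(conc)
        diets.extend([d] * flies_per_diet)
    params = replace(base_params, n_flies=len(diets))
    return simulate_behavior(params, diets=diets)


# ---------------------------------------------------------------------------
# Capillary image rendering
# ---------------------------------------------------------------------------

def _draw_band(frame: np.ndarray, center: float, thickness: int, cols: slice,
               level: float) -> None:
    """Add a horizontal band with sub-pixel anti-aliasing at ``center``."""
    lo = center - thickness / 2.0
    hi = center + thickness / 2.0
    rows = np.arange(frame.shape[0])
    overlap = np.clip(np.minimum(rows + 1, hi) - np.maximum(rows, lo), 0.0, 1.0)
    frame[:, cols] += level * overlap[:, None]


def render_capillary_stack(
    behavior: GroundTruthBehavior,
    geom: CapillaryGeometry,
    seed: int | None = None,
):
    """Render a time-lapse stack of dye-banded capillaries, one per fly.

    Returns ``(stack, rois, ledger)``: a ``(n_frames, H, W)`` uint8 stack
    at one frame per minute, per-capillary column ROIs, and the renderer's
    displacement ledger (band travel in px from its start, per frame per
    fly) — the ground truth for round-trip tests.

    Frame ``t`` shows the state at the end of minute ``t``: the band has
    moved by (cumulative intake through minute t) / volume_per_px plus
    ``evaporation_px_per_frame * t``, while the reference mark is fixed.
    """
    params = behavior.params
    n_frames = params.n_minutes
    n_cap = len(behavior.flies)
    H, w = geom.frame_shape
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed if seed is None else seed, 0xCA11])
    )

    ledger = np.zeros((n_cap, n_frames))
    for i, fly in enumerate(behavior.flies):
        intake = np.zeros(n_frames)
        if len(fly.meals):
            mins = fly.meals["minute"].to_numpy()
            vols = fly.meals["volume_ul"].to_numpy()
            np.add.at(intake, mins, vols)
        cum_px = np.cumsum(intake) / geom.volume_per_px
        ledger[i] = cum_px + geom.evaporation_px_per_frame * np.arange(n_frames)

    max_row = geom.band_start_row + ledger.max() + geom.band_thickness_px / 2.0
    if max_row >= H - 1:
        raise ParameterError(
            f"dye band exits the frame (needs row {max_row:.1f} of {H}); "
            "enlarge frame_shape or shorten the recording"
        )

    stack = np.empty((n_frames, H, w * n_cap), dtype=np.uint8)
    rois = [(i, slice(i * w + 2, (i + 1) * w - 2)) for i in range(n_cap)]
    mark_thick = geom.band_thickness_px
    for t in range(n_frames):
        frame = np.full((H, w * n_cap), geom.background_level, dtype=float)
        for i, (_, cols) in enumerate(rois):
            _draw_band(frame, geom.ref_mark_row + 0.5, mark_thick, cols,
                       geom.foreground_level)
            _draw_band(frame, geom.band_start_row + 0.5 + ledger[i, t],
                       geom.band_thickness_px, cols, geom.foreground_level)
        frame += rng.normal(0.0, geom.pixel_noise_sd, size=frame.shape)
        stack[t] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack, rois, ledger


# ---------------------------------------------------------------------------
# Position-trace rendering
# ---------------------------------------------------------------------------

def render_position_trace(
    behavior: GroundTruthBehavior,
    fbl_px: float = 16.0,
    jitter_fraction: float = 0.3,
    chamber_px: tuple[float, float] = (60.0, 180.0),
    food_xy: tuple[float, float] = (30.0, 10.0),
    baseline_y: float = 120.0,
    position_sd: float = 30.0,
    post_meal_bias_px: float = 0.0,
    bias_duration_min: int = 20,
) -> list[PositionTrace]:
    """Emit 1 Hz centroid traces consistent with the ground-truth states.

    Asleep (rest) seconds hold position exactly.  Each awake second the
    fly either relocates (a fresh draw around its target y, step lengths
    generally above the 0.5*FBL immobility filter) or, with probability
    ``jitter_fraction``, makes a sub-FBL jitter step that the motion
    filter discards.  Feeding seconds place the fly at the food.  A
    nonzero ``post_meal_bias_px`` shifts the target y toward the food by
    that many pixels for ``bias_duration_min`` after each meal,
    reproducing post-meal food proximity.
    """
    if not 0.0 <= jitter_fraction <= 1.0:
        raise ParameterError("jitter_fraction must lie in [0, 1]")
    if fbl_px <= 0:
        raise ParameterError("fbl_px must be > 0")
    params = behavior.params
    n = params.duration_s
    W, Hc = chamber_px
    traces = []
    for fly in behavior.flies:
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 0x905, fly.fly_id])
        )
        rest_s = np.repeat(fly.rest_state_min, SECONDS_PER_MINUTE).astype(bool)
        awake = ~rest_s
        move = awake & (rng.random(n) >= jitter_fraction)
        meal_sec = fly.meals["time_s"].to_numpy(dtype=int) if len(fly.meals) else \
            np.empty(0, dtype=int)
        move[meal_sec] = True
        # settling/rousing movements flank every rest bout, so the scored
        # immobility run coincides with the rest run
        edge = np.diff(rest_s.astype(np.int8))
        move[np.flatnonzero(edge == 1)] = True          # last awake second
        after = np.flatnonzero(edge == -1) + 1          # first awake second
        move[after[after < n]] = True

        target_y = np.full(n, baseline_y)
        if post_meal_bias_px:
            for s in meal_sec:
                target_y[s: s + bias_duration_min * 60] = baseline_y - post_meal_bias_px

        bx = rng.uniform(2.0, W - 2.0, size=n)
        by = np.clip(rng.normal(target_y, position_sd), 2.0, Hc - 2.0)
        bx[meal_sec] = food_xy[0]
        by[meal_sec] = food_xy[1]

        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        step = rng.uniform(0.05, 0.45, size=n) * fbl_px
        jitter = awake & ~move
        jx = np.where(jitter, step * np.cos(theta), 0.0)
        jy = np.where(jitter, step * np.sin(theta), 0.0)
        cjx, cjy = np.cumsum(jx), np.cumsum(jy)

        # Position = base of last relocation + jitter accumulated since.
        move_idx = np.flatnonzero(move)
        t = np.arange(n)
        if len(move_idx):
            last = move_idx[np.searchsorted(move_idx, t, side="right") - 1]
            before_first = t < move_idx[0]
            last[before_first] = 0
            x = bx[last] + (cjx - cjx[last])
            y = by[last] + (cjy - cjy[last])
            if before_first.any():
                x[before_first] = bx[0]
                y[before_first] = by[0]
        else:
            x = np.full(n, bx[0])
            y = np.full(n, by[0])
        x = np.clip(x, 0.0, W)
        y = np.clip(y, 0.0, Hc)
        traces.append(
            PositionTrace(
                fly_id=fly.fly_id,
                x=x,
                y=y,
                tracked=np.ones(n, dtype=bool),
                fbl_px=fbl_px,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Arousal-experiment simulation
# ---------------------------------------------------------------------------

def simulate_arousal_traces(
    n_flies: int,
    duration_s: int,
    train_times_s: np.ndarray,
    intensities: Sequence[float],
    base_threshold_g: float = 0.8,
    depth_slope_g_per_min: float = 0.15,
    depth_cap_min: float = 15.0,
    meal_times_s: Mapping[int, np.ndarray] | None = None,
    post_meal_shift_g: float = 0.0,
    post_meal_window_s: int = 3600,
    rest_entry_prob: float = 0.04,
    rest_exit_prob: float = 0.05,
    fbl_px: float = 16.0,
    seed: int = 0,
    threshold_noise_g: float = 0.3,
):
    """Deepening-sleep arousal simulation with known true thresholds.

    Each fly alternates rest/active via a per-minute chain.  At each
    stimulus of a train, a resting fly responds iff the intensity
    reaches its current true threshold

        theta = base + depth_slope * min(prior_inactivity, cap)
                + post_meal_shift (within the post-meal window) + noise,

    in which case a supra-FBL movement is injected a couple of seconds
    after that stimulus.  Returns ``(traces, truth)`` where ``traces``
    are per-fly displacement series (px per second, already above/below
    the motion filter by construction) and ``truth`` is a DataFrame of
    the injected responses for oracle comparison.
    """
    rng_master = np.random.SeedSequence(seed)
    inter_stim_s = 15
    traces = []
    truth_rows = []
    for fly_id, child in enumerate(rng_master.spawn(n_flies)):
        rng = np.random.default_rng(child)
        n_min = duration_s // 60
        rest = np.zeros(n_min, dtype=bool)
        state = False
        for m in range(n_min):
            rest[m] = state
            state = (rng.random() >= rest_exit_prob) if state else \
                (rng.random() < rest_entry_prob)
        rest_s = np.repeat(rest, 60)
        disp = np.where(rest_s, 0.0, fbl_px)  # active seconds move a body length
        meals = (np.asarray(meal_times_s.get(fly_id, []), dtype=int)
                 if meal_times_s else np.empty(0, dtype=int))
        for t0 in np.asarray(train_times_s, dtype=int):
            if t0 >= duration_s or disp[t0] != 0.0:
                continue
            run_start = t0
            while run_start > 0 and disp[run_start - 1] == 0.0:
                run_start -= 1
            prior_inactive = t0 - run_start
            shift = 0.0
            if len(meals):
                d = t0 - meals
                if np.any((d > 0) & (d <= post_meal_window_s)):
                    shift = post_meal_shift_g
            theta = (base_threshold_g
                     + depth_slope_g_per_min * min(prior_inactive / 60.0, depth_cap_min)
                     + shift + rng.normal(0.0, threshold_noise_g))
            for j, g in enumerate(intensities):
                if g >= theta:
                    hit = t0 + j * inter_stim_s + 1 + int(rng.integers(3))
                    if hit < duration_s:
                        disp[hit] = fbl_px
                        truth_rows.append(
                            {"fly_id": fly_id, "train_time_s": int(t0),
                             "prior_inactivity_s": int(prior_inactive),
                             "true_threshold_g": theta,
                             "response_intensity_g": float(g)}
                        )
                    break
        traces.append(disp)
    return traces, pd.DataFrame(truth_rows)
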