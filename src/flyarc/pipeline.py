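"""End-to-end pipeline: capillaries -> meals -> sleep -> peri-meal stats.

``run_pipeline`` wires the stages together on synthetic or pre-extracted
inputs and writes every output CSV with a header carrying the config
hash and master seed, so a rerun with the same config is bit-identical
for the deterministic stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment, grading, io, meals as meals_mod, meniscus, tracking
from .config import RunConfig
from .errors import ParameterError
from .synthetic import (
    BehaviorParams, CapillaryGeometry, GroundTruthBehavior,
    render_capillary_stack, render_position_trace, simulate_behavior,
)

__all__ = ["PipelineResult", "run_pipeline", "analyze_traces"]


@dataclass
class PipelineResult:
    config: RunConfig
    meals: list = field(default_factory=list)
    meal_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    sleep_bouts: dict = field(default_factory=dict)
    psleep: pd.DataFrame = field(default_factory=pd.DataFrame)
    dpsleep: object = None
    volume_bins: list = field(default_factory=list)
    out_dir: Path | None = None


def analyze_traces(traces, positions, config: RunConfig,
                   grooming: dict[int, np.ndarray] | None = None,
                   ) -> PipelineResult:
    """Meals + sleep + alignment + grading from extracted traces.

    ``traces``: list of MeniscusTrace (one per fly/capillary);
    ``positions``: list of PositionTrace with matching fly_ids.
    """
    diet = meals_mod.Diet(dict(config.diet))
    all_meals = []
    for tr in traces:
        noise = meals_mod.estimate_noise(
            tr.delta_px, tr.flagged, sd_multiplier=config.noise_sd_multiplier
        )
        called = meals_mod.call_meals(tr, noise, config.meal_sd_multiplier)
        called = meals_mod.correct_meals(called, tr.delta_px, tr.flagged)
        called = meals_mod.to_volume_and_nutrients(called, config.volume_per_px,
                                                   diet)
        all_meals.extend(called)

    series = {}
    bouts = {}
    sleep_fraction = {}
    for pos in positions:
        ser = tracking.displacement_series(pos, config.fbl_fraction)
        series[pos.fly_id] = ser
        if grooming and pos.fly_id in grooming:
            bs = tracking.score_sleep_grooming(ser, grooming[pos.fly_id],
                                               config.min_sleep_s)
        else:
            bs = tracking.score_sleep(ser, config.min_sleep_s)
        bouts[pos.fly_id] = bs
        sleep_fraction[pos.fly_id] = tracking.per_minute_sleep_fraction(
            tracking.sleep_seconds(bs, len(pos))
        )

    result = PipelineResult(config=config, meals=all_meals,
                            sleep_bouts=bouts)
    meal_table = io.meals_to_frame(all_meals)
    if len(meal_table):
        matrix = alignment.align_to_meals(sleep_fraction, meal_table,
                                          config.align_window_min)
        result.psleep = alignment.psleep_curve(matrix)
        summary = alignment.delta_psleep(matrix, config.dpsleep_span_min)
        result.dpsleep = summary
        meal_table = meal_table.assign(dpsleep=summary.per_meal)
        graded = meal_table.dropna(subset=["volume_ul", "dpsleep"])
        if len(graded) >= 2:
            result.volume_bins = grading.bin_by_volume(
                graded, config.volume_bin_ul, config.volume_percentile_cut
            )
    result.meal_table = meal_table
    return result


def run_pipeline(config: RunConfig, out_dir,
                 behavior: GroundTruthBehavior | None = None,
                 params: BehaviorParams | None = None,
                 geometry: CapillaryGeometry | None = None,
                 from_images: bool = True) -> PipelineResult:
    """Simulate (unless given), run every stage, write the result bundle.

    With ``from_images`` the capillary stack is rendered and re-read by
    the meniscus tracker (the full image path); otherwise the renderer's
    displacement ledger feeds the meal caller directly, which is much
    faster for large simulated cohorts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}

    if behavior is None:
        params = params or BehaviorParams(seed=config.seed, diet=config.diet)
        behavior = simulate_behavior(params)
    geometry = geometry or CapillaryGeometry()

    if from_images:
        stack, rois, _ = render_capillary_stack(behavior, geometry)
        roi_objs = [meniscus.CapillaryROI(cid, cols.start, cols.stop)
                    for cid, cols in rois]
        traces = meniscus.extract_trace(
            stack, roi_objs, threshold=config.binarize_threshold,
            rolling_ball_radius=config.rolling_ball_radius,
            min_area_px=config.min_feature_area_px,
        )
    else:
        _, _, ledger = render_capillary_stack(behavior, geometry)
        n = ledger.shape[1]
        traces = []
        for i in range(ledger.shape[0]):
            delta = np.zeros(n)
            delta[1:] = np.diff(ledger[i])
            traces.append(meniscus.MeniscusTrace(
                capillary_id=i, distance_px=ledger[i].copy(), delta_px=delta,
                minutes=np.arange(n, dtype=float),
                flagged=np.zeros(n, dtype=bool),
            ))

    positions = render_position_trace(behavior)
    grooming = {f.fly_id: f.grooming_s for f in behavior.flies}
    result = analyze_traces(traces, positions, config, grooming=None)
    result.out_dir = out_dir

    io.write_traces_csv(traces, out_dir / "traces.csv", meta)
    io.write_meals_csv(result.meals, out_dir / "meals.csv", meta)
    io.write_positions_csv(positions, out_dir / "positions.csv", meta)
    io.write_sleep_csv(result.sleep_bouts, out_dir / "sleep_bouts.csv", meta)
    io.write_grooming_csv(grooming, out_dir / "grooming.csv", meta)
    if len(result.psleep):
        io._write_csv(result.psleep, out_dir / "psleep_curve.csv", meta)
    if len(result.meal_table):
        io._write_csv(result.meal_table, out_dir / "meal_summary.csv", meta)
    if result.volume_bins:
        io._write_csv(pd.DataFrame([vars(b) for b in result.volume_bins]),
                      out_dir / "volume_grading.csv", meta)
    config.to_yaml(out_dir / "config.yaml")
    return result
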