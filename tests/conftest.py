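import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import flyarc  # noqa: E402


@pytest.fixture(scope="session")
def small_behavior():
    """5 flies x 6 h with the default postprandial kernel."""
    params = flyarc.BehaviorParams(n_flies=5, duration_s=6 * 3600, seed=42)
    return flyarc.simulate_behavior(params)


@pytest.fixture(scope="session")
def null_behavior():
    """15 flies x 24 h with no meal->sleep coupling at all."""
    params = flyarc.BehaviorParams(
        n_flies=15, duration_s=24 * 3600, seed=7,
        kernel_amplitude=0.0, volume_coefficient=0.0,
    )
    return flyarc.simulate_behavior(params)


def make_fly_truth(n_minutes, rest_minutes=(), meal_specs=(), fly_id=0,
                   diet=None):
    """Hand-built FlyTruth: explicit rest minutes and meals.

    ``meal_specs``: iterable of (minute, volume_ul).  Nutrient masses
    follow ``diet`` (% w/v) when given.
    """
    from flyarc.synthetic import FlyTruth, sleep_from_rest

    diet = diet or {}
    rest = np.zeros(n_minutes, dtype=np.uint8)
    rest[list(rest_minutes)] = 1
    rows = []
    for minute, vol in meal_specs:
        row = {"fly_id": fly_id, "time_s": minute * 60 + 30, "minute": minute,
               "volume_ul": vol}
        row.update({f"{c}_ug": vol * 10.0 * pct for c, pct in diet.items()})
        rows.append(row)
    meals = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["fly_id", "time_s", "minute", "volume_ul"])
    return FlyTruth(
        fly_id=fly_id, meals=meals, rest_state_min=rest,
        sleep_state_s=sleep_from_rest(rest),
        grooming_s=np.zeros(n_minutes * 60, dtype=np.uint8),
        entry_prob_min=np.full(n_minutes, 0.04),
        diet=dict(diet),
    )


def make_behavior(flies, seed=0, **param_overrides):
    """Wrap hand-built FlyTruth objects in a GroundTruthBehavior."""
    from flyarc.synthetic import GroundTruthBehavior

    n_min = len(flies[0].rest_state_min)
    defaults = dict(n_flies=len(flies), duration_s=n_min * 60, seed=seed)
    defaults.update(param_overrides)
    return GroundTruthBehavior(params=flyarc.BehaviorParams(**defaults),
                               flies=list(flies))
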