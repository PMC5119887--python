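"""Arousal thresholds from hourly trains of rising vibration intensity.

A deepening-sleep simulation (true threshold rises with time inactive)
is probed with the standard 0.8-3.2 g, 0.6 g-step trains; scored
thresholds are binned by prior inactivity with a quadratic trend.
"""

import numpy as np

import flyarc
from flyarc.arousal import (assign_arousal, build_schedule,
                            threshold_by_inactivity)
from flyarc.synthetic import simulate_arousal_traces
from flyarc.tracking import ActivitySeries

schedule = build_schedule(0, 12 * 3600, period_s=1200)
print(f"schedule: {len(schedule.train_times_s)} trains, "
      f"intensities {schedule.intensities_g} g")

traces, truth = simulate_arousal_traces(
    n_flies=20, duration_s=12 * 3600,
    train_times_s=schedule.train_times_s,
    intensities=schedule.intensities_g,
    depth_slope_g_per_min=0.15, threshold_noise_g=0.2, seed=51)

events = []
for fly_id, disp in enumerate(traces):
    events += assign_arousal(ActivitySeries(fly_id, disp, [], 16.0),
                             schedule, fly_id=fly_id)
responded = [e for e in events if e.responded]
print(f"{len(events)} arousal events scored, {len(responded)} responded")

table, coeffs = threshold_by_inactivity(events, bin_width_s=300)
for row in table.itertuples(index=False):
    print(f"  inactive {row.inactivity_low_s // 60:2d}-"
          f"{row.inactivity_high_s // 60:2d} min: threshold "
          f"{row.mean_threshold_g:.2f} g (n={row.n})")
print(f"quadratic trend coefficients: {np.round(coeffs, 6)}")
# Mean threshold climbs over the first bins of prior inactivity and then
# saturates: flies transitioning into sleep need stronger stimuli the
# longer they have been still.
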