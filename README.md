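# flyarc

Simultaneous feeding and sleep analysis for single flies.

Experiments that pair a capillary feeder (CAFE) with machine-vision
tracking record, for each fly, a time-lapse image series of a
dye-banded capillary (one frame per minute) and a 1 Hz centroid trace.
`flyarc` turns those raw streams into discrete, volume-calibrated
feeding events and sleep bouts, and computes the peri-prandial
statistics that describe how a meal changes sleep:

- **Meniscus tracking** — rolling-ball background subtraction,
  thresholding, and sub-pixel localization of the reference mark and
  dye band; per-frame distance and Δpixel series.
- **Meal calling** — iterative noise estimation (distal values 4.0 s.d.
  above the Δpixel mean are filtered out until none remain), selection
  of frames 3.5 s.d. above noise, merging of adjacent feeding bouts
  (time-stamped at the latter bout frame), evaporation/luminance
  correction, and conversion to µl and per-nutrient µg at the
  10 nL-per-pixel calibration of 5 µl capillaries.
- **Sleep scoring** — reference-subtraction blob detection, resetting
  of dropped positions, discarding of motion below 0.5 fly body
  lengths, and the standard rule that immobility exceeding 5 min is
  sleep (optionally grooming-aware).
- **Peri-meal statistics** — P_sleep per 1-min bin aligned to meals,
  ΔP_sleep (post-meal minus time-matched pre-meal, per bin and as the
  20-min summary), sleep-initiation probability, positional kymographs
  and occupancy heat maps, Δ_speed/Δ_motion, Wilcoxon matched-pairs
  tests, and 4-h Zeitgeber-time partitions.
- **Dose–response grading** — 0.01 µl volume bins with 97th-percentile
  exclusion; nutrient grading inside the 0.02–0.04 µl volume window
  (1.333 µg sucrose / 0.333 µg protein / 0.05 µg salt bins); Pearson
  and Spearman correlations; ΔP_sleep time-course kinetics (smoothing
  spline, amplitude and decay total); and the equal-sampling Monte
  Carlo control (3000 trials of a fixed number of meals per fly).
- **Arousal thresholds** — hourly trains of rising vibration intensity
  (0.8–3.2 g in 0.6 g steps, 15 s between intensities); the threshold
  is the first intensity that moves a fly that was inactive at stimulus
  onset; thresholds binned by prior inactivity and compared pre/post
  meal with sleep depth controlled.
- **Synthetic experiments** — a generative model (two-state
  rest/activity Markov chain with a postprandial boost to sleep entry,
  thinned meal process, capillary image renderer, position renderer,
  arousal simulator) that emits both the raw data streams and their
  ground truth, so the whole pipeline is validated end to end.

The central quantity is ΔP_sleep: with P_sleep(k) the population mean
probability of being asleep in 1-min bin k relative to a meal at k = 0,

    ΔP_sleep(k)      = P_sleep(+k) − P_sleep(−k)
    20-min ΔP_sleep  = mean over k = +1…+20  −  mean over k = −20…−1

computed per meal and tested with the Wilcoxon matched-pairs
signed-rank test.

## Worked example

`examples/` holds one short script per capability.  Aligning sleep to
meals on a simulated cohort (`examples/03_peri_meal_sleep.py`):

```
$ python examples/03_peri_meal_sleep.py
307 meals from 20 flies
P_sleep, 20 min pre-meal : 0.357
P_sleep, 20 min post-meal: 0.661
mean 20-min dP_sleep     : +0.301 (12 meals lacked a full window)
Wilcoxon matched-pairs: W=6762, p=5.02e-23
```

The flies sleep in 66% of post-meal minutes versus 36% of time-matched
pre-meal minutes; the per-meal 20-min ΔP_sleep of +0.30 reflects the
sleep-entry boost this cohort was simulated with, and the paired test
confirms the rise is systematic across meals.  Meal calling itself is
exact on clean renders (`examples/01_simulate_and_call_meals.py`):

```
fly 0: 5 meals called / 5 true; intake 0.123 ul called / 0.123 ul true (noise sd 0.02 px)
```

A thin CLI wraps the same library for shell use:

```sh
flyarc run-all --seed 2 --n-flies 5 --hours 6 --out-dir out/
flyarc simulate ... / track-capillaries ... / call-meals ... / score-sleep ...
```

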