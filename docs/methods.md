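# Methods

`flyarc` analyzes experiments in which a single fly's food intake and
sleep are measured simultaneously: a camera images a calibrated glass
capillary whose dyed oil band rides the food meniscus (one frame per
minute), while a second camera tracks the fly's centroid at 1 Hz.  The
package implements the full analysis stack for such recordings and a
generative model of the behavior with known ground truth, so every
stage can be validated end to end.

## Feeding: meniscus tracking and meal calling

Frames are background-subtracted with a rolling ball (radius 5 px,
smoothing disabled) and binarized at a global threshold.  In each
capillary ROI the two expected features — a static external reference
mark and the mobile dye band — are located as connected components
(minimum area configurable, default 4 px²); the reference mark is the
feature nearest its position in the previous frame.  Centroids are
intensity-weighted over the component (support grown by one row so
anti-aliased edges contribute): a binary-mask centroid quantizes slow
evaporation drift into half-pixel steps that the downstream outlier
filtration would misread as feeding events.  The per-frame distance
`band_row − ref_row` grows with consumption; its first difference
(Δpixel, with Δ(0)=0) is the feeding signal.  Frames where a feature is
lost carry the last distance forward with Δ=0 and are flagged; flagged
frames never participate in noise estimation or meal selection.

Noise is estimated by iterative filtration: values more than 4.0 sample
s.d. above the mean of the retained set are removed until none qualify,
fewer than 10 values remain, or 100 passes elapse (removal-only, so
termination is guaranteed; sample s.d. uses ddof=1).  Frames with
Δ > mean + 3.5 s.d. are feeding frames; maximal runs of consecutive
feeding frames merge into one meal, time-stamped at the latter bout
frame — so bouts separated by at least one minute of non-feeding are
distinct meals.  Each meal's summed Δ is corrected for evaporation and
luminance drift by subtracting the mean Δ of all non-feeding,
non-flagged frames times the bout length; the per-frame form makes the
correction scale with bout duration and is unbiased under constant
drift (a per-event variant is provided).  Corrected displacement is
floored at zero and converted by the calibration (default 0.01 µl/px,
the 10 nL-per-pixel scale of 5 µl capillaries) to volume, and by the
diet's % w/v concentrations (1% w/v = 10 µg/µl) to per-component
masses.  Noise is estimated per capillary per food-change epoch, since
daily food changes reset the meniscus.

## Sleep: motion filtering and immobility scoring

Fly centroids come from reference-frame subtraction: the brightest
residual pixel seeds an edge-following outline whose polygon centroid,
area, and major axis describe the object; a frame whose peak falls
below the object threshold is untracked.  Fly body length (FBL) is
estimated as the median detected major axis (config-overridable).
Untracked seconds are reset to the last known location *before*
filtering; per-second Euclidean displacements below 0.5·FBL are set to
zero (treated as immobility, keeping the timeline gap-free), making the
filter idempotent.  Motion events are maximal runs of nonzero filtered
displacement with speed = distance / uninterrupted duration.  Sleep is
any immobility run strictly exceeding 300 s; runs truncated at
recording boundaries count if their observed duration exceeds the
criterion.  Grooming-aware scoring requires immobility *and* absence of
grooming (per-second binary annotation) for >300 s, and can only reduce
total sleep.

## Peri-meal statistics

Each meal contributes one row of an aligned matrix over relative
minutes k ∈ {−W…−1, +1…+W} (default W=60; the meal's own minute is
excluded); the cell is the fraction of that minute spent asleep, so
averages of 1-min bins are well defined and bounded.  Bins outside the
recording or inside masked epochs (e.g. the daily ZT 0–0.5 food change)
are masked and excluded from every statistic.  P_sleep(k) is the column
mean; ΔP_sleep(k) = P_sleep(+k) − P_sleep(−k); the per-meal 20-min
ΔP_sleep is the mean over +1…+20 minus −20…−1 and is computed only for
meals with a fully unmasked span (excluded meals are counted).  When no
cells are masked, the mean per-bin ΔP over k=1…20 equals the mean
per-meal 20-min ΔP (an algebraic identity the tests assert).  Meals
with overlapping windows are both retained by default (each meal is an
event); window-overlap exclusion is available for sensitivity analysis.
Companion statistics: probability of a sleep-bout start per relative
minute; a positional kymograph (mean vertical position per relative
minute) and pre/post occupancy heat maps (seconds per pixel, optional
Gaussian smoothing; unsmoothed mass equals observed seconds); per-meal
Δ_speed (mean motion-event speed post − pre) and Δ_motion (mean
per-second displacement post − pre).  Pre/post comparisons use the
Wilcoxon matched-pairs signed-rank test, two-sided, zeros dropped
(exact distribution at n ≤ 25; all pairs tied returns p=1 by
convention).  Time-of-day analyses partition meals into 4-h Zeitgeber
bins anchored at lights-on.

## Dose–response grading

Meals carrying a 20-min ΔP_sleep are graded into half-open 0.01 µl
volume bins after excluding volumes above the 97th percentile
(linear-interpolation estimator), or — within the closed 0.02–0.04 µl
volume window, which holds roughly a third of meals at the default
volume distribution — into nutrient-mass bins (1.333 µg sucrose,
0.333 µg tryptone, 0.05 µg NaCl by convention).  Binned means are
related to dose by OLS of bin means on bin centers.  The equal-sampling
Monte Carlo control keeps this regression unweighted (each trial
resamples a fixed number of meals per fly without replacement, 3000
trials, Gaussian fitted to the slope histogram, full-data slope
alongside); for dose–response *recovery* the slope is occupancy-
weighted, because terminal bins holding a handful of meals otherwise
dominate the estimator's variance.  Slope standard errors for
group-design contrasts come from a fly-level bootstrap: meals cluster
within flies, so resampling whole flies respects the correlation a
pooled within-bin variance ignores.  Binned relationships are tested
with Pearson correlation, per-meal relationships with Spearman rank
correlation (an exact-permutation p-value, doubled smaller tail, is
available for small n).  Time-course kinetics smooth the 1-min ΔP
curve with a cubic smoothing spline (λ configurable, default 1.0);
amplitude is the curve maximum and decay total the summed ΔP over the
20 min after the maximum's bin.

## Arousal thresholds

Hourly trains present vibrations of increasing intensity (defaults
0.8–3.2 g in 0.6 g steps; 200 ms pulses with 800 ms gaps, 15 s between
intensities).  An arousal event requires the fly (1) inactive at
stimulus onset, (2) meeting the prior-inactivity criterion (default
≥1 s, measured at train onset), and (3) moving — any nonzero filtered
displacement — within the 15 s after the stimulus.  Intensities are
walked in order; the first whose window contains movement is the
response intensity and ends the train for that fly (once aroused, later
intensities are uninformative; a fly already moving at a later stimulus
onset also ends the walk).  Responded events are binned by prior
inactivity (5-min bins) with a second-order polynomial trend, and
compared pre- vs post-meal in 0–20/20–40/40–60 min windows with events
filtered to 0–5 min prior inactivity to control for sleep depth
(two-sided Mann-Whitney per window pair; Pearson correlation between
window P_sleep and mean threshold across the six windows).

## The synthetic experiment generator

Rest/activity is a two-state Markov chain at 1-min resolution (matching
the 1-min analysis bins), mapped to seconds.  Per-minute rest-entry
probability is baseline plus, for `kernel_duration_min` after each
meal, amplitude + volume_coefficient·volume + Σ coefficient·mass
(boxcar by default; an exponential variant with the same time constant
is provided), clipped to [0,1]; rest exit is constant.  Meals arise
only in active minutes (a fly must wake to eat) as a thinned Bernoulli
process with log-normal volumes.  *Sleep* ground truth applies the same
>5-min rule the scorer uses to the rest state: rest runs of ≤5 min are
quiet wakefulness, which is what makes scorer round-trips a meaningful
identity rather than a tautology.  Defaults, chosen once as a realistic
control fly: entry 0.04/min and exit 0.06/min (≈40% rest, ~17 min rest
bouts), 1.5 candidate meals/h while active (≈0.9/h realized, ≈650
meals per 30 flies per day), volumes log-normal with median 0.02 µl and
σ=0.6 (≈37% of meals in 0.02–0.04 µl), kernel amplitude 0.2 over
30 min (a postprandial rise lasting tens of minutes), grooming 2
bouts/h of ~60 s on active seconds.  One RNG stream per fly is spawned
from the master seed, so subsetting flies never perturbs the others.

The capillary renderer draws the reference mark fixed and the band
displaced by cumulative intake / (µl/px) plus a constant evaporation
rate (px/frame), with anti-aliased edges and additive Gaussian pixel
noise; its displacement ledger is the ground truth for round-trip
tests, and the band must stay inside the frame for the simulated total
intake.  The position renderer holds position exactly during rest,
relocates awake flies around a target vertical position (optionally
shifted toward the food for a configurable post-meal window), and gives
a configurable fraction of awake seconds sub-FBL jitter that the motion
filter discards; settling/rousing movements flank each rest bout so the
scored immobility run coincides with the rest run.  An arousal
simulator gives each fly a true threshold that rises with time inactive
(capped), plus an optional uniform post-meal shift, and injects a
supra-FBL movement after the first suprathreshold stimulus.

What the generator does *not* emulate: within-bout sip microstructure
(unresolvable at one frame per minute), circadian modulation of sleep
pressure, optical artifacts beyond additive noise and constant drift
(bubbles, condensation, lens distortion), multi-fly occlusion, and any
real biomechanics of fly posture.  Passing tests therefore demonstrate
correctness of the scoring rules and statistics under the model's
assumptions, not robustness to every artifact of real video.

## Validation oracles and problem sizes

The test suite checks each scoring rule against a literal brute-force
re-implementation (iterative filtration, threshold-merge meal
selection, per-second displacement scan, run-length sleep scan,
three-criteria arousal walk, sign-flip and permutation enumerations for
the rank tests).  Peri-meal statistics are checked against an exact
evaluation of the generating chain: the >5-min rule is handled by
augmenting the chain state with rest-run age capped at 6 min (exit is
homogeneous, so the probability a run of age j reaches 6 is
(1−q)^(6−j)), and the expected sleep probability at every minute is
obtained by forward–backward smoothing conditioned on each fly's
realized meal pattern — a meal minute implies wakefulness, and meal
absence down-weights activity by (1−p_meal).  By the tower property the
mean of these smoothed probabilities over meals equals the expectation
of the empirical aligned averages, so recovered ΔP_sleep can be
compared to theory without Monte Carlo error on the theory side; the
smoothing evaluation itself was verified against direct simulation of
the chain.  The model-implied dose–response slope (the chain-predicted
per-meal ΔP binned and regressed exactly like the data) defines the
"injected slope" for recovery checks, since the coefficients act on the
entry probability and the entry-probability→ΔP map is nonlinear.

Validation problem sizes are chosen so each bound is a ≥3 s.e.
statement rather than a coin flip: null calibration pools four
independent 30-fly × 24-h cohorts (>2500 meals) and checks the paired
test's type-I error over 800–1000 small replicate experiments;
kernel recovery uses one 30-fly × 24-h cohort against the chain
evaluation (±0.05); dose–response recovery uses a 900-fly × 24-h cohort
(~15,000 meals, 15% band ≈ 2.9 s.e.); group-design nutrient contrasts
take the median z over three independent concentration series (a single
2-s.e. check is a ~95% event by construction).  The full suite runs in
under two minutes on one CPU.

## Numerical conventions and edge cases

0-based, row-major image coordinates; ROIs are half-open intervals.
Times are integer seconds from recording start, with a ZT offset for
light-cycle binning; CSVs are UTF-8, comma-separated, '.' decimal, with
`#` header lines carrying the config hash and master seed.  Degenerate
inputs have defined behavior rather than crashes: constant Δ series
return (value, sd=0) in one filtration pass; empty meal lists are
valid; all-tied paired tests return p=1; zero-variance correlations
raise a typed error; bins with one meal report an undefined s.e.m.;
empty arousal bins are omitted.  All analysis defaults (4.0/3.5 s.d.
multipliers, 300 s sleep rule, 0.5 FBL fraction, 0.01 µl/px, window
and bin sizes) live in `RunConfig`, and every output file is stamped
with the config hash so overrides are visible.

## Known limitations

The evaporation model (and its correction) is stationary; humidity
transients after food changes are handled only by masking the
food-change epoch.  Meal windows of closely spaced meals overlap, which
dilutes measured ΔP_sleep at high meal rates relative to a single-meal
expectation — both retained-window and excluded-window analyses are
provided, and the chain oracle conditions on the full meal pattern for
exactly this reason.  The arousal walk assumes one response terminates
a train; flies that move spontaneously mid-train are scored at the
intensity whose window caught the movement.  Sub-pixel meniscus
localization assumes reasonably symmetric band intensity; strongly
skewed illumination would bias distances by a constant that the Δ
series cancels.
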