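"""Independent brute-force oracles used by the test suite.

Everything here is deliberately literal and slow: plain-Python loops
re-implementing each scoring rule exactly as stated, plus an exact
dynamic-programming evaluation of the rest/active Markov chain with the
>5-min sleep rule.  None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np


# -- iterative noise filtration + meal selection ----------------------------

def noise_filtration_oracle(delta, sd_multiplier=4.0, min_retained=10,
                            max_iterations=100):
    """Literal re-run of the iterative distal-value filtration."""
    retained = [float(v) for v in delta if np.isfinite(v)]
    iterations = 0
    mean = sd = 0.0
    while iterations < max_iterations:
        iterations += 1
        mean = sum(retained) / len(retained)
        if len(retained) > 1:
            sd = (sum((v - mean) ** 2 for v in retained) / (len(retained) - 1)) ** 0.5
        else:
            sd = 0.0
        cut = mean + sd_multiplier * sd
        kept = [v for v in retained if v <= cut]
        if len(kept) == len(retained) or len(kept) < min_retained:
            break
        retained = kept
    return mean, sd, len(retained), iterations


def meal_selection_oracle(delta, flagged, mean, sd, multiplier=3.5):
    """Literal threshold + merge: list of (start, end, raw, time_of_latter)."""
    cut = mean + multiplier * sd
    hot = [(d > cut) and not f for d, f in zip(delta, flagged)]
    events = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            events.append((i, j, sum(delta[i:j + 1]), j))
            i = j + 1
        else:
            i += 1
    return events


# -- displacement / sleep ---------------------------------------------------

def displacement_oracle(x, y, tracked, fbl, fraction=0.5):
    """Per-second literal reset-then-filter displacement."""
    n = len(x)
    disp = [0.0] * n
    last = None
    for t in range(n):
        if tracked[t]:
            cur = (x[t], y[t])
        else:
            cur = last  # reset to last known location
        if last is not None and cur is not None:
            d = ((cur[0] - last[0]) ** 2 + (cur[1] - last[1]) ** 2) ** 0.5
            disp[t] = d if d >= fraction * fbl else 0.0
        if cur is not None:
            last = cur
    return disp


def sleep_scan_oracle(disp, min_duration=300):
    """Run-length scan for immobility bouts strictly exceeding 5 min."""
    bouts = []
    i = 0
    n = len(disp)
    while i < n:
        if disp[i] == 0.0:
            j = i
            while j < n and disp[j] == 0.0:
                j += 1
            if j - i > min_duration:
                bouts.append((i, j))
            i = j
        else:
            i += 1
    return bouts


# -- arousal three-criteria walk --------------------------------------------

def arousal_oracle(disp, train_time, intensities, inter_stim=15,
                   min_inactivity=1):
    """Literal application of the three arousal criteria to one train.

    Returns None when no event is scored, else a dict with prior
    inactivity and the response intensity (None if never responded).
    """
    n = len(disp)
    t0 = train_time
    if t0 >= n or disp[t0] != 0.0:
        return None  # criterion (1): inactive at the stimulus
    start = t0
    while start > 0 and disp[start - 1] == 0.0:
        start -= 1
    prior = t0 - start
    if prior < min_inactivity:
        return None  # criterion (2): inactivity criterion
    for j, g in enumerate(intensities):
        ts = t0 + j * inter_stim
        if ts >= n:
            break
        if j > 0 and disp[ts] != 0.0:
            break  # already aroused by an earlier intensity
        if any(d > 0 for d in disp[ts + 1:min(n, ts + inter_stim + 1)]):
            return {"prior_inactivity": prior, "response": g}
    return {"prior_inactivity": prior, "response": None}


# -- Markov chain with the >5-min sleep rule --------------------------------
#
# The generator's rest/active chain runs at 1-min resolution with
# per-minute entry probability p_in(m) (baseline + postprandial boost)
# and constant exit probability q.  "Asleep" applies the immobility
# criterion: a minute is asleep iff its rest run spans >= 6 minutes
# (> 300 s).  Because exit is homogeneous, the probability that a run of
# current age j eventually reaches length >= 6 is (1-q)^(6-j), which
# makes both directions exactly computable.

AGE_CAP = 6


def _augmented_step(alpha, p_in, q):
    """One transition of the age-augmented chain (A, R1..R6cap)."""
    out = np.zeros(AGE_CAP + 1)
    out[0] = alpha[0] * (1 - p_in) + sum(alpha[1:]) * q
    out[1] = alpha[0] * p_in
    for j in range(1, AGE_CAP):
        out[min(j + 1, AGE_CAP)] += alpha[j] * (1 - q)
    out[AGE_CAP] += alpha[AGE_CAP] * (1 - q)
    return out


def _asleep_prob(alpha, q):
    p = alpha[AGE_CAP]
    for j in range(1, AGE_CAP):
        p += alpha[j] * (1 - q) ** (AGE_CAP - j)
    return float(p)


def stationary_augmented(p_in, q, n_burn=5000):
    alpha = np.zeros(AGE_CAP + 1)
    alpha[0] = 1.0
    for _ in range(n_burn):
        alpha = _augmented_step(alpha, p_in, q)
    return alpha


def chain_post_psleep(p_in_seq, q, horizon):
    """P(asleep at minute +k | active at the meal minute), k = 1..horizon.

    ``p_in_seq[m]`` is the realized entry probability governing the
    transition out of minute m (m = 0 is the meal minute).
    """
    alpha = np.zeros(AGE_CAP + 1)
    alpha[0] = 1.0
    out = np.zeros(horizon)
    for k in range(1, horizon + 1):
        alpha = _augmented_step(alpha, p_in_seq[k - 1], q)
        out[k - 1] = _asleep_prob(alpha, q)
    return out


def chain_pre_psleep(p_base, q, horizon, p_in_seq=None, init_alphas=None):
    """P(asleep at minute -k | active at the meal minute), k = 1..horizon.

    Starts each -k evaluation from the stationary distribution of the
    baseline chain and runs a joint DP tracking whether the rest run
    containing minute -k reaches 6 minutes, conditioned on the chain
    being active at minute 0.  ``p_in_seq[m]`` (length ``horizon``,
    index 0 = transition out of minute -horizon) overrides the baseline
    entry probability between -k and 0 when given; ``init_alphas[k-1]``
    optionally supplies the augmented-state distribution at minute -k
    (e.g. evolved through realized pre-window entry probabilities so
    kernels of earlier meals are accounted for).
    """
    pi = stationary_augmented(p_base, q)
    out = np.zeros(horizon)
    for k in range(1, horizon + 1):
        if init_alphas is not None:
            pi = init_alphas[k - 1]
        # DP states: run age 1..5 (original run alive), then
        # (flag, chain in {A, R}) once resolved.
        run = np.zeros(AGE_CAP)          # index = age (1..5 used)
        done = np.zeros((2, 2))          # [flag][0=A, 1=R]
        done[0, 0] = pi[0]
        done[1, 1] = pi[AGE_CAP]
        for j in range(1, AGE_CAP):
            run[j] = pi[j]
        for step in range(k):
            if p_in_seq is not None:
                p_in = p_in_seq[horizon - k + step]
            else:
                p_in = p_base
            new_run = np.zeros(AGE_CAP)
            new_done = np.zeros((2, 2))
            for j in range(1, AGE_CAP):
                if run[j] == 0.0:
                    continue
                stay = run[j] * (1 - q)
                if j + 1 >= AGE_CAP:
                    new_done[1, 1] += stay
                else:
                    new_run[j + 1] += stay
                new_done[0, 0] += run[j] * q
            for f in range(2):
                new_done[f, 0] += done[f, 0] * (1 - p_in) + done[f, 1] * q
                new_done[f, 1] += done[f, 0] * p_in + done[f, 1] * (1 - q)
            run, done = new_run, new_done
        p_active = done[0, 0] + done[1, 0]
        out[k - 1] = done[1, 0] / p_active if p_active > 0 else np.nan
    return out


def smoothed_sleep_probability(fly, params):
    """P(asleep at minute t | the fly's whole realized meal pattern).

    Exact forward-backward smoothing of the age-augmented chain run with
    the fly's realized entry probabilities, treating the meal pattern as
    evidence: a meal minute implies wakefulness (weight p_meal on the
    active state), a meal-free minute down-weights activity by
    (1 - p_meal).  "Asleep" needs a forward-looking factor: a minute in
    a rest run of age j < 6 is asleep iff the run later reaches age 6,
    handled by an auxiliary backward recursion alongside the standard
    backward pass.  The mean of these smoothed probabilities over meals
    equals, by the tower property, the expectation of the empirical
    per-cell averages under the generative model.
    """
    p_in = np.asarray(fly.entry_prob_min, dtype=float)
    q = params.baseline_sleep_exit_prob
    p_meal = params.meal_rate_per_hour / 60.0
    T = len(p_in)
    meal_min = set(int(m) for m in fly.meals["minute"]) if len(fly.meals) else set()

    w = np.ones((T, AGE_CAP + 1))
    for t in range(T):
        if t in meal_min:
            w[t, 0] = p_meal
            w[t, 1:] = 0.0
        else:
            w[t, 0] = 1.0 - p_meal

    # forward (scaled): simulator starts active
    a = np.zeros((T, AGE_CAP + 1))
    v = np.zeros(AGE_CAP + 1)
    v[0] = 1.0
    v *= w[0]
    a[0] = v / v.sum()
    for t in range(1, T):
        v = _augmented_step(a[t - 1], p_in[t - 1], q) * w[t]
        a[t] = v / v.sum()

    # backward pass plus the run-reaches-6 factor h (same scaling)
    b = np.zeros((T, AGE_CAP + 1))
    h = np.zeros((T, AGE_CAP))          # h[t, j] for ages j = 1..5
    b[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        nxt = w[t + 1] * b[t + 1]
        bt = np.zeros(AGE_CAP + 1)
        bt[0] = (1 - p_in[t]) * nxt[0] + p_in[t] * nxt[1]
        for j in range(1, AGE_CAP):
            bt[j] = q * nxt[0] + (1 - q) * nxt[min(j + 1, AGE_CAP)]
        bt[AGE_CAP] = q * nxt[0] + (1 - q) * nxt[AGE_CAP]
        ht = np.zeros(AGE_CAP)
        for j in range(1, AGE_CAP):
            cont = (w[t + 1, min(j + 1, AGE_CAP)] *
                    (b[t + 1, AGE_CAP] if j + 1 >= AGE_CAP else h[t + 1, j + 1]))
            ht[j] = (1 - q) * cont
        scale = bt.sum()
        b[t] = bt / scale
        h[t] = ht / scale

    asleep = np.zeros(T)
    for t in range(T):
        denom = float(np.dot(a[t], b[t]))
        num = a[t, AGE_CAP] * b[t, AGE_CAP]
        for j in range(1, AGE_CAP):
            num += a[t, j] * h[t, j]
        asleep[t] = num / denom if denom > 0 else np.nan
    return asleep


def chain_dp20(behavior, span=20, meal_filter=None):
    """Expected 20-min dP_sleep for a simulated cohort, meal by meal.

    For each meal, the forward evaluation of the generating chain
    (:func:`smoothed_sleep_probability`) supplies the expected sleep
    probability at every relative minute; the 20-min post-minus-pre
    difference is averaged over meals with a full +/- span inside the
    recording.  ``meal_filter(fly, minute)`` can restrict the set.
    """
    vals = []
    for fly in behavior.flies:
        n_min = len(fly.entry_prob_min)
        asleep = None
        for m0 in fly.meals["minute"]:
            m0 = int(m0)
            if m0 - span < 0 or m0 + span >= n_min:
                continue
            if meal_filter is not None and not meal_filter(fly, m0):
                continue
            if asleep is None:
                asleep = smoothed_sleep_probability(fly, behavior.params)
            post = asleep[m0 + 1: m0 + span + 1].mean()
            pre = asleep[m0 - span: m0].mean()
            vals.append(post - pre)
    return float(np.mean(vals)) if vals else float("nan")
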