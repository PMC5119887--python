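"""Meal-size and nutrient dose-response analysis of postprandial sleep.

Meals (each carrying a per-meal 20-min dP_sleep) are graded into
half-open 0.01 ul volume bins (meals above the 97th volume percentile
excluded first) or, within a 0.02-0.04 ul volume window, into nutrient
mass bins (1.333 ug sucrose, 0.333 ug protein, 0.05 ug salt by
convention).  Binned means are compared by Pearson correlation and OLS
slope; per-meal pairs by Spearman rank correlation.  The equal-sampling
Monte Carlo control re-runs the binned regression on a fixed number of
randomly sampled meals per fly to rule out bias from unequal per-fly
meal counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .errors import DegenerateSeries, ParameterError

__all__ = [
    "GradedBinSummary",
    "MonteCarloResult",
    "bin_by_volume",
    "grade_nutrient",
    "binned_slope",
    "correlate",
    "kinetics",
    "monte_carlo_equal_sampling",
    "DEFAULT_NUTRIENT_BIN_UG",
]

DEFAULT_VOLUME_BIN_UL = 0.01
DEFAULT_VOLUME_WINDOW_UL = (0.02, 0.04)
DEFAULT_NUTRIENT_BIN_UG = {"sucrose": 1.333, "tryptone": 0.333, "nacl": 0.05}
VOLUME_PERCENTILE_CUT = 97.0


@dataclass(frozen=True)
class GradedBinSummary:
    """One half-open dose bin with its mean 20-min dP_sleep."""

    bin_low: float
    bin_high: float
    n: int
    mean_dpsleep: float
    sem_dpsleep: float

    @property
    def center(self) -> float:
        return 0.5 * (self.bin_low + self.bin_high)


@dataclass(frozen=True)
class MonteCarloResult:
    """Equal-sampling Monte Carlo control for the binned regression."""

    trials: int
    samples_per_fly: int
    slopes: np.ndarray
    gaussian_mu: float
    gaussian_sigma: float
    full_data_slope: float
    n_flies_used: int
    n_flies_excluded: int


def _summarize_bins(x: np.ndarray, dp: np.ndarray, width: float,
                    origin: float = 0.0) -> list[GradedBinSummary]:
    idx = np.floor((x - origin) / width).astype(int)
    out = []
    for i in np.unique(idx):
        sel = idx == i
        vals = dp[sel]
        out.append(GradedBinSummary(
            bin_low=origin + i * width,
            bin_high=origin + (i + 1) * width,
            n=int(sel.sum()),
            mean_dpsleep=float(vals.mean()),
            sem_dpsleep=float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else np.nan,
        ))
    return out


def bin_by_volume(meals: pd.DataFrame, width_ul: float = DEFAULT_VOLUME_BIN_UL,
                  percentile_cut: float | None = VOLUME_PERCENTILE_CUT,
                  ) -> list[GradedBinSummary]:
    """Grade meals into half-open volume bins [i*w, (i+1)*w).

    Meals with volume above the ``percentile_cut`` (linear-interpolation
    percentile of the meal volumes; pass None to disable) are excluded
    before binning, dropping the thin large-meal tail where bins are too
    sparse to average.  ``meals`` needs ``volume_ul`` and ``dpsleep``
    columns with finite dpsleep.
    """
    df = meals.dropna(subset=["dpsleep"])
    v = df["volume_ul"].to_numpy(dtype=float)
    dp = df["dpsleep"].to_numpy(dtype=float)
    if percentile_cut is not None and len(v):
        keep = v <= np.percentile(v, percentile_cut)
        v, dp = v[keep], dp[keep]
    return _summarize_bins(v, dp, width_ul)


def grade_nutrient(meals: pd.DataFrame, component: str,
                   bin_width_ug: float | None = None,
                   volume_window_ul: tuple[float, float] = DEFAULT_VOLUME_WINDOW_UL,
                   ) -> list[GradedBinSummary]:
    """Grade meals by ingested mass of one diet component.

    Meals are first filtered to the closed volume window (default
    0.02-0.04 ul) so volume contributes little across nutrient bins,
    then binned by ``<component>_ug``.  Default bin widths follow the
    grading conventions: 1.333 ug sucrose, 0.333 ug tryptone (protein),
    0.05 ug NaCl.
    """
    col = f"{component}_ug"
    if col not in meals.columns or not np.isfinite(meals[col]).any():
        raise ParameterError(f"component {component!r} absent from all diets")
    if bin_width_ug is None:
        try:
            bin_width_ug = DEFAULT_NUTRIENT_BIN_UG[component]
        except KeyError:
            raise ParameterError(
                f"no default bin width for {component!r}; pass bin_width_ug"
            ) from None
    df = meals.dropna(subset=["dpsleep"])
    lo, hi = volume_window_ul
    df = df[(df["volume_ul"] >= lo) & (df["volume_ul"] <= hi)]
    return _summarize_bins(df[col].to_numpy(dtype=float),
                           df["dpsleep"].to_numpy(dtype=float), bin_width_ug)


def binned_slope(bins: list[GradedBinSummary],
                 weighted: bool = False) -> tuple[float, float]:
    """OLS slope (and its s.e.) of bin means on bin centers.

    Unweighted by default (each bin one point, the convention for the
    equal-sampling control); ``weighted`` weights bins by occupancy,
    which stops sparse terminal bins from dominating the estimate in
    dose-response recovery.
    """
    if len(bins) < 2:
        raise ParameterError("need >= 2 bins for a slope")
    x = np.array([b.center for b in bins])
    y = np.array([b.mean_dpsleep for b in bins])
    if not weighted:
        res = stats.linregress(x, y)
        return float(res.slope), float(res.stderr)
    w = np.array([b.n for b in bins], dtype=float)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    # se from the pooled within-bin (per-meal) variance: var(bin mean) =
    # s^2/n_i, so var(slope) = s^2 / sum n_i (x_i - xbar)^2
    sems = np.array([b.sem_dpsleep for b in bins])
    ns = w
    ok = np.isfinite(sems) & (ns > 1)
    if ok.any():
        pooled = np.sum((ns[ok] - 1) * (sems[ok] ** 2 * ns[ok])) / \
            np.sum(ns[ok] - 1)
        se = float(np.sqrt(pooled / sxx))
    else:
        se = float("nan")
    return float(slope), se


def fly_bootstrap_slope_se(meals: pd.DataFrame, slope_fn, n_boot: int = 200,
                           seed: int = 0) -> float:
    """Fly-level bootstrap s.e. of a binned dose-response slope.

    Meals from one fly share sleep windows and a diet, so per-meal
    residuals are correlated within flies and a pooled-variance s.e.
    understates the uncertainty.  Resampling whole flies with
    replacement respects that cluster structure.  ``slope_fn`` maps a
    meal table to a slope (e.g. grade + binned_slope).
    """
    flies = meals["fly_id"].unique()
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_boot):
        take = rng.choice(flies, size=len(flies), replace=True)
        df = pd.concat([meals[meals["fly_id"] == f] for f in take],
                       ignore_index=True)
        try:
            slopes.append(slope_fn(df))
        except (ParameterError, DegenerateSeries):
            continue
    if len(slopes) < n_boot // 2:
        raise ParameterError("too many degenerate bootstrap replicates")
    return float(np.std(slopes, ddof=1))


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson",
              exact: bool = False) -> tuple[float, float]:
    """Correlation coefficient and p-value.

    ``pearson`` for binned means (linear), ``spearman`` for per-meal
    pairs (rank-based, robust to the non-normal dP_sleep distribution).
    ``exact`` switches the p-value to the exact permutation distribution
    (all pairings; feasible for small n).  Zero variance in either
    variable is undefined and raises :class:`DegenerateSeries`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ParameterError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeries("zero variance; correlation undefined")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ParameterError("method must be 'pearson' or 'spearman'")
    if exact:
        perm = stats.PermutationMethod(n_resamples=np.inf)
        res = stats.pearsonr(x, y, method=perm)
    else:
        res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def kinetics(rel_minutes: np.ndarray, dpsleep: np.ndarray,
             smoothing_lam: float | None = 1.0, decay_span_min: int = 20,
             ) -> tuple[float, float]:
    """Amplitude and decay total of a post-meal dP_sleep time-course.

    The 1-min curve over k = 1..W is smoothed with a cubic smoothing
    spline (``smoothing_lam``; None for no smoothing); amplitude is the
    curve maximum and decay_total the summed dP_sleep over the
    ``decay_span_min`` minutes following the maximum's bin.
    """
    k = np.asarray(rel_minutes, dtype=float)
    y = np.asarray(dpsleep, dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ParameterError("all-missing dP_sleep curve")
    k, y = k[ok], y[ok]
    if smoothing_lam is not None and len(k) > 4:
        spline = interpolate.make_smoothing_spline(k, y, lam=smoothing_lam)
        y = spline(k)
    imax = int(np.argmax(y))
    amplitude = float(y[imax])
    decay = y[imax + 1: imax + 1 + decay_span_min]
    return amplitude, float(decay.sum())


def monte_carlo_equal_sampling(meals: pd.DataFrame, samples_per_fly: int,
                               trials: int = 3000, seed: int = 0,
                               width_ul: float = DEFAULT_VOLUME_BIN_UL,
                               percentile_cut: float | None = VOLUME_PERCENTILE_CUT,
                               ) -> MonteCarloResult:
    """Equal-sampling Monte Carlo control for the volume-dP regression.

    Each trial samples ``samples_per_fly`` meals without replacement
    from every qualifying fly (flies with fewer meals are excluded and
    counted), grades them into volume bins, and records the OLS slope of
    binned mean dP_sleep on bin center.  A Gaussian is fitted to the
    slope histogram and the full-data slope reported alongside, so an
    unbiased pooled-meal regression shows the Gaussian centered on it.
    """
    df = meals.dropna(subset=["dpsleep"]).reset_index(drop=True)
    counts = df.groupby("fly_id").size()
    qualified = counts[counts >= samples_per_fly].index.to_numpy()
    if len(qualified) == 0:
        raise ParameterError(
            f"no fly has >= {samples_per_fly} meals; cannot equal-sample"
        )
    groups = {f: df.index[df["fly_id"] == f].to_numpy() for f in qualified}
    rng = np.random.default_rng(seed)
    slopes = np.empty(trials)
    for t in range(trials):
        take = np.concatenate([
            rng.choice(groups[f], size=samples_per_fly, replace=False)
            for f in qualified
        ])
        bins = bin_by_volume(df.loc[take], width_ul, percentile_cut)
        slopes[t], _ = binned_slope(bins)
    mu, sigma = stats.norm.fit(slopes)
    full_slope, _ = binned_slope(
        bin_by_volume(df[df["fly_id"].isin(qualified)], width_ul, percentile_cut)
    )
    return MonteCarloResult(
        trials=trials, samples_per_fly=samples_per_fly, slopes=slopes,
        gaussian_mu=float(mu), gaussian_sigma=float(sigma),
        full_data_slope=float(full_slope),
        n_flies_used=int(len(qualified)),
        n_flies_excluded=int((counts < samples_per_fly).sum()),
    )
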