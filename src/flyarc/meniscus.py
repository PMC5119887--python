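"""Capillary image stacks -> meniscus-distance and delta-pixel series.

Each capillary carries an external reference mark (static) and an
internal dyed oil band riding the food meniscus (mobile).  Frames are
background-subtracted with a rolling ball, binarized at a global
threshold, and the two features are located per ROI; the per-frame
reference-to-band pixel distance and its first difference (delta) feed
the meal caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.restoration import rolling_ball

from .errors import AmbiguousFeature, MissingFeature, ParameterError

__all__ = [
    "CapillaryROI",
    "MeniscusTrace",
    "preprocess_frame",
    "locate_bands",
    "extract_trace",
]


@dataclass(frozen=True)
class CapillaryROI:
    """Half-open column span of one capillary; 0-based, row-major frames."""

    capillary_id: int
    col_start: int
    col_stop: int
    row_start: int = 0
    row_stop: int | None = None

    def cols(self) -> slice:
        return slice(self.col_start, self.col_stop)

    def rows(self) -> slice:
        return slice(self.row_start, self.row_stop)


@dataclass
class MeniscusTrace:
    """Per-capillary reference-to-band distance and its per-frame change.

    ``delta[t] = distance[t] - distance[t-1]`` with ``delta[0] = 0``;
    the sign convention makes consumption increase distance, so feeding
    shows up as positive delta spikes.  ``flagged`` marks dropout frames
    where a feature was missing and the last distance was carried
    forward (delta forced to 0 there).
    """

    capillary_id: int
    distance_px: np.ndarray
    delta_px: np.ndarray
    minutes: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.distance_px)
        if not (len(self.delta_px) == len(self.minutes) == len(self.flagged) == n):
            raise ParameterError("trace arrays must have equal length")
        if np.any(np.diff(self.minutes) <= 0):
            raise ParameterError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distance_px)


def preprocess_frame(frame: np.ndarray, rolling_ball_radius: int = 5,
                     threshold: float = 60.0,
                     return_residual: bool = False):
    """Background-subtract (rolling ball, no smoothing) then binarize.

    Returns a boolean image (optionally together with the
    background-subtracted residual, used for sub-pixel centroid
    weighting).  A threshold above the residual maximum yields an
    all-background image, which downstream feature location flags as a
    dropout frame rather than an error.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ParameterError("preprocess_frame expects a non-empty 2-D image")
    background = rolling_ball(frame, radius=rolling_ball_radius)
    residual = frame.astype(float) - background.astype(float)
    binary = residual > threshold
    if return_residual:
        return binary, residual
    return binary


def locate_bands(binary_roi: np.ndarray, prev_ref_row: float | None = None,
                 min_area_px: int = 4,
                 weights: np.ndarray | None = None) -> tuple[float, float]:
    """Centroid rows of the reference mark and dye band in a binary ROI.

    ``weights`` (e.g. the background-subtracted intensities) gives
    sub-pixel centroids; without it the binary-mask centroid is used,
    which quantizes slow drift into half-pixel steps.  The reference
    mark is the feature nearest its position in the previous frame (it
    is static); the mobile feature is the band.  On the first frame,
    the mark is the upper feature — capillaries are loaded with the
    band below the mark, and consumption only moves it further down.
    """
    binary_roi = np.asarray(binary_roi, dtype=bool)
    labels = measure.label(binary_roi, connectivity=2)
    feats = [p for p in measure.regionprops(labels) if p.area >= min_area_px]
    if len(feats) < 2:
        raise MissingFeature(f"found {len(feats)} feature(s), expected 2")
    if len(feats) > 2:
        raise AmbiguousFeature(f"found {len(feats)} features after size filtering")

    def centroid_row(p) -> float:
        if weights is None:
            return float(p.centroid[0])
        # grow the support by one row each way so anti-aliased edge
        # intensity below threshold still contributes to the centroid
        rmin = max(0, p.bbox[0] - 1)
        rmax = min(binary_roi.shape[0], p.bbox[2] + 1)
        sub = np.clip(weights[rmin:rmax, p.bbox[1]:p.bbox[3]], 0.0, None)
        profile = sub.sum(axis=1)
        if profile.sum() <= 0:
            return float(p.centroid[0])
        return float(np.average(np.arange(rmin, rmax), weights=profile))

    rows = sorted(centroid_row(p) for p in feats)
    if prev_ref_row is None:
        return rows[0], rows[1]
    if abs(rows[0] - prev_ref_row) <= abs(rows[1] - prev_ref_row):
        return rows[0], rows[1]
    return rows[1], rows[0]


def extract_trace(stack: np.ndarray, rois: list[CapillaryROI],
                  threshold: float = 60.0, rolling_ball_radius: int = 5,
                  min_area_px: int = 4,
                  minutes: np.ndarray | None = None) -> list[MeniscusTrace]:
    """Per-capillary meniscus traces from an image stack.

    ``distance[t] = band_row[t] - ref_row[t]`` (band sits below the mark
    and consumption moves it down, so distance grows with intake).
    Frames where either feature cannot be located carry the last
    distance forward with delta 0 and are flagged, never aborting the
    extraction.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ParameterError("extract_trace expects a stack of >= 2 frames")
    n_frames = stack.shape[0]
    if minutes is None:
        minutes = np.arange(n_frames, dtype=float)

    traces = []
    for roi in rois:
        distance = np.zeros(n_frames)
        flagged = np.zeros(n_frames, dtype=bool)
        prev_ref: float | None = None
        last_distance = np.nan
        for t in range(n_frames):
            sub, residual = preprocess_frame(stack[t][roi.rows(), roi.cols()],
                                             rolling_ball_radius, threshold,
                                             return_residual=True)
            try:
                ref_row, band_row = locate_bands(sub, prev_ref, min_area_px,
                                                 weights=residual)
            except (MissingFeature, AmbiguousFeature):
                flagged[t] = True
                distance[t] = last_distance if np.isfinite(last_distance) else 0.0
                continue
            prev_ref = ref_row
            distance[t] = band_row - ref_row
            last_distance = distance[t]
        if np.all(flagged):
            distance[:] = 0.0
        else:
            first_good = int(np.flatnonzero(~flagged)[0])
            distance[:first_good] = distance[first_good]
        delta = np.zeros(n_frames)
        delta[1:] = np.diff(distance)
        delta[flagged] = 0.0
        traces.append(MeniscusTrace(roi.capillary_id, distance, delta,
                                    np.asarray(minutes, dtype=float), flagged))
    return traces
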