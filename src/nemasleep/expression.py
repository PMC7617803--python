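"""Fluorescent-reporter expression quantification.

Daily snapshots of a red-fluorescent reporter (e.g. HSP-12.6::mKate2) are
cropped to one-worm ROIs. Within each ROI, Otsu's method separates the
worm signal from background and the reporter level is the mean intensity
of the pixels above the threshold. Per-worm time courses are expressed as
dF/F relative to day 0, and group comparisons use the per-worm mean over
the last four recorded days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .stats import RankSumResult, wilcoxon_rank_sum

__all__ = [
    "ReporterMeasurement",
    "quantify_reporter",
    "ReporterSeries",
    "reporter_series",
    "compare_last4",
]


@dataclass(frozen=True)
class ReporterMeasurement:
    """Otsu-thresholded reporter readout for one ROI."""

    mean_above_threshold: float
    threshold: float
    n_pixels_above: int
    flagged: bool  # True when the ROI is not convincingly bimodal


def _between_class_variance(pixels: np.ndarray, threshold: float) -> float:
    above = pixels > threshold
    w1 = above.mean()
    w0 = 1.0 - w1
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = pixels[~above].mean()
    mu1 = pixels[above].mean()
    return float(w0 * w1 * (mu1 - mu0) ** 2)


def quantify_reporter(roi_frame, variance_floor: float = 25.0) -> ReporterMeasurement:
    """Mean intensity of the pixels strictly above the ROI's Otsu threshold.

    The flag is raised when the between-class variance at the chosen
    threshold falls below variance_floor (intensity^2 units): a worm-free
    or out-of-focus ROI separates its histogram by only a few intensity
    levels, indistinguishable from noise, and the threshold is then
    unreliable (a value is still returned). The default floor corresponds
    to a class separation of about 5 intensity levels at balanced class
    weights.
    """
    roi = np.asarray(roi_frame, dtype=float)
    if roi.ndim != 2:
        raise ValueError("roi_frame must be a 2-D image")
    pixels = roi.ravel()
    if np.ptp(pixels) == 0:
        warnings.warn("constant ROI; reporter threshold is undefined")
        return ReporterMeasurement(float(pixels[0]), float(pixels[0]), 0, True)
    thr = float(threshold_otsu(roi))
    above = pixels > thr
    sep = _between_class_variance(pixels, thr)
    flagged = sep < variance_floor
    if flagged:
        warnings.warn(f"ROI separability {sep:.3f} below floor {variance_floor}")
    mean_above = float(pixels[above].mean()) if above.any() else float("nan")
    return ReporterMeasurement(mean_above, thr, int(above.sum()), flagged)


@dataclass
class ReporterSeries:
    """Per-worm reporter time course relative to day 0.

    delta_f_over_f is a worms x days array with (F_d - F_0) / F_0;
    last4_mean is each worm's mean raw intensity over the final four
    recorded days. Worms with non-positive day-0 fluorescence are
    excluded (their dF/F is undefined).
    """

    days: np.ndarray
    worm_ids: list
    fluorescence: np.ndarray
    delta_f_over_f: np.ndarray
    last4_mean: np.ndarray
    excluded_worms: list


def reporter_series(per_day_values, days=None) -> ReporterSeries:
    """Build a dF/F reporter series from per-worm, per-day intensities.

    Parameters
    ----------
    per_day_values : DataFrame or 2-D array
        Rows are worms, columns are days (a DataFrame's columns are taken
        as the day numbers). Day 0 must be present.
    days : sequence of int, optional
        Day labels for an array input.
    """
    if isinstance(per_day_values, pd.DataFrame):
        df = per_day_values.copy()
        df.columns = [int(c) for c in df.columns]
    else:
        arr = np.asarray(per_day_values, dtype=float)
        if days is None:
            days = np.arange(arr.shape[1])
        df = pd.DataFrame(arr, columns=[int(d) for d in days])
    df = df[sorted(df.columns)]
    if 0 not in df.columns:
        raise ValueError("day 0 must be present")
    f0 = df[0].to_numpy(dtype=float)
    keep = f0 > 0
    excluded = list(df.index[~keep])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} worm(s) with F(day 0) <= 0")
    df = df.loc[keep]
    f0 = f0[keep]
    values = df.to_numpy(dtype=float)
    dff = (values - f0[:, None]) / f0[:, None]
    last4 = values[:, -min(4, values.shape[1]):].mean(axis=1)
    return ReporterSeries(
        days=np.asarray(sorted(df.columns), dtype=int),
        worm_ids=list(df.index),
        fluorescence=values,
        delta_f_over_f=dff,
        last4_mean=last4,
        excluded_worms=excluded,
    )


def compare_last4(series_a: ReporterSeries, series_b: ReporterSeries) -> RankSumResult:
    """Wilcoxon rank-sum on per-worm last-4-day mean intensities."""
    return wilcoxon_rank_sum(series_a.last4_mean, series_b.last4_mean)
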