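"""Calcium-transient detection and event-triggered averaging.

Transients in the ratiometric neuron trace are found on a heavily
smoothed copy of the trace (Savitzky-Golay, 120-sample window) as local
maxima with topographic prominence of at least 0.02. Heavy smoothing
shifts peaks rightward, so each detected position is corrected to the
argmax of a lightly smoothed copy (20-sample window) within an interval
of +/- (half-height peak width + 25 samples) around the raw position.

Event-triggered ensembles cut windows from 15 minutes before to 25
minutes after each event (sleep-bout onset or transient peak), average
within each animal first — each worm is one n — and then across animals.
Interval statistics compare per-animal means over a chosen time window
between two groups with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .stats import RankSumResult, wilcoxon_rank_sum

__all__ = [
    "PeakSet",
    "AlignedEnsemble",
    "IntervalStat",
    "smooth_trace",
    "detect_peaks",
    "correct_peak_positions",
    "align_to_events",
    "interval_stat",
]

HEAVY_SG_WINDOW = 120  # frames; keeps only the large transients
LIGHT_SG_WINDOW = 20   # frames; preserves peak timing
MIN_PROMINENCE = 0.02  # ratio units
SEARCH_PAD = 25        # extra frames each side of the correction interval
ALIGN_WINDOW_S = (-900.0, 1500.0)  # 15 min before to 25 min after the event


def smooth_trace(trace, window: int, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with the window clipped to the trace length."""
    trace = np.asarray(trace, dtype=float)
    window = min(window, len(trace))
    if window <= polyorder:
        return trace.copy()
    return savgol_filter(trace, window, polyorder)


@dataclass
class PeakSet:
    """Detected calcium-activation transients for one animal."""

    raw_index: np.ndarray
    prominence: np.ndarray
    width_at_half: np.ndarray       # frames, at 50% of prominence height
    corrected_index: np.ndarray | None
    frequency_per_hour: float
    heavy_trace: np.ndarray

    def __len__(self) -> int:
        return len(self.raw_index)


def detect_peaks(ratio_trace, frame_interval: float,
                 sg_window_heavy: int = HEAVY_SG_WINDOW,
                 min_prominence: float = MIN_PROMINENCE,
                 sg_polyorder: int = 3) -> PeakSet:
    """Find transients on the heavily smoothed trace.

    Local maxima with topographic prominence >= min_prominence are kept;
    the half-prominence width of each is recorded for the later position
    correction. The per-animal frequency is peaks per hour of recording.
    """
    ratio_trace = np.asarray(ratio_trace, dtype=float)
    if len(ratio_trace) <= sg_window_heavy:
        raise ValueError("trace must be longer than the heavy smoothing window")
    heavy = smooth_trace(ratio_trace, sg_window_heavy, sg_polyorder)
    idx, props = find_peaks(heavy, prominence=min_prominence)
    widths = (peak_widths(heavy, idx, rel_height=0.5)[0]
              if idx.size else np.empty(0))
    hours = len(ratio_trace) * frame_interval / 3600.0
    return PeakSet(raw_index=idx, prominence=props.get("prominences", np.empty(0)),
                   width_at_half=widths, corrected_index=None,
                   frequency_per_hour=len(idx) / hours if hours > 0 else 0.0,
                   heavy_trace=heavy)


def correct_peak_positions(peaks: PeakSet, lightly_smoothed_trace) -> PeakSet:
    """Undo the rightward peak shift introduced by heavy smoothing.

    For each raw peak, the search interval extends left and right of the
    raw position by (half-height width + 25) frames; the corrected
    position is the argmax of the lightly smoothed trace inside the
    interval (earliest frame on ties). Intervals are clipped to the trace
    bounds; a peak whose interval is empty is dropped with a warning.
    """
    light = np.asarray(lightly_smoothed_trace, dtype=float)
    if len(light) != len(peaks.heavy_trace):
        raise ValueError("light trace must match the detection trace length")
    corrected, keep = [], []
    for i, (raw, width) in enumerate(zip(peaks.raw_index, peaks.width_at_half)):
        half = int(round(width)) + SEARCH_PAD
        lo = max(0, int(raw) - half)
        hi = min(len(light), int(raw) + half + 1)
        if hi <= lo:
            warnings.warn(f"peak at frame {raw}: empty search interval, dropped")
            continue
        corrected.append(lo + int(np.argmax(light[lo:hi])))
        keep.append(i)
    keep = np.asarray(keep, dtype=int)
    return replace(peaks,
                   raw_index=peaks.raw_index[keep],
                   prominence=peaks.prominence[keep],
                   width_at_half=peaks.width_at_half[keep],
                   corrected_index=np.asarray(corrected, dtype=int))


@dataclass
class AlignedEnsemble:
    """Event-relative signal and sleep-fraction ensemble.

    Rows of the per-animal arrays are one animal's mean over its own
    events; the grand mean and s.e.m. weight every animal equally.
    """

    rel_time: np.ndarray
    per_animal_signal: np.ndarray
    per_animal_sleep: np.ndarray
    signal_mean: np.ndarray
    signal_sem: np.ndarray
    sleep_mean: np.ndarray
    sleep_sem: np.ndarray
    event_kind: str
    animal_ids: list

    @property
    def n_animals(self) -> int:
        return self.per_animal_signal.shape[0]


def _nan_sem(rows: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(rows, axis=0, ddof=1)
        n = np.sum(~np.isnan(rows), axis=0)
    return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)


def align_to_events(signal_by_animal, sleep_by_animal, events_by_animal,
                    frame_interval: float,
                    window_s: tuple[float, float] = ALIGN_WINDOW_S,
                    event_kind: str = "sleep_onset",
                    signal_sg_window: int = LIGHT_SG_WINDOW,
                    animal_ids=None) -> AlignedEnsemble:
    """Build an event-triggered ensemble across animals.

    Parameters are parallel sequences over animals: the ratiometric
    signal trace, the binary sleep labels and the event frame indices of
    each animal. The signal is lightly Savitzky-Golay smoothed before
    cutting; sleep labels are used as-is. Windows truncated by the
    recording edges contribute NaNs at the missing positions, which are
    excluded from the means. Animals with zero events are excluded.
    """
    signal_by_animal = [np.asarray(s, dtype=float) for s in signal_by_animal]
    sleep_by_animal = [np.asarray(s, dtype=float) for s in sleep_by_animal]
    if not (len(signal_by_animal) == len(sleep_by_animal) == len(events_by_animal)):
        raise ValueError("per-animal sequences must have equal length")
    if animal_ids is None:
        animal_ids = list(range(len(signal_by_animal)))
    rel_frames = np.arange(int(round(window_s[0] / frame_interval)),
                           int(round(window_s[1] / frame_interval)) + 1)
    rel_time = rel_frames * frame_interval

    sig_rows, sleep_rows, kept = [], [], []
    for aid, sig, slp, events in zip(animal_ids, signal_by_animal,
                                     sleep_by_animal, events_by_animal):
        events = np.asarray(events, dtype=int)
        if events.size == 0:
            continue
        if len(sig) != len(slp):
            raise ValueError(f"animal {aid}: signal and sleep lengths differ")
        smooth = smooth_trace(sig, signal_sg_window)
        sig_cuts = np.full((events.size, rel_frames.size), np.nan)
        sleep_cuts = np.full((events.size, rel_frames.size), np.nan)
        for k, e in enumerate(events):
            pos = e + rel_frames
            ok = (pos >= 0) & (pos < len(sig))
            sig_cuts[k, ok] = smooth[pos[ok]]
            sleep_cuts[k, ok] = slp[pos[ok]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sig_rows.append(np.nanmean(sig_cuts, axis=0))
            sleep_rows.append(np.nanmean(sleep_cuts, axis=0))
        kept.append(aid)
    if not sig_rows:
        raise ValueError("no animal contributed any event")
    per_sig = np.vstack(sig_rows)
    per_sleep = np.vstack(sleep_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sig_mean = np.nanmean(per_sig, axis=0)
        sleep_mean = np.nanmean(per_sleep, axis=0)
    return AlignedEnsemble(rel_time=rel_time, per_animal_signal=per_sig,
                           per_animal_sleep=per_sleep,
                           signal_mean=sig_mean, signal_sem=_nan_sem(per_sig),
                           sleep_mean=sleep_mean, sleep_sem=_nan_sem(per_sleep),
                           event_kind=event_kind, animal_ids=kept)


@dataclass(frozen=True)
class IntervalStat:
    """Group comparison of per-animal means over an event-relative interval."""

    interval: tuple[float, float]
    quantity: str
    per_animal_means_a: np.ndarray
    per_animal_means_b: np.ndarray
    statistic: float
    p_value: float


def interval_stat(ensemble_a: AlignedEnsemble, ensemble_b: AlignedEnsemble,
                  interval: tuple[float, float],
                  quantity: str = "signal") -> IntervalStat:
    """Wilcoxon rank-sum between two groups over a relative-time interval.

    Each animal contributes its mean signal (or sleep fraction) over
    interval = (start_s, end_s), inclusive on both ends, e.g. (-600,
    -300) for the 10-5 min pre-onset baseline or (-60, 60) around the
    transient peak.
    """
    if quantity not in ("signal", "sleep"):
        raise ValueError("quantity must be 'signal' or 'sleep'")

    def per_animal(ens: AlignedEnsemble) -> np.ndarray:
        lo, hi = interval
        if lo < ens.rel_time[0] or hi > ens.rel_time[-1]:
            raise ValueError("interval lies outside the ensemble grid")
        sel = (ens.rel_time >= lo) & (ens.rel_time <= hi)
        rows = ens.per_animal_signal if quantity == "signal" else ens.per_animal_sleep
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(rows[:, sel], axis=1)

    a = per_animal(ensemble_a)
    b = per_animal(ensemble_b)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 animals with data")
    res: RankSumResult = wilcoxon_rank_sum(a, b)
    return IntervalStat(interval=interval, quantity=quantity,
                        per_animal_means_a=a, per_animal_means_b=b,
                        statistic=res.statistic, p_value=res.p_value)
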