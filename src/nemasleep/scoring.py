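"""Behavioral sleep scoring from motion-quiescence traces.

Sleep in arrested L1 larvae is operationally defined as movement
quiescence lasting at least two minutes. The scoring pipeline is:

1. linearly interpolate missing speed values;
2. smooth with a Savitzky-Golay filter (window 40 frames);
3. min-max normalize the smoothed speed to [0, 1] per worm;
4. threshold: normalized speed below the threshold (0.1-0.3, default
   0.2) is quiescence (0), at or above is movement (1);
5. maximal quiescent runs of at least the minimum duration become sleep
   bouts;
6. iterative twitch removal: brief movements inside sleep split a bout
   into fragments; for each bout the two minutes flanking its start and
   end are examined, and if any quiescent frame lies in the flank and the
   flank's mean smoothed speed stays below the threshold, the bout is
   extended across it. The pass repeats until no bout boundary moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .motion import MotionTrace

__all__ = [
    "ScoringConfig",
    "SleepScore",
    "preprocess_speed",
    "threshold_quiescence",
    "score_bouts",
    "refine_bouts",
    "score_sleep",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the sleep-scoring procedure.

    sg_window
        Savitzky-Golay smoothing window in frames (40 frames = 200 s at
        0.2 FPS).
    sg_polyorder
        Polynomial order of the filter.
    speed_threshold
        Quiescence threshold on the normalized [0, 1] speed scale; the
        empirically useful range is 0.1-0.3.
    min_sleep_duration
        Minimum quiescence duration in seconds to count as sleep (the
        two-minute rule).
    flank_window
        Duration in seconds of the window before a bout start / after a
        bout end examined during twitch removal.
    max_refine_iters
        Safety cap on twitch-removal iterations.
    """

    sg_window: int = 40
    sg_polyorder: int = 3
    speed_threshold: float = 0.2
    min_sleep_duration: float = 120.0
    flank_window: float = 120.0
    max_refine_iters: int = 100

    def __post_init__(self) -> None:
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.min_sleep_duration <= 0:
            raise ValueError("min_sleep_duration must be positive")
        if self.flank_window <= 0:
            raise ValueError("flank_window must be positive")
        if self.max_refine_iters < 1:
            raise ValueError("max_refine_iters must be at least 1")


@dataclass
class SleepScore:
    """Scored sleep for one worm.

    quiescence uses the 0 = quiescent / 1 = moving convention; sleep is
    the per-frame boolean bout membership after twitch removal; bouts are
    half-open (start_frame, end_frame) pairs.
    """

    quiescence: np.ndarray
    sleep: np.ndarray
    bouts: list[tuple[int, int]]
    fraction_sleeping: float
    bout_frequency: float
    mean_bout_length: float
    frame_interval: float
    n_refine_iters: int = 0
    converged: bool = True
    config: ScoringConfig = field(default_factory=ScoringConfig)


def preprocess_speed(trace: MotionTrace, cfg: ScoringConfig = ScoringConfig()) -> MotionTrace:
    """Interpolate, smooth and normalize a raw speed trace.

    Missing values are linearly interpolated (edge gaps take the nearest
    observed value), the trace is Savitzky-Golay smoothed, and the result
    is min-max normalized to [0, 1] over the whole recording. A
    zero-variance trace normalizes to all zeros (an immobile worm) with a
    warning.
    """
    speed = np.asarray(trace.speed, dtype=float).copy()
    missing = trace.missing | ~np.isfinite(speed)
    ok = ~missing
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing speed values")
    idx = np.arange(len(speed))
    speed[missing] = np.interp(idx[missing], idx[ok], speed[ok])
    window = min(cfg.sg_window, len(speed))
    if window > cfg.sg_polyorder:
        speed = savgol_filter(speed, window, cfg.sg_polyorder)
    # speed is physically non-negative; the polynomial filter undershoots at
    # sharp wake->sleep transitions, and letting that artifact set the
    # normalization floor would lift the quiescent level off zero
    speed = np.clip(speed, 0.0, None)
    lo, hi = speed.min(), speed.max()
    # relative tolerance: filtering a constant trace leaves ~1e-13 edge
    # noise that must not be blown up to full scale by the normalization
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):
        warnings.warn("constant speed trace; normalizing to all-zero (immobile worm)")
        speed = np.zeros_like(speed)
    else:
        speed = (speed - lo) / (hi - lo)
    return MotionTrace(time_s=trace.time_s, speed=speed,
                       missing=np.zeros(len(speed), dtype=bool),
                       frame_interval=trace.frame_interval)


def threshold_quiescence(speed, threshold: float) -> np.ndarray:
    """Binary quiescence labels: 0 below the threshold, 1 at or above.

    The boundary convention follows from quiescence being defined as speed
    *below* the threshold, so a frame exactly at the threshold is moving.
    """
    if not 0 < threshold < 1:
        warnings.warn(f"speed threshold {threshold} lies outside (0, 1)")
    speed = np.asarray(speed, dtype=float)
    return (speed >= threshold).astype(np.int8)


def _runs_of(values: np.ndarray, target: int) -> list[tuple[int, int]]:
    """Half-open (start, end) indices of maximal runs equal to target."""
    hit = np.asarray(values) == target
    if not hit.any():
        return []
    padded = np.concatenate([[False], hit, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def score_bouts(quiescence, frame_interval: float,
                cfg: ScoringConfig = ScoringConfig()) -> list[tuple[int, int]]:
    """Sleep bouts: maximal quiescent runs of at least the minimum duration.

    Returns half-open (start_frame, end_frame) pairs. Shorter quiescent
    runs, like movement, count as wakefulness.
    """
    quiescence = np.asarray(quiescence)
    min_frames = int(np.ceil(cfg.min_sleep_duration / frame_interval))
    return [(s, e) for s, e in _runs_of(quiescence, 0) if e - s >= min_frames]


def _merge(bouts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(bouts):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def refine_bouts(bouts, smoothed_speed, quiescence, cfg: ScoringConfig = ScoringConfig(),
                 frame_interval: float = 5.0) -> SleepScore:
    """Iterative twitch removal and final sleep summary.

    A twitch briefly crosses the speed threshold inside a sleep bout and
    splits it. For each bout, the flank window before its start (and after
    its end) is inspected: if at least one quiescent frame lies in the
    window and the mean smoothed speed over the window is below the
    threshold, the bout is extended across the whole window. Extended
    bouts that touch merge, and the procedure repeats until no boundary
    changes (or the iteration cap is hit, which raises a warning).

    Bouts at the recording edges are checked on the in-recording side
    only. Refinement only ever extends or merges bouts.
    """
    smoothed_speed = np.asarray(smoothed_speed, dtype=float)
    quiescence = np.asarray(quiescence)
    n = len(smoothed_speed)
    if len(quiescence) != n:
        raise ValueError("smoothed_speed and quiescence must have equal length")
    flank = max(1, int(round(cfg.flank_window / frame_interval)))
    current = _merge([(int(s), int(e)) for s, e in bouts])
    converged = False
    iters = 0
    for iters in range(1, cfg.max_refine_iters + 1):
        changed = False
        grown: list[tuple[int, int]] = []
        for s, e in current:
            if s > 0:
                lo = max(0, s - flank)
                win = slice(lo, s)
                if (quiescence[win] == 0).any() and smoothed_speed[win].mean() < cfg.speed_threshold:
                    s = lo
                    changed = True
            if e < n:
                hi = min(n, e + flank)
                win = slice(e, hi)
                if win.stop > win.start and (quiescence[win] == 0).any() \
                        and smoothed_speed[win].mean() < cfg.speed_threshold:
                    e = hi
                    changed = True
            grown.append((s, e))
        current = _merge(grown)
        if not changed:
            converged = True
            break
    if not converged:
        warnings.warn(f"twitch removal did not converge in {cfg.max_refine_iters} iterations")

    sleep = np.zeros(n, dtype=bool)
    for s, e in current:
        sleep[s:e] = True
    hours = n * frame_interval / 3600.0
    lengths = [(e - s) * frame_interval for s, e in current]
    return SleepScore(
        quiescence=quiescence,
        sleep=sleep,
        bouts=current,
        fraction_sleeping=float(sleep.mean()) if n else 0.0,
        bout_frequency=len(current) / hours if hours > 0 else 0.0,
        mean_bout_length=float(np.mean(lengths)) if lengths else 0.0,
        frame_interval=frame_interval,
        n_refine_iters=iters,
        converged=converged,
        config=cfg,
    )


def score_sleep(trace: MotionTrace, cfg: ScoringConfig = ScoringConfig(),
                refine: bool = True) -> SleepScore:
    """Run the full scoring pipeline on a raw motion trace."""
    pre = preprocess_speed(trace, cfg)
    quiescence = threshold_quiescence(pre.speed, cfg.speed_threshold)
    bouts = score_bouts(quiescence, trace.frame_interval, cfg)
    if refine:
        return refine_bouts(bouts, pre.speed, quiescence, cfg, trace.frame_interval)
    n = len(quiescence)
    sleep = np.zeros(n, dtype=bool)
    for s, e in bouts:
        sleep[s:e] = True
    hours = n * trace.frame_interval / 3600.0
    lengths = [(e - s) * trace.frame_interval for s, e in bouts]
    return SleepScore(
        quiescence=quiescence, sleep=sleep, bouts=bouts,
        fraction_sleeping=float(sleep.mean()) if n else 0.0,
        bout_frequency=len(bouts) / hours if hours > 0 else 0.0,
        mean_bout_length=float(np.mean(lengths)) if lengths else 0.0,
        frame_interval=trace.frame_interval, n_refine_iters=0,
        converged=True, config=cfg,
    )
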