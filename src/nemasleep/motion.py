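"""Per-frame motion quantification.

Two modalities convert raw imaging into a worm-speed trace:

* frame subtraction on label-free (DIC) stacks — the mean absolute
  per-pixel intensity change between consecutive frames, an arbitrary-unit
  proxy for whole-body movement;
* centroid tracking on fluorescence stacks — the Euclidean displacement of
  a tracked head-neuron centroid converted to micrometres per second.

Both assign the motion value to the later frame of each pair; the first
frame of a recording therefore carries a missing value, as does any frame
where neuron detection failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "MotionTrace", "frame_subtraction_motion", "centroid_speed"]


@dataclass
class ImageStack:
    """A T x H x W grayscale time-lapse stack.

    frame_interval is seconds per frame; pixel_size is micrometres per
    pixel (after binning). Intensities are kept as floating point
    internally regardless of acquisition bit depth.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MotionTrace:
    """Per-frame worm speed with timing metadata.

    speed is NaN wherever missing is True. Units are arbitrary for
    frame-subtraction traces and micrometres/second for centroid tracking.
    """

    time_s: np.ndarray
    speed: np.ndarray
    missing: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.time_s) == len(self.speed) == len(self.missing)):
            raise ValueError("time_s, speed and missing must have equal length")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        ok = ~self.missing
        if np.any(self.speed[ok] < 0):
            raise ValueError("speed must be non-negative where not missing")

    def __len__(self) -> int:
        return len(self.speed)


def frame_subtraction_motion(stack: ImageStack) -> MotionTrace:
    """Motion trace from consecutive-frame subtraction.

    For every frame t >= 1 the motion value is the mean over pixels of
    |I_t - I_{t-1}|; higher values indicate more movement. Frame 0 has no
    predecessor and is flagged missing. Absolute differences are taken
    before averaging: signed differences would cancel and flatten the
    trace for moving worms.
    """
    if stack.n_frames < 2:
        raise ValueError("frame subtraction needs at least 2 frames")
    frames = stack.frames.astype(np.float64, copy=False)
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    speed = np.concatenate([[np.nan], diffs])
    missing = np.zeros(stack.n_frames, dtype=bool)
    missing[0] = True
    time_s = np.arange(stack.n_frames) * stack.frame_interval
    return MotionTrace(time_s=time_s, speed=speed, missing=missing,
                       frame_interval=stack.frame_interval)


def centroid_speed(centroids, pixel_size: float, frame_interval: float) -> MotionTrace:
    """Motion trace from a tracked neuron-centroid path.

    centroids is a (T, 2) array of (row, col) pixel positions; rows
    containing NaN mark frames where neuron detection failed. The speed at
    frame t is the Euclidean displacement from frame t-1 scaled by
    pixel_size (um/px) and divided by frame_interval (s), i.e. um/s.
    Frame 0 and frames adjacent to a failed detection are missing.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 2:
        raise ValueError("centroids must be a (T, 2) array of (row, col)")
    if centroids.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("pixel_size and frame_interval must be positive")
    bad = np.isnan(centroids).any(axis=1)
    if bad.all():
        raise ValueError("all centroids are missing")
    step = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    speed = np.concatenate([[np.nan], step * pixel_size / frame_interval])
    missing = np.zeros(len(centroids), dtype=bool)
    missing[0] = True
    # a failed detection invalidates both displacements that touch it
    missing |= bad
    missing[1:] |= bad[:-1]
    speed[missing] = np.nan
    time_s = np.arange(len(centroids)) * frame_interval
    return MotionTrace(time_s=time_s, speed=speed, missing=missing,
                       frame_interval=frame_interval)
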