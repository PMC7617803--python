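"""Ground-truth-annotated synthetic data generators.

Every analysis stage in this package can be exercised without microscopy
data: the generators below emulate the statistical structure of the raw
inputs — worm speed traces alternating between wake and sleep with brief
intra-sleep twitches, two-channel fluorescence stacks containing a single
drifting neuron soma with calcium transients on the activity channel,
single-worm reporter snapshots, and daily alive/dead survival counts —
and return the ground truth alongside, so recovery can be measured.

All generators are pure functions of their parameters (including the
seed): the same parameters give bitwise-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .motion import ImageStack, MotionTrace
from .survival import SurvivalCurve

__all__ = [
    "LocomotionParams",
    "CalciumSceneParams",
    "GroundTruth",
    "gen_locomotion_trace",
    "gen_calcium_stack",
    "gen_survival_counts",
    "gen_reporter_image",
    "transient_kernel",
    "transient_peak_offset",
]


@dataclass(frozen=True)
class LocomotionParams:
    """Parameters of the wake/sleep locomotion model.

    The worm alternates between wake and sleep states with exponentially
    distributed dwell times. Speed is the state mean plus Gaussian noise
    (clipped at zero); during sleep, single-frame twitch spikes occur as
    a Poisson process. Defaults reflect L1-arrest behavioral imaging:
    0.2 frames/s over a 10 h recording, and a missing-frame rate of
    0.03%.
    """

    frame_interval: float = 5.0      # s/frame (0.2 FPS)
    duration: float = 36000.0        # s
    wake_speed_mean: float = 1.0     # speed a.u.
    wake_speed_sd: float = 0.1
    sleep_speed_mean: float = 0.05
    mean_wake_dwell: float = 2100.0  # s
    mean_sleep_dwell: float = 900.0  # s
    twitch_rate: float = 0.001       # events/s during sleep
    twitch_amplitude: float = 2.5    # speed a.u., added for one frame
    missing_frame_prob: float = 0.0003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        if self.mean_wake_dwell <= 0 or self.mean_sleep_dwell <= 0:
            raise ValueError("dwell-time means must be positive")
        if not self.sleep_speed_mean < self.wake_speed_mean:
            raise ValueError("sleep_speed_mean must be below wake_speed_mean")
        if not 0 <= self.missing_frame_prob < 1:
            raise ValueError("missing_frame_prob must lie in [0, 1)")
        if self.twitch_rate < 0 or self.twitch_amplitude < 0:
            raise ValueError("twitch parameters must be non-negative")


@dataclass(frozen=True)
class CalciumSceneParams:
    """Parameters of the two-channel neuron-imaging scene.

    Both channels contain one isotropic Gaussian blob (the soma) on a
    reflected Gaussian random walk. The reference channel (the
    calcium-insensitive fluorophore) has constant amplitude; the activity
    channel adds double-exponential calcium transients, normalized so
    transient_amplitude is the peak amplitude over baseline. The activity
    blob is offset from the reference by per-frame Gaussian jitter,
    mimicking worm movement between the two channel exposures.
    """

    frame_count: int = 500
    height: int = 128
    width: int = 128
    blob_sigma: float = 3.0          # px
    blob_drift_sd: float = 0.5       # px/frame
    reference_amplitude: float = 1000.0
    activity_baseline: float = 400.0
    transient_times: tuple[int, ...] = ()
    transient_amplitude: float = 600.0
    transient_rise: float = 5.0      # frames
    transient_decay: float = 30.0    # frames
    channel_jitter_sd: float = 0.0   # px
    noise_sd: float = 20.0
    bit_depth: int = 16
    frame_interval: float = 5.88     # s/frame (~0.17 FPS)
    pixel_size: float = 0.4          # um/px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1 or self.height < 1 or self.width < 1:
            raise ValueError("frame_count, height and width must be positive")
        margin = 3 * self.blob_sigma
        if min(self.height, self.width) <= 2 * margin:
            raise ValueError("blob must fit inside the frame with margin >= 3 sigma")
        for name in ("reference_amplitude", "activity_baseline",
                     "transient_amplitude", "noise_sd", "channel_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        times = tuple(self.transient_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("transient_times must be strictly increasing")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.transient_rise <= 0 or self.transient_decay <= 0:
            raise ValueError("transient rise and decay must be positive")


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    true_bouts: list[tuple[float, float]] = field(default_factory=list)
    true_sleep_state: np.ndarray | None = None
    true_twitch_frames: np.ndarray | None = None
    true_transient_frames: np.ndarray | None = None
    true_centroids: np.ndarray | None = None
    true_ratio: np.ndarray | None = None


def gen_locomotion_trace(params: LocomotionParams) -> tuple[MotionTrace, GroundTruth]:
    """Simulate one worm's speed trace with annotated sleep bouts.

    Wake/sleep states alternate (starting awake) with exponential dwell
    times; each dwell is rounded to at least one frame. Twitches are
    single-frame speed spikes inside sleep; missing frames are flagged
    and carry NaN speed. The ground truth records the per-frame sleep
    state, the bout list in seconds and the twitch frames.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    n = int(round(params.duration / dt))
    state = np.zeros(n, dtype=bool)  # True = sleep
    t = 0
    asleep = False
    while t < n:
        mean = params.mean_sleep_dwell if asleep else params.mean_wake_dwell
        dwell = max(1, int(round(rng.exponential(mean) / dt)))
        state[t:t + dwell] = asleep
        t += dwell
        asleep = not asleep

    base = np.where(state, params.sleep_speed_mean, params.wake_speed_mean)
    speed = base + rng.normal(0.0, params.wake_speed_sd, n)
    speed = np.clip(speed, 0.0, None)

    p_twitch = params.twitch_rate * dt
    twitch = state & (rng.random(n) < p_twitch)
    speed[twitch] += params.twitch_amplitude

    missing = rng.random(n) < params.missing_frame_prob
    speed[missing] = np.nan

    bouts = [(s * dt, e * dt) for s, e in _bool_runs(state)]
    trace = MotionTrace(time_s=np.arange(n) * dt, speed=speed,
                        missing=missing, frame_interval=dt)
    truth = GroundTruth(true_bouts=bouts, true_sleep_state=state,
                        true_twitch_frames=np.flatnonzero(twitch))
    return trace, truth


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def transient_peak_offset(rise: float, decay: float) -> float:
    """Frames from transient onset to the kernel maximum (closed form)."""
    return rise * np.log((rise + decay) / rise)


def transient_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak double-exponential calcium transient kernel.

    k(t) = (1 - exp(-t/rise)) * exp(-t/decay) for t >= 0, scaled so its
    maximum is 1; zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, (1.0 - np.exp(-np.clip(t, 0, None) / rise))
                   * np.exp(-np.clip(t, 0, None) / decay), 0.0)
    t_peak = transient_peak_offset(rise, decay)
    peak = (1.0 - np.exp(-t_peak / rise)) * np.exp(-t_peak / decay)
    return raw / peak


def _reflect(value: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi]; one pass suffices for small steps
    span = hi - lo
    while value < lo or value > hi:
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
        if span <= 0:
            return lo
    return value


def gen_calcium_stack(params: CalciumSceneParams
                      ) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Simulate aligned reference- and activity-channel image stacks.

    Returns (reference, activity, truth). The true ratio is the activity
    blob's peak amplitude divided by the reference amplitude (identical
    blob shapes make the ratio of in-mask means equal the amplitude
    ratio in the noise-free, jitter-free case).
    """
    rng = np.random.default_rng(params.seed)
    T, H, W = params.frame_count, params.height, params.width
    margin = 3 * params.blob_sigma
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]

    # reflected Gaussian random walk, started at the frame center
    centroids = np.empty((T, 2))
    r, c = H / 2.0, W / 2.0
    for t in range(T):
        if t > 0:
            dr, dc = rng.normal(0.0, params.blob_drift_sd, 2)
            r = _reflect(r + dr, margin, H - 1 - margin)
            c = _reflect(c + dc, margin, W - 1 - margin)
        centroids[t] = (r, c)

    jitter = (rng.normal(0.0, params.channel_jitter_sd, (T, 2))
              if params.channel_jitter_sd > 0 else np.zeros((T, 2)))

    times = np.asarray(params.transient_times, dtype=float)
    frames_idx = np.arange(T, dtype=float)
    activity_amp = np.full(T, params.activity_baseline)
    for tk in times:
        activity_amp += params.transient_amplitude * transient_kernel(
            frames_idx - tk, params.transient_rise, params.transient_decay)

    two_sig2 = 2.0 * params.blob_sigma ** 2
    max_val = float(2 ** params.bit_depth - 1)

    def render(amp: float, center: np.ndarray) -> np.ndarray:
        blob = amp * np.exp(-((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / two_sig2)
        return blob

    ref = np.empty((T, H, W))
    act = np.empty((T, H, W))
    for t in range(T):
        ref[t] = render(params.reference_amplitude, centroids[t])
        act_center = np.clip(centroids[t] + jitter[t], 0, [H - 1, W - 1])
        act[t] = render(activity_amp[t], act_center)
    if params.noise_sd > 0:
        ref += rng.normal(0.0, params.noise_sd, ref.shape)
        act += rng.normal(0.0, params.noise_sd, act.shape)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    ref_q = np.clip(np.round(ref), 0, max_val).astype(dtype)
    act_q = np.clip(np.round(act), 0, max_val).astype(dtype)

    mk = dict(frame_interval=params.frame_interval, pixel_size=params.pixel_size,
              bit_depth=params.bit_depth)
    truth = GroundTruth(
        true_transient_frames=np.asarray(params.transient_times, dtype=int),
        true_centroids=centroids,
        true_ratio=activity_amp / params.reference_amplitude,
    )
    return (ImageStack(ref_q, channel="reference", **mk),
            ImageStack(act_q, channel="activity", **mk),
            truth)


def gen_survival_counts(hazard_per_day: float, n0: int, days: int,
                        seed: int = 0, group: str = "") -> SurvivalCurve:
    """Simulate daily alive/dead counts under a constant daily hazard.

    Deaths each day are binomial among the still-alive animals; alive +
    dead totals n0 on every day. Day 0 is the starting census (all
    alive).
    """
    if not 0 <= hazard_per_day <= 1:
        raise ValueError("hazard_per_day must lie in [0, 1]")
    if n0 < 1 or days < 1:
        raise ValueError("n0 and days must be positive")
    rng = np.random.default_rng(seed)
    alive = [n0]
    current = n0
    for _ in range(days):
        deaths = rng.binomial(current, hazard_per_day) if current > 0 else 0
        current -= deaths
        alive.append(current)
    alive_arr = np.asarray(alive)
    return SurvivalCurve(day=np.arange(days + 1), n_alive=alive_arr,
                         n_dead=n0 - alive_arr, group=group)


def gen_reporter_image(height: int = 120, width: int = 120,
                       worm_intensity: float = 200.0,
                       background: float = 20.0, noise_sd: float = 5.0,
                       bit_depth: int = 16, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a one-worm reporter snapshot (synthetic stand-in ROI).

    A worm-shaped bright region — a thick sinusoid path — over a noisy
    background. Returns (image, worm_mask); the mask marks the pixels
    whose true intensity is worm_intensity.
    """
    if worm_intensity <= background:
        raise ValueError("worm_intensity must exceed background")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), background, dtype=float)
    # parametric body: sinusoid across the ROI center, ~6% of ROI thick
    s = np.linspace(0.15, 0.85, 400)
    path_r = height * (0.5 + 0.12 * np.sin(2 * np.pi * 1.5 * s))
    path_c = width * s
    rr, cc = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    radius = max(2.0, 0.03 * min(height, width))
    for pr, pc in zip(path_r, path_c):
        mask |= (rr - pr) ** 2 + (cc - pc) ** 2 <= radius ** 2
    img[mask] = worm_intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    max_val = float(2 ** bit_depth - 1)
    img = np.clip(np.round(img), 0, max_val)
    if mask.sum() == 0:
        warnings.warn("degenerate worm mask")
    return img, mask
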