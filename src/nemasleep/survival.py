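"""Survival-curve smoothing and statistics for L1-arrest assays.

Arrested larvae kept in liquid culture are scored alive/dead once per
day. Curves are smoothed by adjacent averaging (a centered moving window
of 5 days), and genotypes are compared with Fisher's exact test on the
raw alive/dead counts at the day the shortest-living condition first
drops to 50% survival. A small dosing helper computes the effective bath
concentration when a drug drop diffuses into the agarose volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2

__all__ = [
    "SurvivalCurve",
    "smooth_survival",
    "fisher_at_median",
    "MedianSurvivalTest",
    "effective_concentration",
]


@dataclass
class SurvivalCurve:
    """Daily alive/dead counts for one condition.

    Counts are sampling aliquots, so fraction_alive is not forced to be
    monotone. smoothed_fraction is filled in by smooth_survival.
    """

    day: np.ndarray
    n_alive: np.ndarray
    n_dead: np.ndarray
    group: str = ""
    smoothed_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.n_alive = np.asarray(self.n_alive, dtype=int)
        self.n_dead = np.asarray(self.n_dead, dtype=int)
        if not (len(self.day) == len(self.n_alive) == len(self.n_dead)):
            raise ValueError("day, n_alive and n_dead must have equal length")
        if (self.n_alive < 0).any() or (self.n_dead < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def fraction_alive(self) -> np.ndarray:
        total = self.n_alive + self.n_dead
        return np.where(total > 0, self.n_alive / np.maximum(total, 1), np.nan)


def smooth_survival(curve: SurvivalCurve, window: int = 5) -> SurvivalCurve:
    """Adjacent-averaging smoothing of the alive fraction.

    Centered moving average over `window` days; at the curve edges the
    window is truncated to the available points rather than padded.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    frac = pd.Series(curve.fraction_alive)
    smoothed = frac.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return replace(curve, smoothed_fraction=smoothed)


@dataclass(frozen=True)
class MedianSurvivalTest:
    """Fisher's exact comparison at the 50%-survival day."""

    day: int
    reference_group: str
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (odds ratio, p)
    bonferroni: dict[tuple[str, str], float] | None = None


def fisher_at_median(curves: dict[str, SurvivalCurve], window: int = 5,
                     use_smoothed: bool = True,
                     bonferroni: bool = False) -> MedianSurvivalTest:
    """Pairwise Fisher's exact tests at the shortest-living group's median day.

    The median day is the first day on which the (smoothed, by default)
    alive fraction of the shortest-living group reaches <= 0.5. The 2x2
    alive/dead tables at that day are built from the *raw* counts.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 groups")
    crossing: dict[str, int] = {}
    for name, curve in curves.items():
        sm = smooth_survival(curve, window) if use_smoothed else curve
        frac = sm.smoothed_fraction if use_smoothed else curve.fraction_alive
        below = np.flatnonzero(frac <= 0.5)
        if below.size:
            crossing[name] = int(curve.day[below[0]])
    if not crossing:
        last = {n: float(c.fraction_alive[-1]) for n, c in curves.items()}
        raise ValueError(f"no group reaches 50% survival; last fractions: {last}")
    ref = min(crossing, key=lambda n: (crossing[n], n))
    day = crossing[ref]

    def counts_at(curve: SurvivalCurve) -> tuple[int, int]:
        i = np.flatnonzero(curve.day == day)
        if not i.size:
            raise ValueError(f"group {curve.group!r} has no counts on day {day}")
        return int(curve.n_alive[i[0]]), int(curve.n_dead[i[0]])

    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in combinations(sorted(curves), 2):
        table = [counts_at(curves[a]), counts_at(curves[b])]
        pairwise[(a, b)] = fisher_exact_2x2(table)
    corrected = None
    if bonferroni:
        m = len(pairwise)
        corrected = {k: min(1.0, p * m) for k, (_, p) in pairwise.items()}
    return MedianSurvivalTest(day=day, reference_group=ref,
                              pairwise=pairwise, bonferroni=corrected)


def effective_concentration(c_stock: float, v_added: float, v_bath: float) -> float:
    """Final concentration after a drug drop mixes into a bath volume.

    c = c_stock * v_added / (v_added + v_bath), in the units of c_stock.
    E.g. 10 uL of 5 mM aldicarb into ~600 uL of agarose gives ~0.08 mM.
    """
    if c_stock < 0 or v_added < 0 or v_bath <= 0:
        raise ValueError("concentration must be >= 0 and volumes positive")
    return c_stock * v_added / (v_added + v_bath)
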