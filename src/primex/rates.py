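"""Pseudo-first-order rate estimation from primer-extension time courses.

The primary observable is the unextended-primer fraction P/P0 from gel band
intensities.  Under pseudo-first-order kinetics P/P0 = exp(-kobs * t), so
the default estimator fits ln(P/P0) against t by ordinary least squares
with a free intercept, per replicate, and aggregates across replicates
(kobs = -mean slope, stderr = SD(slopes)/sqrt(n)).  An initial-slope
fit on the raw fraction is available behind ``space="linear"``.

Gel quantification noise can push fractions slightly above 1 (clipped to 1)
or to non-positive values (dropped — the log is undefined); both events are
counted and reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExtensionTimeCourse",
    "RateEstimate",
    "DecayFit",
    "fit_kobs",
    "windowed_rates",
    "fit_decay",
    "fold_ratio",
    "nearest_fold",
    "DETECTABILITY_FLOOR",
]

#: default kobs floor (h^-1): rates below this over a ~52 h window are
#: indistinguishable from no extension on a gel and are flagged.
DETECTABILITY_FLOOR = 2e-4


@dataclass(frozen=True)
class ExtensionTimeCourse:
    """One replicate's (t, P/P0) series. Times in hours, fractions in [0, 1]."""

    replicate: str
    t: tuple[float, ...]
    p_frac: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.t)
        p = tuple(float(x) for x in self.p_frac)
        if len(t) != len(p):
            raise ValueError("t and p_frac must have equal length")
        if any(x < 0 for x in t):
            raise ValueError("times must be >= 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p_frac", p)


@dataclass(frozen=True)
class RateEstimate:
    k_obs: float                    # h^-1, >= 0 as reported
    stderr: float                   # h^-1, SD(slopes)/sqrt(n); 0 for n=1
    window: tuple[float, float]
    n_replicates: int
    below_floor: bool = False
    per_replicate: tuple[float, ...] = field(default_factory=tuple)
    n_clipped: int = 0
    n_dropped: int = 0


@dataclass(frozen=True)
class DecayFit:
    k: float           # h^-1
    half_life: float   # hours; inf when k == 0
    c0: float          # fitted initial concentration, mM


def _prepare(
    tc: ExtensionTimeCourse, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    t = np.asarray(tc.t)
    p = np.asarray(tc.p_frac)
    lo, hi = window
    m = (t >= lo) & (t <= hi)
    t, p = t[m], p[m]
    n_clipped = int(np.sum(p > 1))
    p = np.minimum(p, 1.0)
    keep = p > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(
            f"replicate {tc.replicate}: dropped {n_dropped} non-positive "
            "P/P0 sample(s) (log undefined)",
            stacklevel=3,
        )
    return t[keep], p[keep], n_clipped, n_dropped


def _slope(
    t: np.ndarray,
    p: np.ndarray,
    space: Literal["log", "linear"],
    intercept: Literal["free", "zero"],
) -> float:
    y = np.log(p) if space == "log" else p
    if intercept == "free":
        return float(np.polyfit(t, y, 1)[0])
    # fixed intercept: ln(p) = -k t, or p = 1 - k t in linear space
    y0 = 0.0 if space == "log" else 1.0
    return float(np.sum(t * (y - y0)) / np.sum(t * t))


def fit_kobs(
    timecourses: Sequence[ExtensionTimeCourse],
    window: tuple[float, float] | None = None,
    space: Literal["log", "linear"] = "log",
    intercept: Literal["free", "zero"] = "free",
    floor: float = DETECTABILITY_FLOOR,
) -> RateEstimate:
    """Aggregate kobs over replicates by per-replicate least squares.

    Each replicate needs >= 3 usable in-window samples.  ``space="log"``
    (default) fits ln(P/P0) vs t; ``space="linear"`` fits the raw fraction
    (initial-slope estimator).  Estimates below ``floor`` are reported with
    ``below_floor=True``.
    """
    if not timecourses:
        raise ValueError("no time courses given")
    if window is None:
        all_t = [x for tc in timecourses for x in tc.t]
        window = (min(all_t), max(all_t))
    slopes: list[float] = []
    n_clipped = n_dropped = 0
    for tc in timecourses:
        t, p, c, d = _prepare(tc, window)
        n_clipped += c
        n_dropped += d
        if len(t) < 3:
            raise ValueError(
                f"replicate {tc.replicate}: fewer than 3 usable samples in "
                f"window {window}"
            )
        slopes.append(_slope(t, p, space, intercept))
    arr = np.array(slopes)
    k = max(0.0, float(-np.mean(arr)))
    stderr = float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return RateEstimate(
        k_obs=k,
        stderr=stderr,
        window=tuple(window),
        n_replicates=len(arr),
        below_floor=k < floor,
        per_replicate=tuple(-s for s in arr),
        n_clipped=n_clipped,
        n_dropped=n_dropped,
    )


def windowed_rates(
    timecourses: Sequence[ExtensionTimeCourse],
    windows: Sequence[tuple[float, float]],
    **kwargs,
) -> list[RateEstimate]:
    """One RateEstimate per window (windows must be increasing, disjoint)."""
    if not windows:
        raise ValueError("no windows given")
    for (a, b), (c, d) in zip(windows[:-1], windows[1:]):
        if not (a < b <= c < d):
            raise ValueError("windows must be increasing and non-overlapping")
    if windows[0][0] >= windows[0][1]:
        raise ValueError("empty window")
    return [fit_kobs(timecourses, window=w, **kwargs) for w in windows]


def fit_decay(t: Sequence[float], conc: Sequence[float]) -> DecayFit:
    """Exponential-decay fit c(t) = c0 exp(-k t) by log-linear least squares.

    Non-positive concentrations are dropped; >= 3 points must remain.
    A constant series yields k = 0 with infinite half-life.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(conc, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    if len(t) < 3:
        raise ValueError("need >= 3 positive samples for a decay fit")
    slope, icpt = np.polyfit(t, np.log(c), 1)
    k = max(0.0, float(-slope))
    if k * (t.max() - t.min()) < 1e-12:  # numerically flat series
        k = 0.0
    hl = math.inf if k == 0 else math.log(2) / k
    return DecayFit(k=k, half_life=hl, c0=float(np.exp(icpt)))


def fold_ratio(a: "RateEstimate | float", b: "RateEstimate | float") -> float:
    """Rate ratio a/b (dimensionless fold)."""
    ka = a.k_obs if isinstance(a, RateEstimate) else float(a)
    kb = b.k_obs if isinstance(b, RateEstimate) else float(b)
    if kb == 0:
        raise ZeroDivisionError("fold ratio undefined for zero denominator")
    return ka / kb


def nearest_fold(a, b) -> int:
    """fold_ratio rounded to the nearest integer (the 'n-fold' of prose)."""
    return round(fold_ratio(a, b))
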