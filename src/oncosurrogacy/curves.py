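"""Cleaning of digitized Kaplan–Meier coordinates and statistics from them.

Published survival figures are digitized into (time, survival) coordinate
pairs.  Digitization is noisy: points can be slightly out of order, survival
can transiently exceed 1 or rise, and the (0, 1) anchor may be missing.
`clean_curve` normalises such raw coordinates into a valid monotone step
curve; `milestone_from_curve` and `rmst_from_curve` then read milestone
rates and restricted means directly off the cleaned curve, which is how
arm-level effect measures are recovered from figures when no subject-level
data are available.

Curve-derived estimates carry no standard error: the coordinates alone do
not contain at-risk information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import MilestoneEstimate, RmstEstimate, _step_area

__all__ = [
    "DigitizedCurve",
    "CleanCurve",
    "clean_curve",
    "rmst_from_curve",
    "milestone_from_curve",
]


@dataclass(frozen=True)
class DigitizedCurve:
    """Raw (time, survival) coordinates as read off a published figure."""

    points: np.ndarray  # (n, 2): time in months, survival proportion
    n_arm: int | None = None
    max_follow_up: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (time, survival)")
        if pts.shape[0] < 2:
            raise ValueError("a digitized curve needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        if np.any(pts[:, 0] < 0):
            raise ValueError("negative time coordinate")


@dataclass(frozen=True)
class CleanCurve:
    """Normalised step curve: strictly increasing times, non-increasing
    survival in [0, 1], anchored at (0, 1)."""

    points: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def survival(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def max_time(self) -> float:
        return float(self.points[-1, 0])

    def survival_at(self, t: float) -> float:
        """Right-continuous step value at time t."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def clean_curve(raw: DigitizedCurve) -> CleanCurve:
    """Normalise raw digitized coordinates into a valid step curve.

    Sorting, clamping to [0, 1], duplicate-time collapse (keeping the lower
    survival value, i.e. a drop at that time), a running minimum to enforce
    monotone decrease, and a (0, 1) anchor.  Idempotent: a clean curve passes
    through unchanged.
    """
    pts = raw.points.copy()
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    pts[:, 1] = np.clip(pts[:, 1], 0.0, 1.0)

    times, survival = [], []
    for t, s in pts:
        if times and t == times[-1]:
            survival[-1] = min(survival[-1], s)  # drop at a duplicated time
        else:
            times.append(t)
            survival.append(s)
    survival = np.minimum.accumulate(np.asarray(survival))
    times = np.asarray(times)
    if times[-1] == 0.0:
        raise ValueError("degenerate curve: every coordinate lies at time zero")

    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        survival = np.concatenate([[1.0], survival])
    else:
        survival[0] = 1.0
    return CleanCurve(points=np.column_stack([times, survival]))


def rmst_from_curve(
    curve: CleanCurve, tau: float, mode: str = "step", extrapolate: bool = False
) -> RmstEstimate:
    """Restricted mean survival time from a cleaned digitized curve.

    ``mode="step"`` (default) integrates the right-continuous step
    interpolation of the coordinates — a KM curve is a step function, so
    this is the faithful reading when coordinates sit at step corners.
    ``mode="trapezoid"`` joins coordinates linearly, a sensitivity option for
    digitizations that sampled slanted segments.  On a non-increasing curve
    each interval's trapezoid averages its endpoints while the step keeps
    the higher left value, so trapezoid <= step always.
    """
    if tau <= 0:
        raise ValueError("horizon tau must be positive")
    if tau > curve.max_time and not extrapolate:
        raise ValueError(
            f"horizon beyond digitized range: tau={tau} > last coordinate {curve.max_time}"
        )
    if mode == "step":
        value = _step_area(curve.times, curve.survival, tau)
    elif mode == "trapezoid":
        t = np.clip(curve.times, None, tau)
        s = curve.survival
        if tau > curve.max_time:  # extrapolation: carry last value forward
            t = np.append(t, tau)
            s = np.append(s, s[-1])
        elif tau not in t:
            s_tau = float(np.interp(tau, curve.times, curve.survival))
            keep = curve.times < tau
            t = np.append(curve.times[keep], tau)
            s = np.append(curve.survival[keep], s_tau)
        value = float(np.trapezoid(s, t))
    else:
        raise ValueError(f"unknown integration mode {mode!r}")
    return RmstEstimate(tau=float(tau), value=value, se=None)


def milestone_from_curve(
    curve: CleanCurve, tau: float, extrapolate: bool = False
) -> MilestoneEstimate:
    """Milestone survival rate read off a cleaned digitized curve.

    Step-function convention: the survival of the last coordinate at or
    before ``tau``.  No standard error is attached.
    """
    if tau < 0:
        raise ValueError("milestone time tau must be non-negative")
    if tau > curve.max_time and not extrapolate:
        raise ValueError(
            f"milestone beyond digitized range: tau={tau} > last coordinate {curve.max_time}"
        )
    return MilestoneEstimate(
        tau=float(tau), rate=curve.survival_at(tau), se=None, ci_low=None, ci_high=None
    )
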