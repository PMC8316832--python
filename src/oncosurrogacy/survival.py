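"""Kaplan–Meier estimation and the arm-level statistics derived from it.

This module works at the subject level: right-censored event times for one
trial arm go in, and out come the product-limit survival curve (with
Greenwood variance), milestone survival rates S(tau) with confidence
intervals, restricted mean survival time (RMST — the area under the survival
curve up to a horizon tau), and a two-group Cox hazard ratio.

All times are in months.  The survival curve is the standard right-continuous
step function: S(t) is the value just after the last event time <= t, and
S(t) = 1 before the first event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SubjectRecord",
    "SurvivalCurve",
    "MilestoneEstimate",
    "RmstEstimate",
    "HazardRatioEstimate",
    "km_fit",
    "milestone_rate",
    "rmst",
    "cox_hr",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up: time to event or censoring, in months.

    ``event`` is 1 if the endpoint (death or progression) was observed at
    ``time`` and 0 if the subject was censored then.
    """

    time: float
    event: int
    arm: str = ""

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"invalid time: {self.time!r} (must be positive and finite)")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate for one arm.

    ``times`` is the strictly increasing grid of distinct event times;
    ``survival`` the step values S(t) on that grid; ``at_risk`` the number at
    risk just before each time; ``events`` the deaths at each time;
    ``variance`` the Greenwood variance of S(t) at each step.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray
    n_total: int
    max_follow_up: float

    def survival_at(self, t: float) -> float:
        """Right-continuous step value of S at time ``t``."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return 0.0 if idx < 0 else float(self.variance[idx])

    def to_step_points(self) -> np.ndarray:
        """(time, survival) corners of the step function, anchored at (0, 1)."""
        return np.vstack(
            [np.concatenate([[0.0], self.times]), np.concatenate([[1.0], self.survival])]
        ).T

    def plot(self, ax=None, **kwargs):
        """Draw the step curve (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.to_step_points()
        ax.step(
            np.append(pts[:, 0], self.max_follow_up),
            np.append(pts[:, 1], pts[-1, 1]),
            where="post",
            **kwargs,
        )
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(-0.02, 1.02)
        return ax


@dataclass(frozen=True)
class MilestoneEstimate:
    """S(tau) at a prespecified milestone, with a 95% interval."""

    tau: float
    rate: float
    se: float | None
    ci_low: float | None
    ci_high: float | None


@dataclass(frozen=True)
class RmstEstimate:
    """Restricted mean survival time up to ``tau`` months.

    ``se`` is absent (None) for curve-derived estimates, which carry no
    at-risk information.
    """

    tau: float
    value: float
    se: float | None = None


@dataclass(frozen=True)
class HazardRatioEstimate:
    hr: float
    log_hr_se: float
    ci_low: float
    ci_high: float
    n_events: int = 0
    n_iter: int = 0


def _extract_times_events(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a sequence of SubjectRecord or a (times, events) pair of arrays."""
    if isinstance(records, tuple) and len(records) == 2:
        times = np.asarray(records[0], dtype=float)
        events = np.asarray(records[1], dtype=int)
    else:
        seq = list(records)
        if seq and isinstance(seq[0], SubjectRecord):
            times = np.array([r.time for r in seq], dtype=float)
            events = np.array([r.event for r in seq], dtype=int)
        else:
            arr = np.asarray(seq, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 2:
                times, events = arr[:, 0], arr[:, 1].astype(int)
            else:
                raise TypeError("records must be SubjectRecords, (times, events), or an (n, 2) array")
    if times.size == 0:
        raise ValueError("no records")
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise ValueError("invalid time: all times must be positive and finite")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    return times, events


def km_fit(records) -> SurvivalCurve:
    """Kaplan–Meier product-limit fit for one arm.

    Parameters
    ----------
    records
        Sequence of :class:`SubjectRecord`, or a ``(times, events)`` pair of
        array-likes, or an ``(n, 2)`` array of ``[time, event]`` rows.

    Returns
    -------
    SurvivalCurve
        Step estimate over the distinct event times with Greenwood variance.
        Censored subjects leave the risk set without producing a step; with
        no events at all the curve has an empty grid and S == 1 everywhere.
    """
    times, events = _extract_times_events(records)
    n = times.size
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times, deaths = np.unique(times[events == 1], return_counts=True)
    # at risk just before t: subjects with follow-up >= t
    at_risk = n - np.searchsorted(times, event_times, side="left")

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - deaths / at_risk
        survival = np.cumprod(frac)
        # Greenwood: Var S(t) = S(t)^2 * cumsum d / (n (n - d)); the increment is
        # undefined once the curve hits zero (d == n) — variance is 0 there.
        incr = deaths / (at_risk * (at_risk - deaths))
    incr = np.where(at_risk == deaths, 0.0, incr)
    variance = survival**2 * np.cumsum(incr)
    variance = np.where(survival == 0.0, 0.0, variance)

    return SurvivalCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        events=deaths,
        variance=variance,
        n_total=int(n),
        max_follow_up=float(times.max()),
    )


def milestone_rate(
    curve: SurvivalCurve,
    tau: float,
    ci_scale: str = "cloglog",
    level: float = 0.95,
    extrapolate: bool = False,
) -> MilestoneEstimate:
    """Milestone survival rate S(tau) with a Greenwood-based interval.

    The default interval is computed on the complementary log-log scale
    (log(-log S)), which respects the [0, 1] range; ``ci_scale="plain"``
    applies the normal interval directly to S and clips.

    Raises ``ValueError`` if ``tau`` lies beyond the last observed follow-up
    time and ``extrapolate`` is False; with ``extrapolate=True`` the last
    value of S is carried forward.
    """
    if tau <= 0:
        raise ValueError("milestone time tau must be positive")
    if tau > curve.max_follow_up and not extrapolate:
        raise ValueError(
            f"milestone beyond follow-up: tau={tau} > last observed time {curve.max_follow_up}"
        )
    rate = curve.survival_at(tau)
    se = math.sqrt(max(curve.variance_at(tau), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0 or rate in (0.0, 1.0):
        lo = hi = rate
    elif ci_scale == "cloglog":
        # theta = log(-log S); se(theta) = se(S) / (S |log S|)
        se_theta = se / (rate * abs(math.log(rate)))
        lo = rate ** math.exp(z * se_theta)
        hi = rate ** math.exp(-z * se_theta)
    elif ci_scale == "plain":
        lo = max(0.0, rate - z * se)
        hi = min(1.0, rate + z * se)
    else:
        raise ValueError(f"unknown ci_scale {ci_scale!r}")
    return MilestoneEstimate(tau=float(tau), rate=rate, se=se, ci_low=lo, ci_high=hi)


def rmst(curve: SurvivalCurve, tau: float, extrapolate: bool = False) -> RmstEstimate:
    """Restricted mean survival time: the area under S(t) from 0 to ``tau``.

    The standard error uses the usual variance of the integrated KM curve,

        Var = sum over event times t_i <= tau of A_i^2 * d_i / (n_i (n_i - d_i)),

    where A_i is the remaining area under S from t_i to tau.
    """
    if tau <= 0:
        raise ValueError("horizon tau must be positive")
    if tau > curve.max_follow_up and not extrapolate:
        raise ValueError(
            f"horizon beyond follow-up: tau={tau} > last observed time {curve.max_follow_up}"
        )
    grid = np.concatenate([[0.0], curve.times])
    surv = np.concatenate([[1.0], curve.survival])
    value = _step_area(grid, surv, tau)

    # cumulative area A(t) is piecewise linear in t with slope S, so the
    # remaining areas A_i = A(tau) - A(t_i) come from a single linear interp
    cum_area = np.concatenate([[0.0], np.cumsum(surv[:-1] * np.diff(grid))])
    mask = (curve.times <= tau) & (curve.events > 0) & (curve.at_risk > curve.events)
    a = value - np.interp(curve.times[mask], grid, cum_area)
    d_i = curve.events[mask].astype(float)
    n_i = curve.at_risk[mask].astype(float)
    var = float(np.sum(a**2 * d_i / (n_i * (n_i - d_i))))
    return RmstEstimate(tau=float(tau), value=float(value), se=math.sqrt(var))


def _step_area(grid: np.ndarray, surv: np.ndarray, tau: float) -> float:
    """Area under a right-continuous step function from 0 to tau."""
    upper = np.minimum(np.append(grid[1:], np.inf), tau)
    widths = np.clip(upper - np.minimum(grid, tau), 0.0, None)
    return float(np.sum(widths * surv))


def cox_hr(
    records_experimental,
    records_control,
    max_iter: int = 100,
    rtol: float = 1e-8,
    level: float = 0.95,
) -> HazardRatioEstimate:
    """Two-group Cox proportional-hazards fit (experimental vs control).

    Maximises the partial likelihood for a single binary treatment covariate
    with Efron handling of tied event times, by Newton–Raphson with step
    halving.  The Wald interval is computed on the log scale.
    """
    t1, e1 = _extract_times_events(records_experimental)
    t0, e0 = _extract_times_events(records_control)
    times = np.concatenate([t1, t0])
    events = np.concatenate([e1, e0])
    x = np.concatenate([np.ones_like(t1), np.zeros_like(t0)])

    if events.sum() == 0:
        raise ValueError("no events in pooled data")

    # per distinct event time: deaths d, treated deaths s1, at-risk counts r1/r0
    ev_times, d = np.unique(times[events == 1], return_counts=True)
    s1 = np.zeros(ev_times.size)
    td, tc = np.unique(t1[e1 == 1], return_counts=True)
    s1[np.searchsorted(ev_times, td)] = tc
    st1 = np.sort(t1)
    st0 = np.sort(t0)
    r1 = t1.size - np.searchsorted(st1, ev_times, side="left").astype(float)
    r0 = t0.size - np.searchsorted(st0, ev_times, side="left").astype(float)

    # Efron denominators: one (c + a e^beta) term per tied death, with
    # constants c, a precomputed once over all (event time, tie index) pairs
    rep = np.repeat(np.arange(ev_times.size), d.astype(int))
    ell = np.concatenate([np.arange(k) for k in d.astype(int)])
    frac = ell / d[rep]
    c_flat = r0[rep] - frac * (d[rep] - s1[rep])
    a_flat = r1[rep] - frac * s1[rep]
    s1_total = float(s1.sum())

    def loglik_grad_info(beta: float) -> tuple[float, float, float]:
        e = math.exp(beta)
        phi = c_flat + a_flat * e
        u = a_flat * e / phi
        ll = beta * s1_total - float(np.sum(np.log(phi)))
        grad = s1_total - float(np.sum(u))
        info = float(np.sum(u * (1.0 - u)))
        return ll, grad, info

    beta = 0.0
    ll, grad, info = loglik_grad_info(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if info <= 0:
            raise RuntimeError("Cox fit failed: non-positive information")
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = loglik_grad_info(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = loglik_grad_info(new_beta)
            halvings += 1
        converged = abs(step) <= rtol * max(1.0, abs(new_beta))
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if converged:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(beta={beta:.4g}, grad={grad:.4g}, loglik={ll:.4g}); "
            "the likelihood may be monotone (all events in one arm)"
        )

    se = 1.0 / math.sqrt(info)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return HazardRatioEstimate(
        hr=math.exp(beta),
        log_hr_se=se,
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        n_events=int(events.sum()),
        n_iter=n_iter,
    )


def curve_to_frame(curve: SurvivalCurve):
    """Export the step table (time, survival, at_risk, events) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "variance": curve.variance,
        }
    )


def records_from_frame(df, arm: str | None = None) -> list[SubjectRecord]:
    """Build SubjectRecords from a table with time_months / event (/ arm_id)."""
    if arm is not None and "arm_id" in df.columns:
        df = df[df["arm_id"] == arm]
    return [
        SubjectRecord(time=float(t), event=int(e), arm=str(a))
        for t, e, a in zip(
            df["time_months"], df["event"], df.get("arm_id", [""] * len(df))
        )
    ]
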