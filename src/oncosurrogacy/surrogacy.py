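"""Trial-level surrogacy analysis.

Each experimental-vs-control contrast contributes one observation: the
treatment effect on overall survival (the hazard ratio, HR_OS) and the
treatment effect on a candidate surrogate (a hazard ratio, relative risk, or
ratio of milestone rates / restricted means, always oriented
experimental / control).  Surrogacy is quantified two ways:

* the Spearman rank correlation between the surrogate effect and HR_OS, and
* a weighted least-squares regression of log(HR_OS) on the log surrogate
  effect, weighted by the combined randomized sample size of the two arms,
  summarised by its weighted coefficient of determination R².

The regression is exposed statsmodels-style: :class:`SurrogacyModel` is
built from a comparison table, ``fit()`` returns a
:class:`SurrogacyResults` with coefficients, standard errors, p-values, R²
and a ``summary()`` table.  ``wls_loglog_fit`` and ``evaluate_all`` are thin
functional wrappers over the same machinery.

A strong surrogate shows |r| near 1 and R² near 1, with a slope whose sign
matches the effect orientation: for a benefit-oriented ratio (> 1 favours
the experimental arm) against HR_OS (< 1 favours it), the slope is negative.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SURROGATE_FIELDS",
    "ComparisonRecord",
    "SurrogacyModel",
    "SurrogacyResults",
    "effect_ratio",
    "rr_from_counts",
    "spearman_corr",
    "wls_loglog_fit",
    "evaluate_all",
]

#: Candidate surrogate effect columns, in reporting order.
SURROGATE_FIELDS = (
    "ratio_milestone_12",
    "ratio_rmst_12",
    "ratio_rmst_24",
    "hr_pfs",
    "rr_orr",
    "rr_dcr",
)

_SURROGATE_LABELS = {
    "ratio_milestone_12": "ratio of the 12-month OS milestone rate",
    "ratio_rmst_12": "ratio of the 12-month OS milestone RMST",
    "ratio_rmst_24": "ratio of the 24-month OS milestone RMST",
    "hr_pfs": "HR_PFS",
    "rr_orr": "RR_ORR",
    "rr_dcr": "RR_DCR",
}


@dataclass(frozen=True)
class ComparisonRecord:
    """One experimental-vs-control contrast with its effect measures.

    All effect measures are oriented experimental / control; ``n_total`` is
    the combined randomized n of the two arms and serves as the regression
    weight.  Optional measures may be None (complete-case handling drops the
    comparison from that surrogate's fit only).
    """

    trial_id: str
    experimental_arm_id: str
    control_arm_id: str
    n_total: int
    hr_os: float
    hr_pfs: float | None = None
    rr_orr: float | None = None
    rr_dcr: float | None = None
    ratio_milestone_12: float | None = None
    ratio_rmst_12: float | None = None
    ratio_rmst_24: float | None = None

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        for f in ("hr_os",) + tuple(SURROGATE_FIELDS):
            v = getattr(self, f)
            if f == "hr_os" and v is None:
                raise ValueError("hr_os is required")
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"non-positive effect value: {f}={v!r}")


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """Normalise a list of ComparisonRecord (or a DataFrame) to a DataFrame."""
    if isinstance(comparisons, pd.DataFrame):
        return comparisons
    cols = [f.name for f in dataclass_fields(ComparisonRecord)]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in comparisons], columns=cols
    )


def effect_ratio(value_experimental: float, value_control: float) -> float:
    """Experimental / control ratio of two positive effect values."""
    if not (value_experimental > 0 and value_control > 0):
        raise ValueError(
            f"non-positive effect value: {value_experimental!r} / {value_control!r}"
        )
    return value_experimental / value_control


def rr_from_counts(
    responders_exp: int, n_exp: int, responders_ctrl: int, n_ctrl: int
) -> float:
    """Relative risk of response, (responders_exp/n_exp) / (responders_ctrl/n_ctrl).

    A zero numerator yields RR = 0 with a logged warning; a zero control
    proportion makes the ratio undefined and raises.
    """
    for r, n in ((responders_exp, n_exp), (responders_ctrl, n_ctrl)):
        if n <= 0 or not (0 <= r <= n):
            raise ValueError(f"invalid counts: {r}/{n}")
    if responders_ctrl == 0:
        raise ValueError("undefined relative risk: zero responders in control arm")
    if responders_exp == 0:
        logger.warning("zero responders in experimental arm: RR = 0")
    return (responders_exp / n_exp) / (responders_ctrl / n_ctrl)


def spearman_corr(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    r is the Pearson correlation of average (mid) ranks.  ``method="t"``
    (default) uses the t approximation with n - 2 degrees of freedom;
    ``method="permutation"`` computes the exact permutation p-value,
    available for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: constant input vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(r) >= 1.0:
            return r, 0.0
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    elif method == "permutation":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rx_c = rx - rx.mean()
        denom = math.sqrt(np.sum(rx_c**2))
        count = total = 0
        for perm in itertools.permutations(ry):
            ry_p = np.asarray(perm)
            ry_c = ry_p - ry_p.mean()
            r_p = float(np.dot(rx_c, ry_c)) / (denom * math.sqrt(np.sum(ry_c**2)))
            total += 1
            if abs(r_p) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, float(min(p, 1.0))


class SurrogacyModel:
    """Weighted log–log regression of the OS treatment effect on a surrogate.

    Parameters
    ----------
    comparisons
        Comparison table (DataFrame or list of :class:`ComparisonRecord`)
        with an ``hr_os`` column, the surrogate column, and a weight column.
    surrogate
        Name of the surrogate effect column (one of ``SURROGATE_FIELDS`` or
        any positive-valued column).
    log_base
        Base of the logarithm applied to both sides (default 10).  Slope,
        R² and p-values are invariant to the shared base; the intercept is
        not.
    weights
        Name of the weight column (default ``"n_total"``, the combined
        randomized n of the two arms).
    """

    def __init__(
        self,
        comparisons,
        surrogate: str,
        log_base: float = 10.0,
        weights: str = "n_total",
    ) -> None:
        df = comparisons_to_frame(comparisons)
        if surrogate not in df.columns:
            raise KeyError(f"unknown surrogate column {surrogate!r}")
        sub = df.loc[df["hr_os"].notna() & df[surrogate].notna()]
        if len(sub) < 3:
            raise ValueError(
                f"insufficient comparisons: {len(sub)} usable for {surrogate!r} (need >= 3)"
            )
        xs = sub[surrogate].to_numpy(dtype=float)
        ys = sub["hr_os"].to_numpy(dtype=float)
        ws = sub[weights].to_numpy(dtype=float)
        if np.any(xs <= 0) or np.any(ys <= 0):
            raise ValueError("non-positive effect value in comparisons")
        if np.any(ws <= 0):
            raise ValueError("non-positive weight")
        self.surrogate = surrogate
        self.log_base = float(log_base)
        self.weights = ws
        self.surrogate_values = xs
        self.hr_os_values = ys
        self.exog = np.log(xs) / np.log(log_base)
        self.endog = np.log(ys) / np.log(log_base)
        self.nobs = len(sub)
        self.trial_ids = sub["trial_id"].tolist() if "trial_id" in sub else None

    @classmethod
    def from_comparisons(cls, comparisons, surrogate: str, **kwargs) -> "SurrogacyModel":
        return cls(comparisons, surrogate, **kwargs)

    def fit(self) -> "SurrogacyResults":
        """Weighted least squares via the closed-form normal equations."""
        x, y, w = self.exog, self.endog, self.weights
        sw = w.sum()
        xbar = float(np.sum(w * x) / sw)
        ybar = float(np.sum(w * y) / sw)
        sxx = float(np.sum(w * (x - xbar) ** 2))
        if sxx == 0:
            raise ValueError("surrogate effects are constant on the log scale")
        sxy = float(np.sum(w * (x - xbar) * (y - ybar)))
        slope = sxy / sxx
        intercept = ybar - slope * xbar

        resid = y - intercept - slope * x
        sse = float(np.sum(w * resid**2))
        sst = float(np.sum(w * (y - ybar) ** 2))
        r_squared = 1.0 - sse / sst if sst > 0 else float("nan")

        dof = self.nobs - 2
        sigma2 = sse / dof if dof > 0 else float("nan")
        se_slope = math.sqrt(sigma2 / sxx)
        se_intercept = math.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))
        if se_slope > 0:
            t_slope = slope / se_slope
            p_slope = 2.0 * stats.t.sf(abs(t_slope), dof)
        else:
            t_slope, p_slope = float("inf") * np.sign(slope), 0.0

        sp_r, sp_p = spearman_corr(self.surrogate_values, self.hr_os_values)
        return SurrogacyResults(
            surrogate_name=self.surrogate,
            n_comparisons=self.nobs,
            spearman_r=sp_r,
            spearman_p=sp_p,
            intercept=intercept,
            slope=slope,
            se_intercept=se_intercept,
            se_slope=se_slope,
            r_squared=r_squared,
            regression_p=float(p_slope),
            log_base=self.log_base,
            residuals=resid,
            model=self,
        )


@dataclass
class SurrogacyResults:
    """Results of one surrogate's Spearman correlation and WLS fit."""

    surrogate_name: str
    n_comparisons: int
    spearman_r: float
    spearman_p: float
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r_squared: float
    regression_p: float
    log_base: float
    residuals: np.ndarray | None = None
    model: SurrogacyModel | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.se_intercept, self.se_slope])

    def predict_log_hr_os(self, surrogate_effect) -> np.ndarray:
        """Predicted log(HR_OS) (in the fitted base) for surrogate effect ratios."""
        x = np.log(np.asarray(surrogate_effect, dtype=float)) / np.log(self.log_base)
        return self.intercept + self.slope * x

    def equation(self) -> str:
        """The regression equation in report form."""
        label = _SURROGATE_LABELS.get(self.surrogate_name, self.surrogate_name)
        sign = "−" if self.slope < 0 else "+"
        return (
            f"Log (HRos) = {self.intercept:.3f} {sign} {abs(self.slope):.3f} "
            f"× log ({label})"
        )

    def summary(self) -> str:
        label = _SURROGATE_LABELS.get(self.surrogate_name, self.surrogate_name)
        lines = [
            "Trial-level surrogacy: weighted log-log regression",
            "=" * 58,
            f"surrogate:        {label}",
            f"comparisons (n):  {self.n_comparisons}",
            f"log base:         {self.log_base:g}",
            f"Spearman r:       {self.spearman_r:.3f}   (P = {self.spearman_p:.3f})",
            f"intercept:        {self.intercept:.4f}  (se {self.se_intercept:.4f})",
            f"slope:            {self.slope:.4f}  (se {self.se_slope:.4f}, "
            f"P = {self.regression_p:.4f})",
            f"weighted R2:      {self.r_squared:.3f}",
            f"equation:         {self.equation()}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "surrogate": self.surrogate_name,
            "n_comparisons": self.n_comparisons,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_slope": self.se_slope,
            "r_squared": self.r_squared,
            "regression_p": self.regression_p,
            "log_base": self.log_base,
        }

    def plot(self, ax=None):
        """Scatter of the log-effect pairs with the fitted line (point size ~ weight)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        if m is None:
            raise ValueError("results were detached from their model; cannot plot")
        sizes = 200 * m.weights / m.weights.max()
        ax.scatter(m.exog, m.endog, s=sizes, alpha=0.6, edgecolor="k")
        xx = np.linspace(m.exog.min(), m.exog.max(), 50)
        ax.plot(xx, self.intercept + self.slope * xx, "r-")
        label = _SURROGATE_LABELS.get(self.surrogate_name, self.surrogate_name)
        ax.set_xlabel(f"log({label})")
        ax.set_ylabel("log(HR OS)")
        ax.set_title(f"R² = {self.r_squared:.3f}, r = {self.spearman_r:.3f}")
        return ax


def wls_loglog_fit(
    comparisons, surrogate: str, log_base: float = 10.0, weights: str = "n_total"
) -> SurrogacyResults:
    """Fit one surrogate's weighted log–log regression (see SurrogacyModel)."""
    return SurrogacyModel(comparisons, surrogate, log_base=log_base, weights=weights).fit()


def evaluate_all(
    comparisons,
    surrogates=SURROGATE_FIELDS,
    log_base: float = 10.0,
    weights: str = "n_total",
) -> list[SurrogacyResults]:
    """Fit every candidate surrogate with >= 3 complete-case comparisons.

    Comparisons missing a surrogate's value are dropped from that
    surrogate's fit only, so per-surrogate n varies with data availability;
    each exclusion is logged.
    """
    df = comparisons_to_frame(comparisons)
    results: list[SurrogacyResults] = []
    for name in surrogates:
        if name not in df.columns:
            logger.info("surrogate %s: column absent, skipped", name)
            continue
        usable = df["hr_os"].notna() & df[name].notna()
        dropped = df.loc[~usable, "trial_id"] if "trial_id" in df else []
        for trial in dropped:
            logger.info("surrogate %s: comparison in trial %s dropped (missing value)", name, trial)
        if usable.sum() < 3:
            logger.info(
                "surrogate %s: only %d usable comparisons, no fit", name, int(usable.sum())
            )
            continue
        results.append(wls_loglog_fit(df, name, log_base=log_base, weights=weights))
    return results


def results_to_frame(results: list[SurrogacyResults]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
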