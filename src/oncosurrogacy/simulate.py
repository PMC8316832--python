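"""Synthetic randomized-trial generator with immunotherapy-like survival kinetics.

The generator emulates the features that make first-line immunotherapy
trials in extensive-stage small cell lung cancer statistically awkward:

* short control survival — piecewise-constant hazard, default a single
  exponential rate giving a median OS of 10 months;
* a delayed treatment effect — the experimental hazard equals the control
  hazard until ``delay_months`` (default 6) and is multiplied by
  ``hr_post_delay`` afterwards, so the two survival curves overlap early and
  separate late (a non-proportional-hazards pattern);
* an optional cure fraction — a mixture subpopulation of long-term survivors
  producing a plateau at the tail of the experimental curve;
* staggered accrual with administrative cutoff and exponential dropout;
* progression-free survival with a proportionally larger hazard, clipped to
  be no later than death; and per-arm binomial response outcomes (ORR, DCR).

Event times are drawn by inverse-transform sampling from the
piecewise-exponential survival function.  A single scenario seed governs all
arms through ``numpy.random.SeedSequence`` spawning (arm index order:
control, exp1, exp2), so whole trial suites are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import survival as sv
from .curves import DigitizedCurve
from .surrogacy import ComparisonRecord, effect_ratio, rr_from_counts

__all__ = [
    "TrialScenario",
    "ArmResult",
    "simulate_arm",
    "simulate_trial",
    "simulate_trial_suite",
    "digitize_emulator",
    "piecewise_exp_survival",
    "analytic_rmst",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class TrialScenario:
    """Generative parameters for one simulated randomized trial.

    ``control_hazard`` is a piecewise-constant hazard: ``breakpoints`` are
    the interval start times (first must be 0) and ``rates`` the hazards per
    month on each interval.  The default single rate ln(2)/10 gives a
    control median OS of 10 months.
    """

    n_per_arm: int = 200
    n_experimental_arms: int = 1
    breakpoints: tuple = (0.0,)
    rates: tuple = (_LN2 / 10.0,)
    delay_months: float = 6.0
    hr_post_delay: float = 0.70
    hr_post_delay_exp2: float | None = None
    cure_fraction: float = 0.0
    accrual_months: float = 12.0
    admin_cutoff_months: float = 36.0
    dropout_rate: float = 0.005
    orr: dict = field(default_factory=lambda: {"control": 0.60, "exp1": 0.68, "exp2": 0.66})
    dcr: dict = field(default_factory=lambda: {"control": 0.85, "exp1": 0.88, "exp2": 0.87})
    pfs_fraction: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.n_experimental_arms not in (1, 2):
            raise ValueError("n_experimental_arms must be 1 or 2")
        if len(self.breakpoints) != len(self.rates) or self.breakpoints[0] != 0.0:
            raise ValueError("breakpoints must start at 0 and match rates in length")
        if any(r <= 0 for r in self.rates):
            raise ValueError("hazard rates must be positive")
        if self.delay_months < 0:
            raise ValueError("delay_months must be >= 0")
        if self.hr_post_delay <= 0:
            raise ValueError("hr_post_delay must be positive")
        if self.hr_post_delay_exp2 is not None and self.hr_post_delay_exp2 <= 0:
            raise ValueError("hr_post_delay_exp2 must be positive")
        if not 0.0 <= self.cure_fraction < 1.0:
            raise ValueError("cure_fraction must be in [0, 1)")
        if self.dropout_rate < 0 or self.accrual_months < 0:
            raise ValueError("dropout_rate and accrual_months must be >= 0")
        if self.admin_cutoff_months <= 0:
            raise ValueError("admin_cutoff_months must be positive")
        for d in (self.orr, self.dcr):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("response probabilities must be in [0, 1]")
        for a in self.arm_labels():
            if self.dcr.get(a, 1.0) < self.orr.get(a, 0.0):
                raise ValueError("DCR must be >= ORR in every arm")

    def arm_labels(self) -> list[str]:
        return ["control"] + [f"exp{i + 1}" for i in range(self.n_experimental_arms)]

    def arm_hazard(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise hazard (breakpoints, rates) for one arm.

        Experimental arms keep the control hazard before ``delay_months``
        and multiply it by ``hr_post_delay`` afterwards.
        """
        bks = np.asarray(self.breakpoints, dtype=float)
        rts = np.asarray(self.rates, dtype=float)
        if arm == "control":
            return bks, rts
        hr = self.hr_post_delay
        if arm == "exp2" and self.hr_post_delay_exp2 is not None:
            hr = self.hr_post_delay_exp2
        if hr == 1.0:
            return bks, rts
        d = self.delay_months
        if d > 0 and d not in bks:
            idx = int(np.searchsorted(bks, d))
            bks = np.insert(bks, idx, d)
            rts = np.insert(rts, idx, rts[idx - 1])
        rts = np.where(bks >= d, rts * hr, rts)
        return bks, rts


def piecewise_exp_survival(t, breakpoints, rates) -> np.ndarray:
    """Survival function exp(-H(t)) of a piecewise-constant hazard."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    bks = np.asarray(breakpoints, dtype=float)
    rts = np.asarray(rates, dtype=float)
    # cumulative hazard at interval starts
    seg = rts[:-1] * (bks[1:] - bks[:-1])
    h0 = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.clip(np.searchsorted(bks, t, side="right") - 1, 0, len(bks) - 1)
    h = h0[idx] + rts[idx] * (t - bks[idx])
    return np.exp(-h)


def _sample_piecewise_exp(rng: np.random.Generator, n: int, breakpoints, rates) -> np.ndarray:
    """Inverse-transform draws from the piecewise-exponential law."""
    bks = np.asarray(breakpoints, dtype=float)
    rts = np.asarray(rates, dtype=float)
    seg = rts[:-1] * (bks[1:] - bks[:-1])
    h0 = np.concatenate([[0.0], np.cumsum(seg)])  # H at interval starts
    target = rng.exponential(size=n)  # H(T) ~ Exp(1)
    idx = np.clip(np.searchsorted(h0, target, side="right") - 1, 0, len(bks) - 1)
    return bks[idx] + (target - h0[idx]) / rts[idx]


def analytic_rmst(tau: float, breakpoints, rates, cure_fraction: float = 0.0) -> float:
    """Closed-form RMST of the generative law, with optional cure mixture."""
    bks = np.asarray(breakpoints, dtype=float)
    rts = np.asarray(rates, dtype=float)
    seg = rts[:-1] * (bks[1:] - bks[:-1])
    h0 = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = np.exp(-h0)  # survival at interval starts
    ends = np.minimum(np.append(bks[1:], np.inf), tau)
    widths = np.clip(ends - np.minimum(bks, tau), 0.0, None)
    areas = s0 * (1.0 - np.exp(-rts * widths)) / rts
    base = float(np.sum(np.where(widths > 0, areas, 0.0)))
    return cure_fraction * tau + (1.0 - cure_fraction) * base


def analytic_milestone(tau: float, breakpoints, rates, cure_fraction: float = 0.0) -> float:
    s = float(piecewise_exp_survival(tau, breakpoints, rates)[0])
    return cure_fraction + (1.0 - cure_fraction) * s


@dataclass
class ArmResult:
    """Subject-level output of one simulated arm."""

    arm: str
    os_records: list
    pfs_records: list
    n: int
    responders_orr: int
    responders_dcr: int


def _validate_arm(scenario: TrialScenario, arm: str) -> int:
    labels = scenario.arm_labels()
    if arm not in labels:
        raise ValueError(f"unknown arm {arm!r}; scenario arms are {labels}")
    return labels.index(arm)


def simulate_arm(scenario: TrialScenario, arm: str, _ss: np.random.SeedSequence | None = None) -> ArmResult:
    """Simulate one arm's OS and PFS records and response counts.

    OS times come from the arm's piecewise-exponential law (cure-fraction
    subjects never die and appear censored at cutoff); censoring is the
    minimum of exponential dropout and administrative follow-up
    (``admin_cutoff_months`` minus a uniform accrual entry time).  PFS uses
    the same law with hazard scaled by ``pfs_fraction`` and is clipped to be
    no later than OS.
    """
    arm_idx = _validate_arm(scenario, arm)
    if _ss is None:
        _ss = np.random.SeedSequence(scenario.seed)
    rng = np.random.Generator(np.random.PCG64(_ss.spawn(len(scenario.arm_labels()))[arm_idx]))

    n = scenario.n_per_arm
    bks, rts = scenario.arm_hazard(arm)

    t_death = _sample_piecewise_exp(rng, n, bks, rts)
    if arm != "control" and scenario.cure_fraction > 0:
        cured = rng.random(n) < scenario.cure_fraction
        t_death = np.where(cured, np.inf, t_death)

    entry = rng.uniform(0.0, scenario.accrual_months, size=n) if scenario.accrual_months > 0 else np.zeros(n)
    t_admin = scenario.admin_cutoff_months - entry
    if scenario.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / scenario.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_admin, t_drop)

    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)

    t_prog = _sample_piecewise_exp(rng, n, bks, rts * scenario.pfs_fraction)
    t_prog = np.minimum(t_prog, t_death)  # progression/death ordering
    pfs_time = np.minimum(t_prog, t_cens)
    pfs_event = (t_prog <= t_cens).astype(int)

    eps = 1e-9  # survival times are strictly positive
    os_time = np.maximum(os_time, eps)
    pfs_time = np.maximum(pfs_time, eps)

    p_orr = scenario.orr[arm]
    p_dcr = scenario.dcr[arm]
    n_orr = int(rng.binomial(n, p_orr))
    # disease control includes responders; extra controlled among non-responders
    p_extra = 0.0 if p_orr >= 1.0 else (p_dcr - p_orr) / (1.0 - p_orr)
    n_dcr = n_orr + int(rng.binomial(n - n_orr, min(max(p_extra, 0.0), 1.0)))

    os_records = [
        sv.SubjectRecord(time=float(t), event=int(e), arm=arm)
        for t, e in zip(os_time, os_event)
    ]
    pfs_records = [
        sv.SubjectRecord(time=float(t), event=int(e), arm=arm)
        for t, e in zip(pfs_time, pfs_event)
    ]
    return ArmResult(
        arm=arm,
        os_records=os_records,
        pfs_records=pfs_records,
        n=n,
        responders_orr=n_orr,
        responders_dcr=n_dcr,
    )


def simulate_trial(
    scenario: TrialScenario, trial_id: str = "trial"
) -> tuple[dict[str, ArmResult], list[ComparisonRecord]]:
    """Simulate all arms of a trial and assemble its comparison records.

    Each experimental arm is contrasted with the shared control arm: Cox
    hazard ratios for OS and PFS, relative risks for ORR and DCR, and ratios
    of the 12-month milestone rate and the 12-/24-month RMST computed from
    the fitted Kaplan–Meier curves.
    """
    ss = np.random.SeedSequence(scenario.seed)
    arms = {a: simulate_arm(scenario, a, _ss=ss) for a in scenario.arm_labels()}

    def measures(arm_res: ArmResult) -> dict:
        curve = sv.km_fit(arm_res.os_records)
        out = {"curve": curve}
        for tau, key in ((12.0, "m12"), (12.0, "rmst12"), (24.0, "rmst24")):
            try:
                if key == "m12":
                    out[key] = sv.milestone_rate(curve, tau).rate
                else:
                    out[key] = sv.rmst(curve, tau).value
            except ValueError:
                out[key] = None  # horizon beyond this arm's follow-up
        return out

    per_arm = {a: measures(r) for a, r in arms.items()}
    ctrl = arms["control"]
    comparisons = []
    for a in scenario.arm_labels()[1:]:
        exp = arms[a]
        hr_os = sv.cox_hr(exp.os_records, ctrl.os_records).hr
        hr_pfs = sv.cox_hr(exp.pfs_records, ctrl.pfs_records).hr
        rr_orr = rr_from_counts(exp.responders_orr, exp.n, ctrl.responders_orr, ctrl.n)
        rr_dcr = rr_from_counts(exp.responders_dcr, exp.n, ctrl.responders_dcr, ctrl.n)

        def ratio(key: str):
            ev, cv = per_arm[a][key], per_arm["control"][key]
            if ev is None or cv is None or ev <= 0 or cv <= 0:
                return None
            return effect_ratio(ev, cv)

        comparisons.append(
            ComparisonRecord(
                trial_id=trial_id,
                experimental_arm_id=a,
                control_arm_id="control",
                n_total=exp.n + ctrl.n,
                hr_os=hr_os,
                hr_pfs=hr_pfs,
                rr_orr=rr_orr if rr_orr > 0 else None,
                rr_dcr=rr_dcr if rr_dcr > 0 else None,
                ratio_milestone_12=ratio("m12"),
                ratio_rmst_12=ratio("rmst12"),
                ratio_rmst_24=ratio("rmst24"),
            )
        )
    return arms, comparisons


def simulate_trial_suite(
    k_trials: int,
    effect_grid,
    template: TrialScenario | None = None,
    three_arm_trials: int = 2,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Simulate a suite of trials spanning a grid of treatment effects.

    Returns the subject-level arm results per trial and a comparison table
    with the true generative parameters attached (``true_hr_post_delay``,
    ``true_ratio_rmst_12/24``, ``true_ratio_milestone_12`` from the analytic
    law) for recovery checks.  The first ``three_arm_trials`` trials get a
    second experimental arm whose post-delay hazard ratio is the grid value
    scaled by 1.1 (a weaker sibling regimen).
    """
    if k_trials < 3:
        raise ValueError("need at least 3 trials for a surrogacy fit")
    effect_grid = list(effect_grid)
    if len(effect_grid) != k_trials:
        raise ValueError("effect_grid must have one hr_post_delay per trial")
    if template is None:
        template = TrialScenario()
    if seed is None:
        seed = template.seed

    root = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(k_trials)]

    suites: dict[str, dict[str, ArmResult]] = {}
    rows = []
    for i, (hr_i, seed_i) in enumerate(zip(effect_grid, trial_seeds)):
        trial_id = f"SIM{i + 1:02d}"
        n_exp = 2 if i < three_arm_trials else 1
        scn = replace(
            template,
            hr_post_delay=float(hr_i),
            # sibling arm in 3-arm trials: weaker effect (hr scaled toward 1)
            hr_post_delay_exp2=min(1.0, 1.1 * float(hr_i)) if n_exp == 2 else None,
            n_experimental_arms=n_exp,
            seed=seed_i,
        )
        arms, comps = simulate_trial(scn, trial_id=trial_id)
        suites[trial_id] = arms

        for comp in comps:
            hr_true = float(hr_i) if comp.experimental_arm_id == "exp1" else min(1.0, 1.1 * float(hr_i))
            bks_c, rts_c = scn.arm_hazard("control")
            bks_e, rts_e = scn.arm_hazard(comp.experimental_arm_id)
            cf = scn.cure_fraction
            row = {**comp.__dict__}
            row["true_hr_post_delay"] = hr_true
            row["true_ratio_rmst_12"] = analytic_rmst(12.0, bks_e, rts_e, cf) / analytic_rmst(
                12.0, bks_c, rts_c
            )
            row["true_ratio_rmst_24"] = analytic_rmst(24.0, bks_e, rts_e, cf) / analytic_rmst(
                24.0, bks_c, rts_c
            )
            row["true_ratio_milestone_12"] = analytic_milestone(
                12.0, bks_e, rts_e, cf
            ) / analytic_milestone(12.0, bks_c, rts_c)
            rows.append(row)

    comparison_table = pd.DataFrame(rows)
    return suites, comparison_table


def digitize_emulator(
    curve: sv.SurvivalCurve, n_points: int, jitter_sd: float, seed: int
) -> DigitizedCurve:
    """Emulate manual digitization of a published Kaplan–Meier figure.

    Coordinates are placed at uniform time quantiles of the curve's support
    (plus every step corner when ``n_points`` exceeds the corner count and
    ``jitter_sd == 0``, making the sampling lossless), survival values get
    truncated Gaussian noise, and the point order is lightly shuffled to
    exercise downstream cleaning.
    """
    if n_points < 2:
        raise ValueError("need at least 2 digitized points")
    rng = np.random.default_rng(seed)
    t_grid = np.linspace(0.0, curve.max_follow_up, n_points)
    if jitter_sd == 0:
        # lossless mode: include the exact step corners
        corners = curve.to_step_points()[:, 0]
        t_grid = np.unique(np.concatenate([t_grid, corners]))
    s_vals = np.array([curve.survival_at(t) for t in t_grid])
    if jitter_sd > 0:
        s_vals = np.clip(s_vals + rng.normal(0.0, jitter_sd, size=s_vals.size), 0.0, 1.0)
    pts = np.column_stack([t_grid, s_vals])
    # light shuffling: swap a few adjacent pairs
    n_swaps = max(1, len(pts) // 20)
    for _ in range(n_swaps):
        i = int(rng.integers(0, len(pts) - 1))
        pts[[i, i + 1]] = pts[[i + 1, i]]
    return DigitizedCurve(points=pts, n_arm=curve.n_total, max_follow_up=curve.max_follow_up)
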