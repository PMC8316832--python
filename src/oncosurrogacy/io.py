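"""File schemas, configuration, and the end-to-end pipeline.

All tables are comma-delimited UTF-8 with a header row; missing values are
empty fields.  A YAML manifest ties a run together: the trial metadata
table, a comparison-level effects table (hazard ratios and response
counts, which figures cannot provide), and one digitized coordinate file
per arm for the curve-derived measures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import DigitizedCurve, clean_curve, milestone_from_curve, rmst_from_curve
from .surrogacy import (
    SURROGATE_FIELDS,
    effect_ratio,
    evaluate_all,
    results_to_frame,
    rr_from_counts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrialMeta",
    "RunConfig",
    "load_trials",
    "load_example_trials",
    "trials_summary",
    "load_curve",
    "load_comparisons",
    "load_arm_table",
    "pair_arms",
    "run_pipeline",
]

_TRIAL_COLUMNS = [
    "trial_id",
    "phase",
    "n_patients",
    "n_arms",
    "experimental_arms",
    "control_arm",
    "primary_endpoint",
    "response_criteria",
]


@dataclass(frozen=True)
class TrialMeta:
    """Basic information of one included randomized trial."""

    trial_id: str
    phase: str
    n_patients: int
    n_arms: int
    experimental_arms: str  # labels, ';'-separated for multi-arm trials
    control_arm: str
    primary_endpoint: str
    response_criteria: str


def load_trials(path) -> list[TrialMeta]:
    """Read and validate a trial metadata CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no trials in table")
    dupes = df["trial_id"][df["trial_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicated trial_id: {dupes}")
    trials = []
    for i, row in df.iterrows():
        for col in ("n_patients", "n_arms"):
            try:
                val = int(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"row {i} ({row['trial_id']}): non-numeric {col}: {row[col]!r}")
            if (col == "n_patients" and val <= 0) or (col == "n_arms" and val < 2):
                raise ValueError(f"row {i} ({row['trial_id']}): invalid {col}: {val}")
        trials.append(
            TrialMeta(
                trial_id=str(row["trial_id"]),
                phase=str(row["phase"]),
                n_patients=int(row["n_patients"]),
                n_arms=int(row["n_arms"]),
                experimental_arms=str(row["experimental_arms"]),
                control_arm=str(row["control_arm"]),
                primary_endpoint=str(row["primary_endpoint"]),
                response_criteria=str(row["response_criteria"]),
            )
        )
    return trials


def load_example_trials() -> list[TrialMeta]:
    """The bundled table of the seven first-line immunotherapy ES-SCLC trials."""
    with resources.as_file(
        resources.files("oncosurrogacy.datasets") / "es_sclc_firstline_trials.csv"
    ) as p:
        return load_trials(p)


def trials_summary(trials: list[TrialMeta]) -> dict:
    """Bookkeeping totals: patients, arms, and pairwise comparisons.

    Every experimental arm is contrasted with its trial's shared control
    arm, so a k-arm trial contributes k - 1 comparisons.
    """
    return {
        "n_trials": len(trials),
        "total_patients": sum(t.n_patients for t in trials),
        "total_arms": sum(t.n_arms for t in trials),
        "n_comparisons": sum(t.n_arms - 1 for t in trials),
    }


def load_curve(path, n_arm: int | None = None) -> DigitizedCurve:
    """Read a two-column (time_months, survival) coordinate file."""
    df = pd.read_csv(path)
    for col in ("time_months", "survival"):
        if col not in df.columns:
            raise ValueError(f"coordinate file {path}: missing column {col!r}")
    return DigitizedCurve(
        points=df[["time_months", "survival"]].to_numpy(dtype=float), n_arm=n_arm
    )


_COMPARISON_REQUIRED = ["trial_id", "experimental_arm_id", "control_arm_id", "n_total", "hr_os"]


def load_comparisons(path) -> pd.DataFrame:
    """Read a comparison-level effects CSV (one row per contrast)."""
    df = pd.read_csv(path)
    missing = [c for c in _COMPARISON_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"comparison table missing columns: {missing}")
    for col in SURROGATE_FIELDS:
        if col not in df.columns:
            df[col] = np.nan
    bad = df["hr_os"].isna() | (df["hr_os"] <= 0)
    if bad.any():
        raise ValueError(f"non-positive or missing hr_os in rows {list(df.index[bad])}")
    return df


def load_arm_table(path) -> pd.DataFrame:
    """Read an arm-level effects CSV (one row per arm, supplementary-table style).

    Required: trial_id, arm_id, role (experimental|control), n.  Effect
    columns (hr_os, hr_pfs on experimental rows; milestone_12, rmst_12,
    rmst_24, responders_orr, responders_dcr on all rows) are optional and
    empty where unavailable.
    """
    df = pd.read_csv(path)
    for col in ("trial_id", "arm_id", "role", "n"):
        if col not in df.columns:
            raise ValueError(f"arm table missing column {col!r}")
    bad_role = ~df["role"].isin(["experimental", "control"])
    if bad_role.any():
        raise ValueError(f"invalid role in rows {list(df.index[bad_role])}")
    return df


def pair_arms(arm_df: pd.DataFrame) -> pd.DataFrame:
    """Pair experimental arms with their trial's control arm into comparisons.

    Ratios of milestone rates and RMSTs, and relative risks from response
    counts, are computed experimental / control; measures missing in either
    arm are left empty (complete-case handling happens per surrogate later).
    """
    rows = []
    for trial_id, grp in arm_df.groupby("trial_id", sort=False):
        ctrl = grp[grp["role"] == "control"]
        if len(ctrl) != 1:
            raise ValueError(f"trial {trial_id}: expected exactly one control arm, got {len(ctrl)}")
        ctrl = ctrl.iloc[0]
        for _, exp in grp[grp["role"] == "experimental"].iterrows():
            row = {
                "trial_id": trial_id,
                "experimental_arm_id": exp["arm_id"],
                "control_arm_id": ctrl["arm_id"],
                "n_total": int(exp["n"]) + int(ctrl["n"]),
                "hr_os": exp.get("hr_os", np.nan),
                "hr_pfs": exp.get("hr_pfs", np.nan),
            }

            def _ratio(col):
                ev, cv = exp.get(col, np.nan), ctrl.get(col, np.nan)
                if pd.isna(ev) or pd.isna(cv):
                    return np.nan
                return effect_ratio(float(ev), float(cv))

            row["ratio_milestone_12"] = _ratio("milestone_12")
            row["ratio_rmst_12"] = _ratio("rmst_12")
            row["ratio_rmst_24"] = _ratio("rmst_24")
            for rr_col, cnt_col in (("rr_orr", "responders_orr"), ("rr_dcr", "responders_dcr")):
                ev, cv = exp.get(cnt_col, np.nan), ctrl.get(cnt_col, np.nan)
                if pd.isna(ev) or pd.isna(cv):
                    row[rr_col] = np.nan
                else:
                    rr = rr_from_counts(int(ev), int(exp["n"]), int(cv), int(ctrl["n"]))
                    row[rr_col] = rr if rr > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Knobs of one analysis run."""

    tau_milestone: float = 12.0
    tau_rmst: tuple = (12.0, 24.0)
    log_base: float = 10.0
    weight_column: str = "n_total"
    integration_mode: str = "step"  # or "trapezoid"
    ci_level: float = 0.95
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.tau_milestone <= 0 or any(t <= 0 for t in self.tau_rmst):
            raise ValueError("milestone/RMST horizons must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.integration_mode not in ("step", "trapezoid"):
            raise ValueError("integration_mode must be 'step' or 'trapezoid'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tau_rmst" in data:
            data["tau_rmst"] = tuple(data["tau_rmst"])
        return cls(**data)


def run_pipeline(config: RunConfig, manifest_path) -> dict:
    """Run the full analysis described by a manifest.

    The manifest (YAML) names the trial table, the comparison-level effects
    table, and per-arm digitized OS coordinate files::

        trials: trials.csv
        effects: effects.csv
        curves:
          - {trial_id: SIM01, arm_id: exp1, endpoint: OS, file: sim01_exp1.csv}

    Stages: curve cleaning -> milestone/RMST extraction -> comparison
    assembly -> surrogacy evaluation.  Writes comparisons.csv, results.csv,
    report.txt and results.json into ``config.output_dir``; every exclusion
    decision is logged.  Any stage error aborts the run and removes partial
    outputs.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        trials = load_trials(base / manifest["trials"])
        summary = trials_summary(trials)
        log(f"stage=load_trials {summary}")

        comparisons = load_comparisons(base / manifest["effects"])
        log(f"stage=load_effects n_comparisons={len(comparisons)}")

        # curve-derived measures per (trial, arm)
        arm_measures: dict[tuple[str, str], dict] = {}
        for entry in manifest.get("curves", []):
            if entry.get("endpoint", "OS") != "OS":
                continue
            key = (str(entry["trial_id"]), str(entry["arm_id"]))
            curve = clean_curve(load_curve(base / entry["file"]))
            meas: dict = {}
            try:
                meas[f"milestone_{config.tau_milestone:g}"] = milestone_from_curve(
                    curve, config.tau_milestone
                ).rate
            except ValueError as exc:
                log(f"stage=milestone trial={key[0]} arm={key[1]} excluded: {exc}")
            for tau in config.tau_rmst:
                try:
                    meas[f"rmst_{tau:g}"] = rmst_from_curve(
                        curve, tau, mode=config.integration_mode
                    ).value
                except ValueError as exc:
                    log(f"stage=rmst trial={key[0]} arm={key[1]} tau={tau:g} excluded: {exc}")
            arm_measures[key] = meas
        log(
            f"stage=curves n_arms={len(arm_measures)} "
            f"integration_mode={config.integration_mode}"
        )
        if arm_measures and all(not m for m in arm_measures.values()):
            raise ValueError(
                "horizon beyond digitized range: no curve supports the configured horizons"
            )

        if arm_measures:
            for i, row in comparisons.iterrows():
                exp_key = (str(row["trial_id"]), str(row["experimental_arm_id"]))
                ctl_key = (str(row["trial_id"]), str(row["control_arm_id"]))
                pairs = [
                    (f"milestone_{config.tau_milestone:g}", "ratio_milestone_12"),
                    ("rmst_12", "ratio_rmst_12"),
                    ("rmst_24", "ratio_rmst_24"),
                ]
                # curve-derived ratios are authoritative once curves are given:
                # a horizon an arm's curve cannot support clears the value, so
                # that comparison drops out of that surrogate's fit only
                for src, dst in pairs:
                    ev = arm_measures.get(exp_key, {}).get(src)
                    cv = arm_measures.get(ctl_key, {}).get(src)
                    if ev is not None and cv is not None and ev > 0 and cv > 0:
                        comparisons.loc[i, dst] = effect_ratio(ev, cv)
                    else:
                        comparisons.loc[i, dst] = np.nan
                        log(
                            f"stage=assemble trial={row['trial_id']} "
                            f"arm={row['experimental_arm_id']} {dst} unavailable from "
                            "curves, comparison excluded from that surrogate"
                        )

        results = evaluate_all(
            comparisons, log_base=config.log_base, weights=config.weight_column
        )
        for r in results:
            log(
                f"stage=surrogacy surrogate={r.surrogate_name} n={r.n_comparisons} "
                f"r={r.spearman_r:.3f} R2={r.r_squared:.3f}"
            )

        comp_path = out_dir / "comparisons.csv"
        comparisons.to_csv(comp_path, index=False)
        written.append(comp_path)
        res_frame = results_to_frame(results)
        res_path = out_dir / "results.csv"
        res_frame.to_csv(res_path, index=False)
        written.append(res_path)

        report_path = out_dir / "report.txt"
        with open(report_path, "w") as fh:
            fh.write("Trial-level surrogacy report\n")
            fh.write(f"{summary['n_trials']} trials, {summary['total_patients']} patients, ")
            fh.write(f"{summary['total_arms']} arms, {summary['n_comparisons']} comparisons\n\n")
            for r in results:
                fh.write(r.summary() + "\n\n")
            fh.write("Run log\n-------\n")
            fh.write("\n".join(log_lines) + "\n")
        written.append(report_path)

        json_path = out_dir / "results.json"
        with open(json_path, "w") as fh:
            json.dump(
                {"summary": summary, "results": [r.to_dict() for r in results]},
                fh,
                indent=2,
            )
        written.append(json_path)

        return {
            "summary": summary,
            "comparisons": comparisons,
            "results": results,
            "log": log_lines,
            "outputs": [str(p) for p in written],
        }
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline aborted: {exc}") from exc
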