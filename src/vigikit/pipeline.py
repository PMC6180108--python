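"""End-to-end study replica: cohort -> staging -> metrics -> statistics.

``run_study`` reproduces the structure of a two-day sleep-deprivation study
report: a baseline-characteristics table (groups compared by t-test and
chi-square), a mixed repeated-measures ANOVA on per-minute Mean Vigilance
Values (group x day x recording minute), nonparametric post-hocs on the
Arousal Stability Score at the alpha-adjusted 0.025 level, and a mood /
sleepiness table.  Input is either a synthetic cohort specification or a
manifest of EDF/BrainVision files plus a clinical CSV.

Per-recording staging failures never abort a run: the recording is excluded
and counted, with the reason in the run log.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as vstats
from .clinical import split_cohort
from .cohort import DAYS, Cohort, CohortSpec, generate_cohort
from .metrics import compute_metrics, mean_vigilance_value
from .staging import StagingConfig, classify_recording
from .stages import STAGE_ORDER

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec.default)
    staging_mode: str = "classify"      # "classify" (synthesize + stage the EEG)
                                        # or "ground_truth" (use true sequences)
    staging: StagingConfig = field(default_factory=StagingConfig)
    ass_strict: bool = True
    level1_rule: str = "fraction"
    alpha_omnibus: float = vstats.ALPHA_OMNIBUS
    alpha: float = 0.05
    make_figures: bool = False

    def validate(self) -> None:
        if self.staging_mode not in ("classify", "ground_truth"):
            raise ValueError("staging_mode must be 'classify' or 'ground_truth'")
        if self.level1_rule not in ("fraction", "literal"):
            raise ValueError("level1_rule must be 'fraction' or 'literal'")
        self.cohort.validate()


@dataclass
class StudyResult:
    """Report bundle produced by :func:`run_study`."""

    metrics: pd.DataFrame            # one row per (subject, day)
    mvv_minutes: pd.DataFrame        # per-minute MVV, long format
    clinical: pd.DataFrame
    tables: dict                     # name -> DataFrame
    exclusions: list
    runlog: dict

    def write(self, outdir) -> None:
        """Write the canonical CSV outputs (+ optional figures) deterministically."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.6g")
        self.metrics.to_csv(out / "metrics.csv", **kw)
        self.mvv_minutes.to_csv(out / "mvv_per_minute.csv", **kw)
        self.clinical.to_csv(out / "clinical.csv", **kw)
        for name, tbl in self.tables.items():
            if isinstance(tbl, pd.DataFrame):
                tbl.to_csv(out / f"table_{name}.csv", **kw)
        log = {k: v for k, v in self.runlog.items() if k != "elapsed_s"}
        with open(out / "runlog.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)


def _not_applicable(reason: str) -> pd.DataFrame:
    return pd.DataFrame([{"status": "not applicable", "reason": reason}])


def _safe(table_fn, reason: str):
    try:
        return table_fn()
    except (ValueError, ZeroDivisionError, KeyError, AttributeError) as exc:
        return _not_applicable(f"{reason}: {exc}")


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full study replica and return the report bundle."""
    config.validate()
    t0 = time.time()
    cohort = generate_cohort(config.cohort)
    clinical = cohort.clinical_frame()
    exclusions: list[dict] = []

    rows, minute_rows = [], []
    for subj in cohort.subjects:
        for day in DAYS:
            key = (subj.id, day)
            try:
                if config.staging_mode == "classify":
                    rec = cohort.recording(subj.id, day)
                    tc = classify_recording(rec, config.staging)
                else:
                    tc = cohort.sequences[key]
                m = compute_metrics(tc, strict_duration=config.ass_strict,
                                    level1_rule=config.level1_rule)
            except Exception as exc:  # failed analysis -> excluded, not fatal
                exclusions.append({"subject": subj.id, "day": day,
                                   "reason": f"{type(exc).__name__}: {exc}"})
                continue
            row = {"subject": subj.id, "group": subj.group, "status": subj.status,
                   "day": day, "mvv": m.mvv, "ass": m.ass,
                   "n_artifact": m.n_artifact}
            for s in STAGE_ORDER:
                row[f"pct_{s.value}"] = m.percentages[s.value]
            rows.append(row)
            for minute, v in enumerate(m.mvv_per_minute, start=1):
                minute_rows.append({"subject": subj.id, "group": subj.group,
                                    "status": subj.status, "day": day,
                                    "minute": minute, "mvv": v})

    metrics = pd.DataFrame(rows)
    mvv_minutes = pd.DataFrame(minute_rows)
    tables: dict[str, pd.DataFrame] = {}

    # --- baseline characteristics (patients vs controls) ---------------
    def baseline_table() -> pd.DataFrame:
        pat = clinical[clinical.group == "patient"]
        con = clinical[clinical.group == "control"]
        if len(pat) < 2 or len(con) < 2:
            raise ValueError("needs >= 2 patients and >= 2 controls")
        out = []
        for var in ("age", "hdrs17_baseline", "ids_c"):
            r = vstats.welch_t_from_summary(
                pat[var].mean(), pat[var].std(ddof=1), len(pat),
                con[var].mean(), con[var].std(ddof=1), len(con))
            out.append({"variable": var, "test": r.name,
                        "patients_mean": pat[var].mean(), "patients_sd": pat[var].std(ddof=1),
                        "controls_mean": con[var].mean(), "controls_sd": con[var].std(ddof=1),
                        "statistic": r.statistic, "df": r.df, "p": r.p})
        chi = vstats.chi_square_2x2(
            (pat.sex == "m").sum(), (pat.sex == "f").sum(),
            (con.sex == "m").sum(), (con.sex == "f").sum())
        out.append({"variable": "sex (m/f)", "test": chi.name,
                    "statistic": chi.statistic, "df": chi.df, "p": chi.p})
        return pd.DataFrame(out)

    tables["baseline_characteristics"] = _safe(baseline_table, "group comparison")

    # --- responder split ------------------------------------------------
    try:
        split = split_cohort(cohort.subjects)
        tables["responder_descriptives"] = pd.concat(
            {k: v for k, v in split["tables"].items()}, names=["group"]
        ).reset_index(level=0).rename(columns={"level_0": "group"})
        resp_counts = {"n_responders": split["n_responders"],
                       "n_non_responders": split["n_non_responders"]}
    except ValueError as exc:
        tables["responder_descriptives"] = _not_applicable(str(exc))
        resp_counts = {}

    # --- mixed rm-ANOVA on per-minute MVV -------------------------------
    def anova_table() -> pd.DataFrame:
        d = mvv_minutes.dropna(subset=["mvv"])
        tbl = vstats.mixed_rm_anova(d, dv="mvv", subject="subject",
                                    within=["day", "minute"], between="group")
        tbl["alpha"] = config.alpha_omnibus
        tbl["significant"] = tbl["p_reported"] < config.alpha_omnibus
        return tbl

    tables["anova_mvv"] = _safe(anova_table, "mixed rm-ANOVA on MVV")

    # --- ASS nonparametric post-hocs ------------------------------------
    def ass_table() -> pd.DataFrame:
        out = []
        for day in DAYS:
            sub = metrics[metrics.day == day]
            a = sub.loc[sub.group == "patient", "ass"]
            b = sub.loc[sub.group == "control", "ass"]
            if len(a) and len(b):
                r = vstats.mann_whitney_u(a, b)
                out.append({"comparison": f"patients vs controls ({day})",
                            "test": r.name, "statistic": r.statistic, "p": r.p,
                            "median_patients": a.median(), "median_controls": b.median(),
                            "alpha": config.alpha_omnibus, "note": r.note})
        for grp in ("patient", "control"):
            wide = metrics[metrics.group == grp].pivot(index="subject",
                                                       columns="day", values="ass")
            if set(DAYS) <= set(wide.columns) and len(wide.dropna()) >= 2:
                w = wide.dropna()
                r = vstats.wilcoxon_signed_rank(w["baseline"], w["post"])
                out.append({"comparison": f"{grp}s: baseline vs post",
                            "test": r.name, "statistic": r.statistic, "p": r.p,
                            "alpha": config.alpha_omnibus, "note": r.note})
        if not out:
            raise ValueError("no comparable groups")
        return pd.DataFrame(out)

    tables["ass_posthocs"] = _safe(ass_table, "ASS post-hocs")

    # --- mood / sleepiness table ----------------------------------------
    def mood_table() -> pd.DataFrame:
        pat = clinical[clinical.group == "patient"]
        con = clinical[clinical.group == "control"]
        out = []
        for var, label in (("hdrs_bech_baseline", "HDRS_Bech baseline"),
                           ("sss_baseline", "SSS baseline"),
                           ("sss_post", "SSS after PSD")):
            a, b = pat[var].dropna(), con[var].dropna()
            if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
                r = vstats.welch_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                                b.mean(), b.std(ddof=1), len(b))
                out.append({"variable": label, "comparison": "patients vs controls",
                            "test": r.name, "statistic": r.statistic,
                            "df": r.df, "p": r.p})
        both = pat.dropna(subset=["hdrs_bech_baseline", "hdrs_bech_post"])
        if len(both) >= 2:
            try:
                r = vstats.paired_t(both["hdrs_bech_baseline"], both["hdrs_bech_post"])
                out.append({"variable": "HDRS_Bech", "comparison":
                            "patients: baseline vs after PSD", "test": r.name,
                            "statistic": r.statistic, "df": r.df, "p": r.p})
            except ValueError:
                pass
        rn = clinical[clinical.responder.notna()] if "responder" in clinical else clinical
        resp = rn[rn.responder == True]          # noqa: E712
        nonr = rn[rn.responder == False]         # noqa: E712
        for var, label in (("hdrs_bech_baseline", "HDRS_Bech baseline"),
                           ("hdrs_bech_post", "HDRS_Bech after PSD")):
            a, b = resp[var].dropna(), nonr[var].dropna()
            if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
                r = vstats.pooled_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                                 b.mean(), b.std(ddof=1), len(b))
                out.append({"variable": label,
                            "comparison": "responders vs non-responders",
                            "test": r.name, "statistic": r.statistic,
                            "df": r.df, "p": r.p})
        if not out:
            raise ValueError("insufficient clinical data")
        return pd.DataFrame(out)

    tables["mood_sleepiness"] = _safe(mood_table, "mood/sleepiness comparisons")

    runlog = {
        "seed": config.cohort.seed,
        "staging_mode": config.staging_mode,
        "n_subjects": len(cohort.subjects),
        "n_recordings_analysed": len(metrics),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "ass_strict": config.ass_strict,
        "level1_rule": config.level1_rule,
        "alpha_omnibus": config.alpha_omnibus,
        "duration_s": config.cohort.duration_s,
        "fs": config.cohort.fs,
        "elapsed_s": round(time.time() - t0, 2),
        **resp_counts,
    }

    result = StudyResult(metrics=metrics, mvv_minutes=mvv_minutes,
                         clinical=clinical, tables=tables,
                         exclusions=exclusions, runlog=runlog)
    return result


def make_figures(result: StudyResult, outdir) -> list:
    """Optional figures: stage composition over minutes, and median ASS by day."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, grp in zip(axes, ("patient", "control")):
        sub = result.mvv_minutes[(result.mvv_minutes.group == grp)]
        for day in sorted(sub.day.unique()):
            m = sub[sub.day == day].groupby("minute")["mvv"].mean()
            ax.plot(m.index, m.values, label=day)
        ax.set_title(grp + "s")
        ax.set_xlabel("recording minute")
    axes[0].set_ylabel("mean vigilance value")
    axes[0].legend()
    p1 = out / "mvv_timecourse.png"
    fig.savefig(p1, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p1)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    med = result.metrics.groupby(["group", "day"])["ass"].median().unstack()
    med.plot.bar(ax=ax, rot=0)
    ax.set_ylabel("median arousal stability score")
    p2 = out / "ass_medians.png"
    fig.savefig(p2, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p2)
    return written
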