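"""Multi-disease attribution survey over subject + diagnosis tables.

Emulates a biobank-style study design: for each disease code, the outcome is
the *first* incidence in the code's ICD-10 chapter; subjects whose first
chapter event predates study entry are excluded, as are subjects with
qualifying prior diagnoses (e.g. cancer other than non-melanoma skin
cancer); follow-up is right-censored at death, at a qualifying exclusion
diagnosis, or at the administrative study end. Each code x sex stratum is
fitted with the multiply-adjusted proportional-hazards model and three
attribution contrasts are computed from the single fit: smoking-only,
BMI-only, and smoking+BMI jointly as the exposure set (other modelled
covariates become W). Diseases enter the reported landscape if either of the
two named Wald contrasts (current-vs-never smoking, top-vs-middle BMI
tertile) survives a Benjamini-Hochberg FDR adjustment; records are ranked and
tiered by attribution fraction, and chapter medians are summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .attribution import af_backdoor, attributed_cases
from .model_spec import CategoricalCoding, CovariateRoles, complete_cases
from .ph_fit import fit_ph, linear_predictors

__all__ = [
    "SurveyConfig",
    "derive_first_incidence",
    "min_case_filter",
    "fdr_select",
    "joint_inclusion",
    "rank_and_tier",
    "chapter_summary",
    "run_survey",
    "sensitivity_rerun",
]

TIER_LABELS = (">=0.5", "0.35-0.5", "0.2-0.35", "-0.2-0.2", "<=-0.2")


@dataclass(frozen=True)
class SurveyConfig:
    """Study-design knobs for the landscape survey."""

    min_cases: int = 140
    fdr_level: float = 0.05
    censor_age: float = 80.0
    # prior diagnoses with these code prefixes exclude a subject / censor follow-up
    exclusion_prefixes: tuple[str, ...] = ("C",)
    exclusion_exempt: tuple[str, ...] = ("C44",)  # non-melanoma skin cancer
    # named Wald contrasts driving FDR inclusion: design-column names
    smoking_contrast: str = "smoking=current"
    bmi_contrast: str = "bmi=T3"
    smoking_exposures: tuple[str, ...] = ("smoking",)
    bmi_exposures: tuple[str, ...] = ("bmi",)
    sexes: tuple[str, ...] = ("F", "M")

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("minimum case count must be >= 1")
        if not 0 < self.fdr_level < 1:
            raise ValueError("FDR level must lie in (0, 1)")

    @property
    def joint_exposures(self) -> tuple[str, ...]:
        return self.smoking_exposures + self.bmi_exposures


def _is_excluded_code(codes: pd.Series, config: SurveyConfig) -> np.ndarray:
    hit = np.zeros(len(codes), dtype=bool)
    for pref in config.exclusion_prefixes:
        hit |= codes.str.startswith(pref).to_numpy()
    for pref in config.exclusion_exempt:
        hit &= ~codes.str.startswith(pref).to_numpy()
    return hit


def derive_first_incidence(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    code: str,
    config: SurveyConfig,
) -> pd.DataFrame:
    """Per-subject (entry_age, exit_age, event) outcome for one disease code.

    The earliest diagnosis in the code's chapter defines the chapter-first
    age. Exclusions: chapter-first before study entry; any qualifying prior
    diagnosis (exclusion prefixes) before entry. Censoring: death (optional
    ``death_age`` column), first qualifying exclusion diagnosis after entry,
    administrative study end. When ages tie, censoring causes take precedence
    over the event (death > exclusion diagnosis > study end > event), so an
    event is counted only when strictly earlier than every censoring age.
    A first-in-chapter diagnosis with a *different* code censors follow-up at
    that age (the subject can no longer have ``code`` as chapter-first).
    """
    chapters = events.loc[events["code"] == code, "chapter"].unique()
    if len(chapters) == 0:
        raise ValueError(f"unknown code {code!r}: no events carry it")
    chapter = chapters[0]

    ev = events
    chap_ev = ev[ev["chapter"] == chapter]
    first_in_chapter = (
        chap_ev.sort_values(["subject_id", "diagnosis_age", "code"], kind="mergesort")
        .groupby("subject_id", sort=True)
        .first()[["code", "diagnosis_age"]]
    )

    out = subjects[["subject_id", "entry_age"]].copy()
    out = out.merge(
        first_in_chapter.rename(
            columns={"code": "fc_code", "diagnosis_age": "fc_age"}
        ),
        left_on="subject_id",
        right_index=True,
        how="left",
    )

    # prior-exclusion diagnoses (e.g. cancer) and post-entry censoring ages
    excl = ev[_is_excluded_code(ev["code"], config) & (ev["chapter"] != chapter)]
    if len(excl):
        first_excl = excl.groupby("subject_id")["diagnosis_age"].min()
        out = out.merge(first_excl.rename("excl_age"), left_on="subject_id",
                        right_index=True, how="left")
    else:
        out["excl_age"] = np.nan

    excluded = (out["fc_age"] <= out["entry_age"]) | (
        out["excl_age"] <= out["entry_age"]
    )
    out = out[~excluded.fillna(False)].copy()

    censor = np.full(len(out), config.censor_age)
    if "death_age" in subjects.columns:
        death = subjects.set_index("subject_id")["death_age"].reindex(out["subject_id"]).to_numpy()
        censor = np.fmin(censor, death)
    censor = np.fmin(censor, out["excl_age"].to_numpy())

    fc_age = out["fc_age"].to_numpy()
    is_target = (out["fc_code"] == code).to_numpy()
    has_event = is_target & (fc_age < censor) & ~np.isnan(fc_age)
    # chapter-first of another code ends time at risk (censoring)
    other_first = ~is_target & ~np.isnan(fc_age)
    exit_age = np.where(has_event, fc_age, np.where(other_first, np.fmin(fc_age, censor), censor))

    res = pd.DataFrame(
        {
            "subject_id": out["subject_id"].to_numpy(),
            "entry_age": out["entry_age"].to_numpy(),
            "exit_age": exit_age,
            "event": has_event.astype(int),
        }
    )
    res = res[res["exit_age"] > res["entry_age"]].reset_index(drop=True)
    return res


def min_case_filter(records: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Keep records with at least ``threshold`` cases."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return records[records["n_cases"] >= threshold].reset_index(drop=True)


def fdr_select(pvalues: Sequence[float], level: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (selection mask, monotone q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, q


def joint_inclusion(smoking_mask: np.ndarray, bmi_mask: np.ndarray) -> np.ndarray:
    """Joint-analysis inclusion: selected by either single-exposure screen."""
    smoking_mask = np.asarray(smoking_mask, dtype=bool)
    bmi_mask = np.asarray(bmi_mask, dtype=bool)
    if smoking_mask.shape != bmi_mask.shape:
        raise ValueError("mask length mismatch")
    return smoking_mask | bmi_mask


def _tier(af: float) -> str:
    if af >= 0.5:
        return TIER_LABELS[0]
    if af >= 0.35:
        return TIER_LABELS[1]
    if af >= 0.2:
        return TIER_LABELS[2]
    if af > -0.2:
        return TIER_LABELS[3]
    return TIER_LABELS[4]


def rank_and_tier(records: pd.DataFrame, af_col: str = "af_joint") -> pd.DataFrame:
    """Add tier labels plus ranks by A_f and by |attributed cases|.

    Rank 1 is the largest A_f (respectively largest |N_Af|); ties break by
    code string for determinism.
    """
    rec = records.copy()
    rec["tier"] = rec[af_col].map(_tier)
    order_af = rec.sort_values([af_col, "code"], ascending=[False, True], kind="mergesort").index
    rec.loc[order_af, "rank_af"] = np.arange(1, len(rec) + 1)
    naf = rec["n_attributed"].abs()
    order_naf = (
        rec.assign(_naf=naf)
        .sort_values(["_naf", "code"], ascending=[False, True], kind="mergesort")
        .index
    )
    rec.loc[order_naf, "rank_naf"] = np.arange(1, len(rec) + 1)
    rec["rank_af"] = rec["rank_af"].astype(int)
    rec["rank_naf"] = rec["rank_naf"].astype(int)
    return rec


def chapter_summary(
    records: pd.DataFrame,
    af_col: str = "af_joint",
    min_diseases: int = 5,
    af_floor: float = 0.2,
) -> pd.DataFrame:
    """Per-chapter median A_f over diseases with A_f above ``af_floor``.

    A chapter is retained only when at least ``min_diseases`` of its member
    diseases exceed the floor; the returned disease count doubles as
    bar-width metadata for plotting.
    """
    rows = []
    for chapter, grp in records.groupby("chapter"):
        member = grp[grp[af_col] > af_floor]
        if len(member) >= min_diseases:
            rows.append(
                {
                    "chapter": chapter,
                    "median_af": float(member[af_col].median()),
                    "n_diseases": int(len(member)),
                }
            )
    out = pd.DataFrame(rows, columns=["chapter", "median_af", "n_diseases"])
    return out.sort_values("median_af", ascending=False).reset_index(drop=True)


def plot_chapter_medians(summary: pd.DataFrame, path) -> None:
    """Bar plot of per-chapter median fractions; bar width tracks the number
    of member diseases."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if len(summary):
        widths = 0.8 * summary["n_diseases"] / summary["n_diseases"].max()
        x = np.arange(len(summary), dtype=float)
        ax.bar(x, summary["median_af"], width=widths)
        ax.set_xticks(x)
        ax.set_xticklabels(summary["chapter"])
    ax.set_xlabel("ICD-10 chapter")
    ax.set_ylabel("median attribution fraction")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _fit_one(
    subjects: pd.DataFrame,
    outcome: pd.DataFrame,
    roles: CovariateRoles,
    coding: CategoricalCoding,
    config: SurveyConfig,
):
    """Fit one code x sex stratum; returns None below the case threshold."""
    cohort = subjects.merge(outcome, on="subject_id", suffixes=("", "_y"))
    if "entry_age_y" in cohort.columns:
        cohort = cohort.drop(columns=["entry_age_y"])
    cohort = complete_cases(cohort, roles.all_covariates)
    n_cases = int(cohort["event"].sum())
    if n_cases < config.min_cases:
        return None
    fit = fit_ph(cohort, roles, coding)
    if not fit.converged:
        return None
    row = {"n_cases": n_cases, "n_subjects": len(cohort)}
    for contrast, col in (
        ("smoking", config.smoking_contrast),
        ("bmi", config.bmi_contrast),
    ):
        row[f"p_{contrast}"] = (
            fit.wald_p(col) if col in fit.p_values.index else np.nan
        )
    for label, exposures in (
        ("smoking", config.smoking_exposures),
        ("bmi", config.bmi_exposures),
        ("joint", config.joint_exposures),
    ):
        contrast_roles = roles.with_exposures(
            [e for e in exposures if e in roles.all_covariates]
        )
        lp = linear_predictors(fit, cohort, contrast_roles, coding)
        row[f"af_{label}"] = af_backdoor(lp).estimate
    row["n_attributed"] = attributed_cases(row["af_joint"], n_cases)
    return row


def run_survey(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    roles: CovariateRoles,
    coding: CategoricalCoding,
    config: SurveyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end landscape survey.

    Per code x sex: derive the chapter-first outcome, fit the adjusted
    proportional-hazards model, compute the three attribution contrasts,
    BH-select on the two named Wald contrasts, pool inclusion, rank and tier,
    and summarise chapters. Returns ``(records, chapter_summary)``;
    deterministic given inputs.
    """
    config = config or SurveyConfig()
    codes = sorted(events["code"].unique())
    rows = []
    for code in codes:
        try:
            outcome_all = derive_first_incidence(subjects, events, code, config)
        except ValueError as exc:
            raise ValueError(f"while deriving outcome for {code!r}: {exc}") from exc
        chapter = events.loc[events["code"] == code, "chapter"].iloc[0]
        for sex in config.sexes:
            sub = subjects[subjects["sex"] == sex] if "sex" in subjects.columns else subjects
            if len(sub) == 0:
                continue
            sex_roles = roles
            try:
                row = _fit_one(sub, outcome_all, sex_roles, coding, config)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(f"survey failed for code {code!r}, sex {sex!r}: {exc}") from exc
            if row is None:
                continue
            row.update({"code": code, "chapter": chapter, "sex": sex})
            rows.append(row)
    records = pd.DataFrame(rows)
    if len(records) == 0:
        return records, pd.DataFrame(columns=["chapter", "median_af", "n_diseases"])
    for contrast in ("smoking", "bmi"):
        p = records[f"p_{contrast}"].to_numpy()
        ok = ~np.isnan(p)
        sel = np.zeros(len(records), dtype=bool)
        q = np.full(len(records), np.nan)
        if ok.any():
            sel[ok], q[ok] = fdr_select(p[ok], config.fdr_level)
        records[f"sel_{contrast}"] = sel
        records[f"q_{contrast}"] = np.fmax(q, p)  # q-values never below p
    records["included"] = joint_inclusion(
        records["sel_smoking"].to_numpy(), records["sel_bmi"].to_numpy()
    )
    records = rank_and_tier(records)
    summary = chapter_summary(records[records["included"]])
    ordered = [
        "code", "chapter", "sex", "n_cases", "n_subjects",
        "af_smoking", "af_bmi", "af_joint", "n_attributed",
        "p_smoking", "q_smoking", "sel_smoking",
        "p_bmi", "q_bmi", "sel_bmi", "included", "tier", "rank_af", "rank_naf",
    ]
    records = records[[c for c in ordered if c in records.columns]]
    return records, summary


def sensitivity_rerun(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    roles: CovariateRoles,
    coding: CategoricalCoding,
    config_main: SurveyConfig,
    config_sensitivity: SurveyConfig,
) -> dict:
    """Re-run the survey under stricter exclusions and summarise A_f shifts.

    Returns the two record tables, the per-disease joint-A_f differences
    (sensitivity minus main) and their mean/median/SD.
    """
    rec_main, _ = run_survey(subjects, events, roles, coding, config_main)
    rec_sens, _ = run_survey(subjects, events, roles, coding, config_sensitivity)
    key = ["code", "sex"]
    merged = rec_main.merge(rec_sens, on=key, suffixes=("_main", "_sens"))
    diff = merged["af_joint_sens"] - merged["af_joint_main"]
    summary = {
        "mean": float(diff.mean()) if len(diff) else float("nan"),
        "median": float(diff.median()) if len(diff) else float("nan"),
        "sd": float(diff.std(ddof=1)) if len(diff) > 1 else float("nan"),
    }
    diffs = merged[key + ["af_joint_main", "af_joint_sens"]].assign(difference=diff)
    return {
        "records_main": rec_main,
        "records_sensitivity": rec_sens,
        "differences": diffs,
        "summary": summary,
    }
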