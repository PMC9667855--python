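"""Confounded survival-cohort simulator with interventional ground truth.

The generative process mirrors the assumed causal diagram Z -> X, Z -> Y,
X -> Y: categorical confounders Z are drawn first, exposures and other risk
factors are drawn conditionally on Z, and a latent event age T follows a
Weibull-baseline proportional-hazards model, T = b(-ln u e^{-eta})^{1/a} for
a uniform draw u. Study-entry left truncation is imposed by rejection
(subjects whose latent event precedes their entry age are discarded and
resampled, emulating a cohort that excludes prevalent cases), and follow-up
ends at an administrative censoring age.

Interventional copies (``simulate_do``) force exposure covariates to fixed
levels *after* Z and W are drawn — the confounder and other-risk marginals
are untouched, which is exactly the distribution P(. | do(X=x)). The
counterfactual generator shares the uniform draw and the (Z, W) pattern
between the two exposure settings (monotone coupling), giving sharp
per-subject counterfactual outcomes for effect-of-treatment-on-the-treated
checks.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ph_fit import BaselineHazard

__all__ = [
    "ConditionalCategorical",
    "GenerativeModel",
    "OutcomeSpec",
    "LandscapeModel",
    "sample_event_time",
    "simulate_cohort",
    "simulate_do",
    "simulate_counterfactual_pair",
    "simulate_landscape",
    "model_from_config",
    "demo_cohort_model",
    "demo_landscape",
    "demo_roles",
    "DEFAULT_BASELINE",
]

_PROB_TOL = 1e-12


def _check_probs(p: Sequence[float], what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError(f"{what}: empty probability vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{what}: probabilities must be >=0 and sum to 1, got {p}")
    return p


@dataclass(frozen=True)
class ConditionalCategorical:
    """Categorical distribution of one covariate, conditional on a Z pattern.

    ``given`` names the confounders conditioned on (may be empty for a
    marginal distribution); ``table`` maps each combination of their levels to
    a probability vector over ``levels``.
    """

    levels: tuple[str, ...]
    given: tuple[str, ...] = ()
    table: Mapping[tuple[str, ...], tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.table.items():
            p = _check_probs(p, f"P({self.levels}|{key})")
            if len(p) != len(self.levels):
                raise ValueError("probability vector length != number of levels")

    def probs_for(self, z_pattern: tuple[str, ...]) -> np.ndarray:
        try:
            return np.asarray(self.table[z_pattern], dtype=float)
        except KeyError:
            raise KeyError(
                f"no conditional probabilities declared for Z pattern {z_pattern}"
            ) from None


@dataclass(frozen=True)
class GenerativeModel:
    """Full data-generating model for one outcome.

    * ``confounders``: per-Z-covariate marginal category probabilities
      (confounders are mutually independent).
    * ``covariates``: per-X/W covariate conditional distributions given Z.
    * ``log_hazard_ratios``: (covariate, level) -> log hazard ratio; baseline
      levels carry 0 implicitly.
    * ``baseline_hazard``: Weibull H0.
    * ``entry_age``: uniform study-entry window (years); ``censor_age``:
      administrative cut-off (years).
    """

    confounders: Mapping[str, Mapping[str, float]]
    covariates: Mapping[str, ConditionalCategorical]
    log_hazard_ratios: Mapping[tuple[str, str], float]
    baseline_hazard: BaselineHazard
    entry_age: tuple[float, float] = (40.0, 70.0)
    censor_age: float = 80.0

    def __post_init__(self) -> None:
        for name, dist in self.confounders.items():
            if not dist:
                raise ValueError(f"confounder {name!r} has an empty level set")
            _check_probs(list(dist.values()), f"P({name})")
        for name, cc in self.covariates.items():
            if not cc.levels:
                raise ValueError(f"covariate {name!r} has an empty level set")
            for g in cc.given:
                if g not in self.confounders:
                    raise ValueError(f"{name!r} conditions on unknown confounder {g!r}")
        for (cov, level), lhr in self.log_hazard_ratios.items():
            if not np.isfinite(lhr):
                raise ValueError(f"non-finite log hazard ratio for {cov}={level}")
        if not self.entry_age[0] <= self.entry_age[1]:
            raise ValueError("entry_age window inverted")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.confounders) + tuple(self.covariates)

    def eta_of(self, levels: Mapping[str, str]) -> float:
        """Total log relative risk of a covariate pattern vs baseline."""
        return float(
            sum(self.log_hazard_ratios.get((c, l), 0.0) for c, l in levels.items())
        )


def sample_event_time(
    model: GenerativeModel, eta_total: np.ndarray | float, u: np.ndarray | float
) -> np.ndarray | float:
    """Invert the Weibull-PH survival curve: T with S(T | eta) = u.

    T = b (-ln u e^{-eta})^{1/a}; at a=b=1, eta=0 this is a unit exponential.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    eta_arr = np.asarray(eta_total, dtype=float)
    if not np.all(np.isfinite(eta_arr)):
        raise ValueError("eta_total must be finite")
    a = model.baseline_hazard.shape
    b = model.baseline_hazard.scale
    t = b * (-np.log(u_arr) * np.exp(-eta_arr)) ** (1.0 / a)
    return t if t.ndim else float(t)


def _draw_covariates(model: GenerativeModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw Z then X/W | Z for n subjects (vectorised per Z pattern)."""
    data: dict[str, np.ndarray] = {}
    for name, dist in model.confounders.items():
        levels = np.array(list(dist.keys()), dtype=object)
        probs = _check_probs(list(dist.values()), f"P({name})")
        data[name] = levels[rng.choice(len(levels), size=n, p=probs)]
    for name, cc in model.covariates.items():
        out = np.empty(n, dtype=object)
        if not cc.given:
            p = cc.probs_for(())
            out[:] = np.array(cc.levels, dtype=object)[rng.choice(len(cc.levels), size=n, p=p)]
        else:
            patterns = pd.Series(list(zip(*(data[g] for g in cc.given))))
            for pattern, idx in patterns.groupby(patterns).groups.items():
                mask = np.asarray(idx, dtype=int)
                p = cc.probs_for(tuple(pattern))
                out[mask] = np.array(cc.levels, dtype=object)[
                    rng.choice(len(cc.levels), size=len(mask), p=p)
                ]
        data[name] = out
    return pd.DataFrame(data)


def _eta_from_table(model: GenerativeModel, table: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(table))
    for (cov, level), lhr in model.log_hazard_ratios.items():
        if cov in table.columns:
            eta += np.where(table[cov].to_numpy() == level, lhr, 0.0)
    return eta


def _finalise(
    table: pd.DataFrame, latent_t: np.ndarray, entry: np.ndarray, censor_age: float
) -> pd.DataFrame:
    event = latent_t <= censor_age
    exit_age = np.where(event, latent_t, censor_age)
    out = table.copy()
    out.insert(0, "entry_age", entry)
    out.insert(1, "exit_age", exit_age)
    out.insert(2, "event", event.astype(int))
    return out


def simulate_cohort(
    model: GenerativeModel,
    n: int,
    seed: int,
    forced_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Observational cohort of n subjects (after left-truncation rejection).

    Returns a subject table with columns subject_id, sex, entry_age,
    exit_age, event, then one column per covariate. Byte-identical for
    identical (model, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[pd.DataFrame] = []
    got = 0
    while got < n:
        m = max(int((n - got) * 1.25) + 16, 32)
        tab = _draw_covariates(model, m, rng)
        if forced_levels:
            for cov, level in forced_levels.items():
                tab[cov] = level
        entry = rng.uniform(model.entry_age[0], model.entry_age[1], size=m)
        u = rng.random(m)
        u = np.clip(u, np.nextafter(0, 1), np.nextafter(1, 0))
        latent_t = sample_event_time(model, _eta_from_table(model, tab), u)
        keep = latent_t > entry  # left truncation by rejection
        piece = _finalise(tab[keep].reset_index(drop=True), latent_t[keep],
                          entry[keep], model.censor_age)
        chunks.append(piece)
        got += len(piece)
    cohort = pd.concat(chunks, ignore_index=True).iloc[:n].reset_index(drop=True)
    cohort.insert(0, "subject_id", np.arange(n))
    if "sex" not in cohort.columns:
        cohort.insert(1, "sex", np.where(
            np.random.default_rng(np.random.SeedSequence([seed, 1])).random(n) < 0.5,
            "F", "M"))
    return cohort


def simulate_do(
    model: GenerativeModel, n: int, seed: int, setting: Mapping[str, str]
) -> pd.DataFrame:
    """Interventional cohort under do(X = setting).

    Identical generative process except the set covariates are forced after
    Z (and the other X/W draws): confounder marginals are unchanged. Only
    non-confounder covariates may be intervened on.
    """
    for cov in setting:
        if cov in model.confounders:
            raise ValueError(f"cannot intervene on confounder {cov!r}")
        if cov not in model.covariates:
            raise ValueError(f"unknown exposure covariate {cov!r}")
        if setting[cov] not in model.covariates[cov].levels:
            raise ValueError(f"undeclared level {setting[cov]!r} for {cov!r}")
    return simulate_cohort(model, n, seed, forced_levels=dict(setting))


def simulate_counterfactual_pair(
    model: GenerativeModel,
    n: int,
    seed: int,
    covariate: str,
    x1: str,
    x0: str,
) -> pd.DataFrame:
    """Paired potential outcomes (Y_{x1}, Y_{x0}) among subjects with X=x1.

    The uniform draw and the (Z, W) pattern are shared between the two
    settings of ``covariate``; rows are returned only for subjects whose
    factual draw equals x1. Columns: Y_x1, Y_x0, T_x1, T_x0, plus covariates.
    No left truncation is applied (the estimand is a birth-cohort risk by the
    censoring age).
    """
    if x1 == x0:
        raise ValueError("x1 and x0 must differ")
    cc = model.covariates.get(covariate)
    if cc is None:
        raise ValueError(f"unknown exposure covariate {covariate!r}")
    for lev in (x1, x0):
        if lev not in cc.levels:
            raise ValueError(f"undeclared level {lev!r} for {covariate!r}")
    rng = np.random.default_rng(seed)
    tab = _draw_covariates(model, n, rng)
    u = np.clip(rng.random(n), np.nextafter(0, 1), np.nextafter(1, 0))
    factual = tab[covariate].to_numpy() == x1
    out = tab[factual].reset_index(drop=True)
    u = u[factual]
    eta_other = _eta_from_table(
        model, out.drop(columns=[covariate])
    )
    lhr = {lev: model.log_hazard_ratios.get((covariate, lev), 0.0) for lev in (x1, x0)}
    t1 = sample_event_time(model, eta_other + lhr[x1], u)
    t0 = sample_event_time(model, eta_other + lhr[x0], u)
    out["T_x1"] = t1
    out["T_x0"] = t0
    out["Y_x1"] = (t1 <= model.censor_age).astype(int)
    out["Y_x0"] = (t0 <= model.censor_age).astype(int)
    return out


# ---------------------------------------------------------------------------
# multi-outcome "landscape" mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """One disease outcome: an ICD-10-like code, its chapter, its Weibull
    baseline and its own log hazard ratios (independent latent time)."""

    code: str
    chapter: str
    baseline_hazard: BaselineHazard
    log_hazard_ratios: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class LandscapeModel:
    """Shared covariate machinery plus independent per-outcome event times."""

    base: GenerativeModel  # supplies covariates, entry window, censoring
    outcomes: tuple[OutcomeSpec, ...]

    def outcome_model(self, spec: OutcomeSpec) -> GenerativeModel:
        return replace(
            self.base,
            baseline_hazard=spec.baseline_hazard,
            log_hazard_ratios=dict(spec.log_hazard_ratios),
        )


def simulate_landscape(
    model: LandscapeModel, n: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subjects table + long-format diagnosis table for a multi-disease study.

    Latent event times are independent across outcomes given covariates. All
    diagnoses up to the administrative censoring age are recorded — including
    those *before* study entry, so the survey's exclusion and left-truncation
    rules can be exercised downstream. No rejection is applied here.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = model.base
    tab = _draw_covariates(base, n, rng)
    entry = rng.uniform(base.entry_age[0], base.entry_age[1], size=n)
    subjects = tab.copy()
    subjects.insert(0, "subject_id", np.arange(n))
    subjects.insert(1, "entry_age", entry)
    if "sex" not in subjects.columns:
        subjects.insert(1, "sex", np.where(rng.random(n) < 0.5, "F", "M"))
    rows: list[pd.DataFrame] = []
    for spec in model.outcomes:
        om = model.outcome_model(spec)
        u = np.clip(rng.random(n), np.nextafter(0, 1), np.nextafter(1, 0))
        t = sample_event_time(om, _eta_from_table(om, tab), u)
        hit = t <= base.censor_age
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.flatnonzero(hit),
                    "code": spec.code,
                    "chapter": spec.chapter,
                    "diagnosis_age": t[hit],
                }
            )
        )
    events = pd.concat(rows, ignore_index=True)
    events = events.sort_values(["subject_id", "diagnosis_age"], kind="mergesort").reset_index(drop=True)
    return subjects, events


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------

#: default Weibull baseline: shape 5 mimics the steep age-incidence of most
#: chronic disease; scale 161 puts cumulative incidence by age 80 near 3%
#: (rare-disease regime), against a UK-Biobank-like entry window of 40-70
#: years with administrative censoring at 80.
DEFAULT_BASELINE = BaselineHazard(shape=5.0, scale=161.0)

_SES_PROBS = {"T1": 0.34, "T2": 0.33, "T3": 0.33}
_EDU_PROBS = {"degree": 0.35, "post16": 0.35, "to16": 0.30}
_SMOKING = ConditionalCategorical(
    levels=("never", "previous", "current"),
    given=("ses",),
    table={
        ("T1",): (0.65, 0.25, 0.10),
        ("T2",): (0.55, 0.28, 0.17),
        ("T3",): (0.45, 0.28, 0.27),
    },
)
_BMI = ConditionalCategorical(
    levels=("T1", "T2", "T3"),
    given=("ses",),
    table={
        ("T1",): (0.38, 0.34, 0.28),
        ("T2",): (0.33, 0.34, 0.33),
        ("T3",): (0.28, 0.33, 0.39),
    },
)
_ALCOHOL = ConditionalCategorical(
    levels=("rarely", "sometimes", "regularly"),
    given=("education",),
    table={
        ("degree",): (0.30, 0.35, 0.35),
        ("post16",): (0.35, 0.35, 0.30),
        ("to16",): (0.45, 0.33, 0.22),
    },
)
#: confounder and other-risk log hazard ratios shared by every demo outcome
_SHARED_LHR = {
    ("ses", "T2"): 0.10,
    ("ses", "T3"): 0.25,
    ("education", "post16"): 0.08,
    ("education", "to16"): 0.18,
    ("alcohol", "sometimes"): 0.05,
    ("alcohol", "regularly"): 0.12,
}


def demo_cohort_model(
    smoking_current_lhr: float = float(np.log(2)),
    smoking_previous_lhr: float = float(np.log(1.3)),
    bmi_t3_lhr: float = 0.0,
    baseline: BaselineHazard = DEFAULT_BASELINE,
) -> GenerativeModel:
    """Single-outcome confounded cohort: smoking and BMI tertile driven by
    socio-economic status, alcohol by education, all of which also shift the
    hazard. Default effect sizes: hazard ratio 2 for current smoking vs
    never, 1.3 for previous."""
    lhr = dict(_SHARED_LHR)
    lhr[("smoking", "current")] = smoking_current_lhr
    lhr[("smoking", "previous")] = smoking_previous_lhr
    if bmi_t3_lhr:
        lhr[("bmi", "T3")] = bmi_t3_lhr
    return GenerativeModel(
        confounders={"ses": _SES_PROBS, "education": _EDU_PROBS},
        covariates={"smoking": _SMOKING, "bmi": _BMI, "alcohol": _ALCOHOL},
        log_hazard_ratios=lhr,
        baseline_hazard=baseline,
    )


_LANDSCAPE_CHAPTERS = ("VI", "IX", "X", "XI")


def demo_landscape(kind: str = "graded", n_outcomes: int = 20) -> LandscapeModel:
    """Twenty-outcome synthetic disease landscape.

    ``kind='null'``: one truly affected disease (hazard ratio 2 for current
    smoking) among otherwise-null outcomes — for selection error-rate checks.
    ``kind='graded'``: every outcome gets its own fixed smoking/BMI effect
    drawn once from uniform(-0.3, 1.1) / uniform(-0.2, 0.8) log hazard ratios
    (frozen generator, not a per-run draw) — for rank-recovery checks.
    Outcomes share the demo covariate model and confounder effects; each has
    an independent latent Weibull event time. Codes are synthetic
    (``Q00``...), spread over four chapters.
    """
    base = demo_cohort_model(0.0, 0.0)  # exposures null at baseline; per-outcome lhr below
    effect_rng = np.random.default_rng(20220722)  # frozen: part of the model spec
    outcomes = []
    for i in range(n_outcomes):
        code = f"Q{i:02d}"
        chapter = _LANDSCAPE_CHAPTERS[i % len(_LANDSCAPE_CHAPTERS)]
        lhr = dict(_SHARED_LHR)
        if kind == "null":
            if i == 0:
                lhr[("smoking", "current")] = float(np.log(2))
                lhr[("smoking", "previous")] = float(np.log(1.3))
        elif kind == "graded":
            s = float(effect_rng.uniform(-0.3, 1.1))
            b = float(effect_rng.uniform(-0.2, 0.8))
            lhr[("smoking", "current")] = s
            lhr[("smoking", "previous")] = 0.4 * s
            lhr[("bmi", "T3")] = b
            lhr[("bmi", "T1")] = -0.2 * b
        else:
            raise ValueError(f"unknown landscape kind {kind!r}")
        outcomes.append(
            OutcomeSpec(
                code=code,
                chapter=chapter,
                baseline_hazard=DEFAULT_BASELINE,
                log_hazard_ratios=lhr,
            )
        )
    return LandscapeModel(base=base, outcomes=tuple(outcomes))


def demo_roles():
    """Roles + coding matching :func:`demo_cohort_model` covariates.

    Smoking and BMI are the exposures (baseline never / middle tertile),
    alcohol is an other-risk factor, socio-economic status and education are
    confounders.
    """
    from .model_spec import CategoricalCoding, CovariateRoles

    roles = CovariateRoles(
        exposures=("smoking", "bmi"),
        other_risks=("alcohol",),
        confounders=("ses", "education"),
        baseline={
            "smoking": "never",
            "bmi": "T2",  # middle tertile is the declared baseline
            "alcohol": "rarely",
            "ses": "T1",
            "education": "degree",
        },
    )
    coding = CategoricalCoding(
        {
            "smoking": ("never", "previous", "current"),
            "bmi": ("T1", "T2", "T3"),
            "alcohol": ("rarely", "sometimes", "regularly"),
            "ses": ("T1", "T2", "T3"),
            "education": ("degree", "post16", "to16"),
        }
    )
    return roles, coding


# ---------------------------------------------------------------------------
# INI-style configuration
# ---------------------------------------------------------------------------

def model_from_config(path) -> GenerativeModel:
    """Read a GenerativeModel from an INI file.

    Sections::

        [study]
        entry_age_low = 40
        entry_age_high = 70
        censor_age = 80

        [baseline_hazard]
        shape = 5
        scale = 120

        [confounder:ses]
        levels = T1, T2, T3
        probs = 0.34, 0.33, 0.33

        [covariate:smoking]
        levels = never, previous, current
        given = ses
        probs@T1 = 0.70, 0.20, 0.10
        probs@T3 = 0.50, 0.25, 0.25
        ...

        [log_hazard_ratios]
        smoking:current = 0.693
        ses:T3 = 0.3
    """
    cp = configparser.ConfigParser(delimiters=("=",))
    cp.optionxform = str
    if not cp.read(path):
        raise FileNotFoundError(path)

    def floats(raw: str) -> list[float]:
        return [float(x) for x in raw.split(",")]

    def strings(raw: str) -> list[str]:
        return [x.strip() for x in raw.split(",")]

    confounders: dict[str, dict[str, float]] = {}
    covariates: dict[str, ConditionalCategorical] = {}
    for section in cp.sections():
        if section.startswith("confounder:"):
            name = section.split(":", 1)[1]
            lv = strings(cp[section]["levels"])
            pr = floats(cp[section]["probs"])
            confounders[name] = dict(zip(lv, pr))
        elif section.startswith("covariate:"):
            name = section.split(":", 1)[1]
            lv = tuple(strings(cp[section]["levels"]))
            given = tuple(strings(cp[section]["given"])) if cp[section].get("given") else ()
            table: dict[tuple[str, ...], tuple[float, ...]] = {}
            for key, raw in cp[section].items():
                if key.startswith("probs@"):
                    pattern = tuple(key[len("probs@"):].split("|"))
                    table[pattern] = tuple(floats(raw))
                elif key == "probs":
                    table[()] = tuple(floats(raw))
            covariates[name] = ConditionalCategorical(levels=lv, given=given, table=table)
    lhr: dict[tuple[str, str], float] = {}
    if cp.has_section("log_hazard_ratios"):
        for key, raw in cp.items("log_hazard_ratios"):
            cov, level = key.split(":", 1)
            lhr[(cov, level)] = float(raw)
    bh = BaselineHazard(
        shape=float(cp["baseline_hazard"]["shape"]),
        scale=float(cp["baseline_hazard"]["scale"]),
    )
    study = cp["study"] if cp.has_section("study") else {}
    return GenerativeModel(
        confounders=confounders,
        covariates=covariates,
        log_hazard_ratios=lhr,
        baseline_hazard=bh,
        entry_age=(
            float(study.get("entry_age_low", 40)),
            float(study.get("entry_age_high", 70)),
        ),
        censor_age=float(study.get("censor_age", 80)),
    )
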