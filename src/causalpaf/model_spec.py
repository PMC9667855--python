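"""Covariate roles, categorical coding and linear-predictor decomposition.

The causal model distinguishes three covariate roles:

* ``X`` — exposures of interest (e.g. smoking status, BMI tertile), the
  variables an intervention ``do(X=x0)`` would set to baseline;
* ``W`` — other modelled risk factors (e.g. alcohol, height) that are adjusted
  for but not intervened on;
* ``Z`` — confounders (e.g. education, socio-economic status) assumed to
  satisfy the backdoor criterion: they may influence both the exposures and
  the hazard, but are not influenced by the exposures.

Every covariate is categorical with a declared baseline level; the design
matrix carries one indicator column per non-baseline level, so a subject at
baseline for everything has an all-zero design row and zero linear predictor.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateRoles",
    "CategoricalCoding",
    "LinearPredictorDecomposition",
    "build_design",
    "decompose_linear_predictor",
    "assign_tertiles",
    "complete_cases",
    "roles_from_config",
]

ROLE_X = "X"
ROLE_W = "W"
ROLE_Z = "Z"


@dataclass(frozen=True)
class CategoricalCoding:
    """Ordered level sets per covariate; baseline maps to the all-zero row."""

    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for cov, lv in self.levels.items():
            if len(lv) < 2:
                raise ValueError(f"covariate {cov!r} needs >=2 levels, got {lv}")
            if len(set(lv)) != len(lv):
                raise ValueError(f"covariate {cov!r} has duplicate levels: {lv}")

    def columns(self, covariate: str, baseline: str) -> list[str]:
        """Indicator column names for the non-baseline levels of a covariate."""
        lv = self.levels[covariate]
        if baseline not in lv:
            raise ValueError(
                f"baseline {baseline!r} not among declared levels of {covariate!r}: {lv}"
            )
        return [f"{covariate}={l}" for l in lv if l != baseline]


@dataclass(frozen=True)
class CovariateRoles:
    """Partition of modelled covariates into exposures (X), other risk
    factors (W) and confounders (Z), plus one declared baseline level each."""

    exposures: tuple[str, ...]
    other_risks: tuple[str, ...]
    confounders: tuple[str, ...]
    baseline: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = (set(self.exposures), set(self.other_risks), set(self.confounders))
        names = self.exposures + self.other_risks + self.confounders
        if len(names) != len(set(names)):
            raise ValueError("role lists must be pairwise disjoint")
        for g in names:
            if g not in self.baseline:
                raise ValueError(f"covariate {g!r} has no declared baseline level")
        extra = set(self.baseline) - set(names)
        if extra:
            raise ValueError(f"baseline declared for unknown covariates: {sorted(extra)}")
        del groups

    @property
    def all_covariates(self) -> tuple[str, ...]:
        return self.exposures + self.other_risks + self.confounders

    def role_of(self, covariate: str) -> str:
        if covariate in self.exposures:
            return ROLE_X
        if covariate in self.other_risks:
            return ROLE_W
        if covariate in self.confounders:
            return ROLE_Z
        raise KeyError(covariate)

    def with_exposures(self, exposures: Sequence[str]) -> "CovariateRoles":
        """Re-partition: the given covariates become X, all other non-confounders W.

        Used for the survey's three contrasts (smoking-only, BMI-only, joint),
        which share one fitted model but move covariates between X and W.
        """
        exposures = tuple(exposures)
        pool = set(self.exposures) | set(self.other_risks)
        unknown = set(exposures) - pool
        if unknown:
            raise ValueError(f"cannot promote to exposure: {sorted(unknown)}")
        other = tuple(c for c in self.all_covariates if c in pool and c not in exposures)
        return CovariateRoles(exposures, other, self.confounders, dict(self.baseline))


@dataclass(frozen=True)
class LinearPredictorDecomposition:
    """Per-subject split of the log relative risk into exposure (eta_x),
    other-risk (eta_w) and confounder (eta_z) parts; all zero at baseline."""

    subject_ids: np.ndarray
    eta_x: np.ndarray
    eta_w: np.ndarray
    eta_z: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("eta_x", "eta_w", "eta_z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} misaligned: {arr.shape} vs {n} subjects")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def eta_total(self) -> np.ndarray:
        return self.eta_x + self.eta_w + self.eta_z

    @property
    def eta_wz(self) -> np.ndarray:
        return self.eta_w + self.eta_z


def build_design(
    cohort: pd.DataFrame,
    roles: CovariateRoles,
    coding: CategoricalCoding,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Indicator design matrix plus a column -> role (X/W/Z) map.

    One column per non-baseline level of each covariate in ``roles``; a
    subject at baseline everywhere gets an all-zero row. Undeclared observed
    levels (including missing values) are an error naming covariate and level.
    """
    cols: dict[str, np.ndarray] = {}
    column_roles: dict[str, str] = {}
    for cov in roles.all_covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} missing from cohort table")
        if cov not in coding.levels:
            raise ValueError(f"covariate {cov!r} has no declared coding")
        observed = cohort[cov]
        declared = set(coding.levels[cov])
        bad = set(observed.dropna().unique()) - declared
        if bad or observed.isna().any():
            label = sorted(bad)[0] if bad else "<missing>"
            raise ValueError(
                f"undeclared level {label!r} for covariate {cov!r}; "
                f"declared levels: {coding.levels[cov]}"
            )
        role = roles.role_of(cov)
        for col in coding.columns(cov, roles.baseline[cov]):
            level = col.split("=", 1)[1]
            cols[col] = (observed == level).to_numpy(dtype=float)
            column_roles[col] = role
    design = pd.DataFrame(cols, index=cohort.index)
    return design, column_roles


def decompose_linear_predictor(
    coefficients: Mapping[str, float] | pd.Series | np.ndarray,
    design: pd.DataFrame,
    column_roles: Mapping[str, str],
    subject_ids: np.ndarray | None = None,
) -> LinearPredictorDecomposition:
    """Split the fitted linear predictor into eta_x + eta_w + eta_z.

    The three parts sum exactly (machine precision) to the full inner product
    of coefficients and design row for every subject.
    """
    if isinstance(coefficients, np.ndarray):
        if len(coefficients) != design.shape[1]:
            raise ValueError(
                f"coefficient length {len(coefficients)} != design columns {design.shape[1]}"
            )
        coefficients = pd.Series(coefficients, index=design.columns)
    else:
        coefficients = pd.Series(coefficients)
        missing = set(design.columns) - set(coefficients.index)
        if missing:
            raise ValueError(f"coefficients missing for columns: {sorted(missing)}")
        coefficients = coefficients.reindex(design.columns)
    parts = {}
    for role in (ROLE_X, ROLE_W, ROLE_Z):
        cols = [c for c in design.columns if column_roles[c] == role]
        if cols:
            parts[role] = design[cols].to_numpy() @ coefficients[cols].to_numpy()
        else:
            parts[role] = np.zeros(len(design))
    if subject_ids is None:
        subject_ids = design.index.to_numpy()
    return LinearPredictorDecomposition(
        subject_ids=np.asarray(subject_ids),
        eta_x=parts[ROLE_X],
        eta_w=parts[ROLE_W],
        eta_z=parts[ROLE_Z],
    )


def assign_tertiles(
    values: Sequence[float] | np.ndarray | pd.Series,
    grouping: Sequence | np.ndarray | pd.Series | None = None,
) -> pd.Series:
    """Cut a numeric vector into tertiles T1/T2/T3, optionally within groups.

    Cut points are the 1/3 and 2/3 linear-interpolation (type-7) empirical
    quantiles, computed within each group (e.g. per sex) rather than pooled.
    Values tied with a cut point go to the lower tertile.
    """
    values = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    if grouping is None:
        grouping = pd.Series(np.zeros(len(values)), index=values.index)
    else:
        grouping = pd.Series(np.asarray(grouping), index=values.index)
    out = pd.Series(index=values.index, dtype=object)
    for _, idx in grouping.groupby(grouping).groups.items():
        v = values.loc[idx]
        vv = v.dropna()
        if len(vv) < 3:
            raise ValueError("need >=3 non-missing values per group for tertiles")
        if vv.nunique() == 1:
            raise ValueError("tertiles undefined: all values identical within a group")
        q1, q2 = np.quantile(vv.to_numpy(), [1 / 3, 2 / 3])  # type-7 (linear)
        cat = np.where(v <= q1, "T1", np.where(v <= q2, "T2", "T3"))
        cat = pd.Series(cat, index=v.index, dtype=object)
        cat[v.isna()] = np.nan
        out.loc[idx] = cat
    return out


def complete_cases(cohort: pd.DataFrame, covariates: Iterable[str]) -> pd.DataFrame:
    """Drop subjects with any missing modelled covariate (complete-case rule)."""
    covariates = list(covariates)
    return cohort.dropna(subset=[c for c in covariates if c in cohort.columns])


def roles_from_config(path) -> tuple[CovariateRoles, CategoricalCoding]:
    """Read roles + coding from an INI file.

    Sections ``[exposures]``, ``[other_risk]``, ``[confounders]``; one key per
    covariate whose value is the comma-separated ordered level list, with the
    baseline level marked by a leading ``*``::

        [exposures]
        smoking = *never, previous, current
        bmi = T1, *T2, T3
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # preserve case of covariate names and levels
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    section_names = {"exposures": [], "other_risk": [], "confounders": []}
    levels: dict[str, tuple[str, ...]] = {}
    baseline: dict[str, str] = {}
    for section, bucket in section_names.items():
        if not cp.has_section(section):
            continue
        for cov, raw in cp.items(section):
            lv = []
            base = None
            for tok in raw.split(","):
                tok = tok.strip()
                if tok.startswith("*"):
                    base = tok[1:].strip()
                    lv.append(base)
                else:
                    lv.append(tok)
            if base is None:
                raise ValueError(f"no baseline (leading '*') declared for {cov!r}")
            levels[cov] = tuple(lv)
            baseline[cov] = base
            bucket.append(cov)
    roles = CovariateRoles(
        exposures=tuple(section_names["exposures"]),
        other_risks=tuple(section_names["other_risk"]),
        confounders=tuple(section_names["confounders"]),
        baseline=baseline,
    )
    return roles, CategoricalCoding(levels)
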