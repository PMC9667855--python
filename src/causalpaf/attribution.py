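"""Backdoor-adjusted attribution fractions and related estimators.

The population attribution fraction A_f compares the observed disease
probability with the probability under an intervention that sets the
exposures X to baseline, do(X=x0), while confounders Z and other risk
factors W keep their observed joint distribution. Under a proportional
hazards model with rare disease (F ~= H), the age-independent sample form is

    A_f = 1 - sum_i e^{eta_w_i + eta_z_i} / sum_i e^{eta_x_i + eta_w_i + eta_z_i}

equivalently 1 - 1 / sum_i w_i e^{eta_x_i} with confounder weights
w_i proportional to e^{eta_w_i + eta_z_i}. The WHO-style fraction
A_W = 1 - 1/mean(e^{eta_x}) ignores the exposure–confounder correlation and
bounds A_f from below (above) when e^{eta_x} and e^{eta_w + eta_z} are
positively (negatively) correlated. The age-dependent form replaces the
rare-disease cumulative hazards by exact Weibull distribution functions and
tends to the age-independent value as t -> 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model_spec import CategoricalCoding, CovariateRoles, LinearPredictorDecomposition
from .ph_fit import BaselineHazard, fit_ph, linear_predictors

__all__ = [
    "AttributionResult",
    "af_backdoor",
    "af_weights",
    "af_who",
    "af_age",
    "af_pairwise",
    "af_ett",
    "attributed_cases",
    "af_flip",
    "af_binary_approx",
    "bootstrap_af",
]

PROTECTIVE_LIMIT = -0.5  # below this, a negative fraction is not interpretable


@dataclass(frozen=True)
class AttributionResult:
    """An attribution-fraction estimate with its bookkeeping.

    ``estimate`` is dimensionless and <= 1; ``horizon`` is an age in years or
    None for the t -> 0 limit; ``n_attributed`` is the signed attributed case
    count when an observed case count was supplied.
    """

    estimate: float
    method: str  # backdoor | backdoor_age_t | who | ett | pairwise
    horizon: float | None = None
    n: int | None = None
    n_obs: int | None = None
    n_attributed: int | None = None
    ci: tuple[float, float, float] | None = None  # (level, lower, upper)
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimate > 1 + 1e-12:
            raise ValueError(f"attribution fraction cannot exceed 1, got {self.estimate}")
        if self.estimate < PROTECTIVE_LIMIT:
            warnings.warn(
                f"large negative attribution fraction ({self.estimate:.3g}) is "
                "outside the interpretable regime",
                RuntimeWarning,
                stacklevel=3,
            )

    def with_cases(self, n_obs: int) -> "AttributionResult":
        return AttributionResult(
            estimate=self.estimate,
            method=self.method,
            horizon=self.horizon,
            n=self.n,
            n_obs=int(n_obs),
            n_attributed=attributed_cases(self.estimate, n_obs),
            ci=self.ci,
            extra=dict(self.extra),
        )


def _require_nonempty(lp: LinearPredictorDecomposition) -> None:
    if len(lp) == 0:
        raise ValueError("empty linear-predictor decomposition")


def af_backdoor(lp: LinearPredictorDecomposition) -> AttributionResult:
    """Age-independent backdoor attribution fraction (rare-disease limit).

    The numerator of the underlying excess-risk contrast is the average
    causal effect of moving the population's exposures to baseline; it is
    recorded (per subject, in units of H0(t)) under ``extra['ace']``.
    """
    _require_nonempty(lp)
    num = np.exp(lp.eta_wz).sum()
    den = np.exp(lp.eta_total).sum()
    est = 1.0 - num / den
    return AttributionResult(
        estimate=float(est),
        method="backdoor",
        horizon=None,
        n=len(lp),
        extra={"ace": float((den - num) / len(lp))},
    )


def af_weights(lp: LinearPredictorDecomposition) -> np.ndarray:
    """Confounder weights w_i = e^{eta_wz_i} / sum_j e^{eta_wz_j} (sum to 1).

    ``1 - 1/sum_i w_i e^{eta_x_i}`` reproduces :func:`af_backdoor` to machine
    precision; with no confounders or other risks, w_i = 1/n.
    """
    _require_nonempty(lp)
    e = np.exp(lp.eta_wz)
    return e / e.sum()


def af_who(lp: LinearPredictorDecomposition) -> AttributionResult:
    """WHO-style fraction A_W = 1 - 1/mean(e^{eta_x}); ignores W and Z."""
    _require_nonempty(lp)
    est = 1.0 - 1.0 / float(np.mean(np.exp(lp.eta_x)))
    return AttributionResult(estimate=est, method="who", horizon=None, n=len(lp))


def af_age(
    lp: LinearPredictorDecomposition, bh: BaselineHazard, t: float
) -> AttributionResult:
    """Age-dependent fraction using exact Weibull distribution functions.

    A_f(t) = 1 - sum_i F(t | eta_wz_i) / sum_i F(t | eta_total_i) with
    F = 1 - exp(-H0(t) e^eta); converges to :func:`af_backdoor` as t -> 0.
    """
    _require_nonempty(lp)
    if not t > 0:
        raise ValueError("horizon t must be positive")
    h0 = bh.cumulative_hazard(t)
    F0 = -np.expm1(-h0 * np.exp(lp.eta_wz))
    F1 = -np.expm1(-h0 * np.exp(lp.eta_total))
    est = 1.0 - F0.sum() / F1.sum()
    return AttributionResult(estimate=float(est), method="backdoor_age_t",
                             horizon=float(t), n=len(lp))


def af_pairwise(eta_x1: float, eta_x2: float) -> float:
    """Fraction for do(X=x2) vs do(X=x1): 1 - e^{eta_x1 - eta_x2}.

    Reduces to the conventional relative-risk form; negative when x1 is the
    riskier setting.
    """
    if not (np.isfinite(eta_x1) and np.isfinite(eta_x2)):
        raise ValueError("linear predictors must be finite")
    return float(1.0 - math.exp(eta_x1 - eta_x2))


def af_ett(relative_risk: float) -> float:
    """Effect-of-treatment-on-the-treated fraction (R - 1)/R."""
    if not relative_risk > 0:
        raise ValueError("relative risk must be positive")
    return float((relative_risk - 1.0) / relative_risk)


def attributed_cases(af: float, n_obs: int) -> int:
    """Signed attributed case count N_Af = round(af * N_obs), half away from zero."""
    if n_obs < 0:
        raise ValueError("observed case count must be nonnegative")
    x = af * n_obs
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def af_flip(af: float) -> tuple[float, float]:
    """Re-express a fraction on the (P0 - P)/P0 scale.

    Returns ``(exact, first_order)``: exact value -af/(1 - af) and the
    first-order expansion -af(1 + af), which agree to O(af^2).
    """
    if af >= 1:
        raise ValueError("af must be < 1 (P0 would vanish)")
    return float(-af / (1.0 - af)), float(-af * (1.0 + af))


def af_binary_approx(p: float, relative_risk: float) -> tuple[float, float]:
    """Rare binary exposure uncorrelated with W, Z: (approximate, exact) A_f.

    approximate = p(R - 1); exact = 1 - 1/(1 + p(R - 1)). The linear form is
    good when p(R - 1) << 1 and halves exactly when p is halved.
    """
    if not 0 <= p <= 1:
        raise ValueError("exposed proportion p must lie in [0, 1]")
    if not relative_risk > 0:
        raise ValueError("relative risk must be positive")
    excess = p * (relative_risk - 1.0)
    return float(excess), float(1.0 - 1.0 / (1.0 + excess))


def bootstrap_af(
    cohort: pd.DataFrame,
    roles: CovariateRoles,
    coding: CategoricalCoding,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> AttributionResult:
    """Nonparametric subject-level bootstrap of fit + backdoor fraction.

    Each replicate resamples subjects with replacement, refits the
    proportional-hazards model and recomputes A_f; the interval is the
    percentile interval at ``level``. Non-convergent replicates are dropped
    with a warning; more than 10% dropped is an error.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    fit = fit_ph(cohort, roles, coding).require_converged()
    lp = linear_predictors(fit, cohort, roles, coding)
    point = af_backdoor(lp)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    estimates = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            bfit = fit_ph(boot, roles, coding)
            if not bfit.converged:
                raise RuntimeError("non-convergent replicate")
            blp = linear_predictors(bfit, boot, roles, coding)
            estimates.append(af_backdoor(blp).estimate)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            dropped += 1
            warnings.warn("dropping non-convergent bootstrap replicate", stacklevel=2)
    if dropped > 0.1 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed to converge")
    alpha = 1.0 - level
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return AttributionResult(
        estimate=point.estimate,
        method="backdoor",
        horizon=None,
        n=n,
        n_obs=fit.n_events,
        n_attributed=attributed_cases(point.estimate, fit.n_events),
        ci=(level, float(lo), float(hi)),
        extra=dict(point.extra),
    )
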