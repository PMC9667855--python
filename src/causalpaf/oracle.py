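"""Independent ground truth for the attribution estimators.

This module computes interventional quantities exactly on small discrete
causal models (by summation over the full joint distribution) and by
Monte-Carlo simulation on the generative model, *re-deriving* every survival
quantity from first principles. It deliberately shares no computational path
with :mod:`causalpaf.attribution`, so agreement between the two is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np

from .ph_fit import BaselineHazard
from .synth_cohort import (
    GenerativeModel,
    simulate_cohort,
    simulate_counterfactual_pair,
    simulate_do,
)

__all__ = [
    "DiscreteCausalModel",
    "do_probability",
    "do_rate_ph",
    "af_exact",
    "af_counterfactual_mc",
    "ett_mc",
    "discrete_from_generative",
]

_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteCausalModel:
    """Finite causal model with composite variables X (exposures), W, Z.

    * ``p_z``: marginal P(Z=z) over Z levels.
    * ``p_xw_given_z``: conditional joint P(X=x, W=w | Z=z).
    * either ``p_y``: P(Y=1 | x, w, z) tables (for pure adjustment-formula
      work), or per-level log relative risks ``eta_x/eta_w/eta_z`` for
      proportional-hazards survival strata.

    Levels may be tuples encoding several underlying covariates.
    """

    p_z: Mapping[object, float]
    p_xw_given_z: Mapping[object, Mapping[tuple[object, object], float]]
    p_y: Mapping[tuple[object, object, object], float] | None = None
    eta_x: Mapping[object, float] = field(default_factory=dict)
    eta_w: Mapping[object, float] = field(default_factory=dict)
    eta_z: Mapping[object, float] = field(default_factory=dict)
    x_baseline: object = None

    def __post_init__(self) -> None:
        if abs(sum(self.p_z.values()) - 1.0) > _TOL:
            raise ValueError("P(Z) must sum to 1")
        for z, table in self.p_xw_given_z.items():
            s = sum(table.values())
            if abs(s - 1.0) > _TOL:
                raise ValueError(f"P(X,W|Z={z}) sums to {s}, expected 1")
            if any(p < 0 for p in table.values()):
                raise ValueError("negative probability")
        if self.p_y is not None:
            for key, p in self.p_y.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"P(Y=1|{key}) = {p} outside [0,1]")

    # -- joint / marginal helpers (exhaustive enumeration) ------------------
    def x_levels(self) -> list:
        return sorted({x for t in self.p_xw_given_z.values() for (x, _w) in t})

    def joint_xwz(self) -> list[tuple[object, object, object, float]]:
        """All (x, w, z, P(x,w,z)) cells."""
        cells = []
        for z, pz in self.p_z.items():
            for (x, w), pxw in self.p_xw_given_z[z].items():
                cells.append((x, w, z, pz * pxw))
        return cells

    def p_wz(self) -> dict[tuple[object, object], float]:
        out: dict[tuple[object, object], float] = {}
        for x, w, z, p in self.joint_xwz():
            out[(w, z)] = out.get((w, z), 0.0) + p
        return out

    def eta_of(self, x, w, z) -> float:
        return (
            self.eta_x.get(x, 0.0) + self.eta_w.get(w, 0.0) + self.eta_z.get(z, 0.0)
        )


def _cdf(bh: BaselineHazard, t: float, eta: float) -> float:
    # independent first-principles evaluation of F(t) = 1 - exp(-(t/b)^a e^eta)
    return -math.expm1(-((t / bh.scale) ** bh.shape) * math.exp(eta))


def do_probability(model: DiscreteCausalModel, x) -> float:
    """Adjustment formula: P(Y=1 | do(X=x)) = sum_{w,z} P(Y=1|x,w,z) P(w,z).

    Differs from the conditional P(Y=1 | X=x), which would weight by
    P(w,z | x) instead of the marginal P(w,z).
    """
    if model.p_y is None:
        raise ValueError("model carries no P(Y=1|x,w,z) table")
    if x not in model.x_levels():
        raise ValueError(f"undeclared X level {x!r}")
    total = 0.0
    for (w, z), pwz in model.p_wz().items():
        total += model.p_y[(x, w, z)] * pwz
    return total


def conditional_probability(model: DiscreteCausalModel, x) -> float:
    """Ordinary P(Y=1 | X=x) for contrast with :func:`do_probability`."""
    if model.p_y is None:
        raise ValueError("model carries no P(Y=1|x,w,z) table")
    num = 0.0
    den = 0.0
    for xx, w, z, p in model.joint_xwz():
        if xx == x:
            num += model.p_y[(x, w, z)] * p
            den += p
    if den == 0:
        raise ValueError(f"X level {x!r} has zero probability")
    return num / den


class DoRate(NamedTuple):
    exact: float
    rare_limit: float


def do_rate_ph(model: DiscreteCausalModel, bh: BaselineHazard, t: float, x) -> DoRate:
    """P(Y=1, T<t | do(X=x)) under proportional-hazards survival strata.

    Returns the exact form sum_{w,z} F(t|x,w,z) P(w,z) and the rare-disease
    limit e^{eta_x} H0(t) A_WZ with A_WZ = sum_{w,z} e^{eta_w+eta_z} P(w,z).
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    ex = model.eta_x.get(x, 0.0)
    exact = 0.0
    a_wz = 0.0
    for (w, z), pwz in model.p_wz().items():
        ewz = model.eta_w.get(w, 0.0) + model.eta_z.get(z, 0.0)
        exact += _cdf(bh, t, ex + ewz) * pwz
        a_wz += math.exp(ewz) * pwz
    rare = math.exp(ex) * bh.cumulative_hazard(t) * a_wz
    return DoRate(exact=exact, rare_limit=rare)


def af_exact(
    model: DiscreteCausalModel, bh: BaselineHazard, t: float | None
) -> float:
    """True A_f(t) by exact summation over the discrete joint distribution.

    ``t=None`` gives the analytic t -> 0 limit via the rare-limit forms
    (ratios of population-averaged relative risks); a positive ``t`` uses
    exact Weibull distribution functions.
    """
    if t is None:
        num = 0.0
        den = 0.0
        for x, w, z, p in model.joint_xwz():
            ewz = model.eta_w.get(w, 0.0) + model.eta_z.get(z, 0.0)
            num += math.exp(ewz) * p
            den += math.exp(model.eta_x.get(x, 0.0) + ewz) * p
        return 1.0 - num / den
    if not t > 0:
        raise ValueError("t must be positive (or None for the limit)")
    p_obs = 0.0
    for x, w, z, p in model.joint_xwz():
        p_obs += _cdf(bh, t, model.eta_of(x, w, z)) * p
    x0 = model.x_baseline
    p_do = 0.0
    for (w, z), pwz in model.p_wz().items():
        p_do += _cdf(bh, t, model.eta_of(x0, w, z)) * pwz
    return (p_obs - p_do) / p_obs


def af_counterfactual_mc(
    genmodel: GenerativeModel,
    n: int,
    seed: int,
    t: float,
    x0: Mapping[str, str],
) -> tuple[float, float]:
    """Monte-Carlo A_f(t) = (P - P0)/P from paired observational/do cohorts.

    Both cohorts are simulated from birth (entry 0, censoring at ``t``) with
    shared seeds; P and P0 are event proportions by age t. Returns
    ``(af, standard_error)`` with the error from binomial standard errors on
    P and P0 propagated by the delta method (conservatively ignoring the
    positive pairing correlation).
    """
    if n < 10_000:
        raise ValueError("need n >= 10^4 for a useful Monte-Carlo estimate")
    birth = replace(genmodel, entry_age=(0.0, 0.0), censor_age=float(t))
    # entry at exactly 0 would reject nothing; shift entry to -0 equivalent
    obs = _birth_cohort_events(birth, n, seed, forced=None)
    do0 = _birth_cohort_events(birth, n, seed, forced=dict(x0))
    p = obs.mean()
    p0 = do0.mean()
    if p == 0:
        raise ValueError("no events observed; cannot form an attribution fraction")
    af = (p - p0) / p
    var_p = p * (1 - p) / n
    var_p0 = p0 * (1 - p0) / n
    se = (p0 / p) * math.sqrt(var_p / p**2 + var_p0 / p0**2) if p0 > 0 else math.sqrt(var_p) / p
    return float(af), float(se)


def _birth_cohort_events(model: GenerativeModel, n, seed, forced) -> np.ndarray:
    """Event indicators by the censoring age for a from-birth cohort."""
    from .synth_cohort import _draw_covariates, _eta_from_table, sample_event_time

    rng = np.random.default_rng(seed)
    tab = _draw_covariates(model, n, rng)
    if forced:
        for cov, level in forced.items():
            if cov in model.confounders:
                raise ValueError(f"cannot intervene on confounder {cov!r}")
            tab[cov] = level
    u = np.clip(rng.random(n), np.nextafter(0, 1), np.nextafter(1, 0))
    latent = sample_event_time(model, _eta_from_table(model, tab), u)
    return (latent <= model.censor_age).astype(float)


def ett_mc(
    genmodel: GenerativeModel,
    n: int,
    seed: int,
    t: float,
    covariate: str,
    x1: str,
    x0: str,
) -> tuple[float, float]:
    """Monte-Carlo ETT attribution fraction among the exposed.

    [P(Y_{x1}=1 | X=x1) - P(Y_{x0}=1 | X=x1)] / P(Y_{x1}=1 | X=x1) from the
    coupled counterfactual pairs, with a delta-method standard error. Within
    the proportional-hazards model this approaches (R-1)/R with
    R = e^{eta_{x1}} regardless of confounding strength.
    """
    birth = replace(genmodel, entry_age=(0.0, 0.0), censor_age=float(t))
    pairs = simulate_counterfactual_pair(birth, n, seed, covariate, x1, x0)
    if len(pairs) == 0:
        raise ValueError(f"no subjects with {covariate}={x1!r}")
    m = len(pairs)
    p1 = pairs["Y_x1"].mean()
    p0 = pairs["Y_x0"].mean()
    if p1 == 0:
        raise ValueError("no events among the exposed")
    est = (p1 - p0) / p1
    var1 = p1 * (1 - p1) / m
    var0 = p0 * (1 - p0) / m
    se = (p0 / p1) * math.sqrt(var1 / p1**2 + var0 / p0**2) if p0 > 0 else math.sqrt(var1) / p1
    return float(est), float(se)


def discrete_from_generative(
    genmodel: GenerativeModel,
    exposures: tuple[str, ...],
    x_baseline: Mapping[str, str],
) -> DiscreteCausalModel:
    """Exact discrete causal model induced by a generative model.

    Confounders form the composite Z, the named ``exposures`` form the
    composite X and the remaining covariates form W; levels are tuples. The
    per-composite log relative risks are sums of the generative model's true
    log hazard ratios, so `af_exact` on the result is the analytic truth for
    cohorts drawn from ``genmodel``.
    """
    import itertools

    conf_names = list(genmodel.confounders)
    z_levels = list(itertools.product(*(genmodel.confounders[c].keys() for c in conf_names)))
    p_z = {}
    for z in z_levels:
        p_z[z] = float(np.prod([genmodel.confounders[c][l] for c, l in zip(conf_names, z)]))

    cov_names = list(genmodel.covariates)
    w_names = [c for c in cov_names if c not in exposures]
    x_names = [c for c in cov_names if c in exposures]

    def cond_probs(cov, z):
        cc = genmodel.covariates[cov]
        pattern = tuple(z[conf_names.index(g)] for g in cc.given)
        return dict(zip(cc.levels, cc.probs_for(pattern)))

    p_xw_given_z: dict = {}
    eta_x: dict = {}
    eta_w: dict = {}
    eta_z: dict = {}
    for z in z_levels:
        eta_z[z] = sum(
            genmodel.log_hazard_ratios.get((c, l), 0.0) for c, l in zip(conf_names, z)
        )
        table: dict = {}
        per_cov = {c: cond_probs(c, z) for c in cov_names}
        x_combos = list(itertools.product(*(per_cov[c].keys() for c in x_names))) or [()]
        w_combos = list(itertools.product(*(per_cov[c].keys() for c in w_names))) or [()]
        for xlev in x_combos:
            px = float(np.prod([per_cov[c][l] for c, l in zip(x_names, xlev)])) if x_names else 1.0
            eta_x[xlev] = sum(
                genmodel.log_hazard_ratios.get((c, l), 0.0) for c, l in zip(x_names, xlev)
            )
            for wlev in w_combos:
                pw = float(np.prod([per_cov[c][l] for c, l in zip(w_names, wlev)])) if w_names else 1.0
                eta_w[wlev] = sum(
                    genmodel.log_hazard_ratios.get((c, l), 0.0) for c, l in zip(w_names, wlev)
                )
                table[(xlev, wlev)] = px * pw
        p_xw_given_z[z] = table
    baseline = tuple(x_baseline[c] for c in x_names)
    return DiscreteCausalModel(
        p_z=p_z,
        p_xw_given_z=p_xw_given_z,
        eta_x=eta_x,
        eta_w=eta_w,
        eta_z=eta_z,
        x_baseline=baseline,
    )
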