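# causalpaf

Causal (backdoor-adjusted) population attribution fractions for survival
data, with a confounded-cohort simulator, exact and Monte-Carlo causal
oracles, and a multi-disease "landscape survey" pipeline.

## Who this is for

Epidemiologists and biostatisticians who fit multiply-adjusted proportional
hazards models to cohort data (age as the time axis, study-entry left
truncation, administrative right censoring) and want the *causal* share of
disease incidence attributable to exposures such as smoking status or BMI
tertile — not just an association — under an assumed causal diagram in
which confounders Z (socio-economic status, education, ...) influence both
the exposures X and the hazard, and satisfy the backdoor criterion.

## The statistic

With P = P(Y=1, T&lt;t) the observed cumulative disease probability and
P0 its value under do(X=x0) (exposures forced to baseline, confounder
mechanism intact), the population attribution fraction is

    A_f = (P − P0) / P .

Under proportional hazards h(t|x,w,z) = h0(t) e^{η_x+η_w+η_z} and rare
disease (F ≈ H), A_f becomes age-independent and is computable directly
from the fitted per-subject linear predictors:

    A_f = 1 − Σᵢ e^{η_wᵢ+η_zᵢ} / Σᵢ e^{η_xᵢ+η_wᵢ+η_zᵢ}
        = 1 − 1 / Σᵢ wᵢ e^{η_xᵢ},   wᵢ ∝ e^{η_wᵢ+η_zᵢ} .

Also provided: the WHO-style fraction A_W = 1 − 1/mean(e^{η_x}) (a lower /
upper bound on A_f depending on the sign of the exposure–confounder
relative-risk covariance), the exact age-dependent form with a Weibull
baseline, the pairwise fraction 1 − e^{η_x1−η_x2}, the treated-only (ETT)
fraction (R−1)/R, attributed case counts N_Af = A_f·N_obs, and bootstrap
intervals. See `docs/methods.md` for derivations, assumptions and design
choices.

## Worked example

```python
import numpy as np
from causalpaf import (
    demo_cohort_model, demo_roles, simulate_cohort,
    fit_ph, linear_predictors, af_backdoor, af_who,
    discrete_from_generative, af_exact,
)

model = demo_cohort_model()          # smoking HR 2, exposure driven by SES
cohort = simulate_cohort(model, 100_000, seed=1)
roles, coding = demo_roles()

fit = fit_ph(cohort, roles, coding).require_converged()
lp = linear_predictors(fit, cohort, roles.with_exposures(("smoking",)), coding)
print("fitted smoking HR:", float(np.exp(fit.params["smoking=current"])))
print("A_f (backdoor):   ", af_backdoor(lp).estimate)
print("A_W (unadjusted): ", af_who(lp).estimate)

disc = discrete_from_generative(model, ("smoking",), {"smoking": "never"})
print("A_f (exact truth):", af_exact(disc, model.baseline_hazard, None))
```

Output:

```
fitted smoking HR: 2.0607668535027934
A_f (backdoor):    0.22149764493919244
A_W (unadjusted):  0.21750353198222694
A_f (exact truth): 0.2111992154112634
```

Reading: about 21% of this cohort's incidence is causally attributable to
smoking — eliminating smoking (do(X=never)) would be expected to remove
roughly one case in five. The estimate from the fitted model matches the
exact value computed by enumerating the generative model's joint
distribution to within sampling error at n = 100,000, and the unadjusted
WHO-style fraction sits just below the backdoor value, as it must when the
exposure is positively correlated with the confounders.

A command-line interface mirrors the library (`causalpaf simulate`,
`causalpaf af`, `causalpaf oracle`, `causalpaf survey`); run
`causalpaf --help`.

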