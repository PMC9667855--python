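# Methods

## The estimand

`causalpaf` estimates, for a survival outcome, the proportion of a
population's disease incidence that is causally attributable to a set of
exposures `X` (canonically smoking status and BMI tertile), in the presence
of confounders `Z` (socio-economic status, education) that influence both
the exposures and the hazard, and other adjusted risk factors `W` (alcohol
frequency, height tertile, ...). The assumed causal diagram is
`Z -> X`, `Z -> Y`, `X -> Y`: `Z` satisfies the backdoor criterion for the
effect of `X` on the outcome `Y`, and `X` does not influence `Z`.

Writing `P = P(Y=1, T<t)` for the observed cumulative disease probability
and `P0 = P(Y=1, T<t | do(X=x0))` for its value under an intervention that
moves every subject's exposures to baseline while leaving the confounder
mechanism intact, the population attribution fraction is the excess
fraction

    A_f = (P - P0) / P.

`P0` is identified from observational data by the adjustment formula
(summing `P(Y=1 | x0, w, z)` against the *marginal* `P(w, z)` rather than
`P(w, z | x0)`).

## Estimators

Under a proportional-hazards model on the age scale,
`h(t | x, w, z) = h0(t) exp(eta_x + eta_w + eta_z)`, with cumulative hazard
`H = H0(t) e^eta` and the rare-disease approximation `F = 1 - e^{-H} ~= H`,
the fraction becomes age-independent and purely a function of the fitted
linear predictors over the cohort:

    A_f = 1 - sum_i exp(eta_w_i + eta_z_i) / sum_i exp(eta_x_i + eta_w_i + eta_z_i)
        = 1 - 1 / sum_i w_i exp(eta_x_i),   w_i ∝ exp(eta_w_i + eta_z_i).

The weight form shows how exposure–confounder correlation enters: when
`exp(eta_x)` covaries positively with `exp(eta_w + eta_z)`, adjusting raises
the fraction relative to the unweighted (WHO-style) comparison
`A_W = 1 - 1/mean(exp(eta_x))`, which is a lower bound exactly when that
sample covariance is positive, an upper bound when it is negative, and equal
at zero covariance (this is asserted property-wise in the tests).

Other estimators provided:

* **Age-dependent form** `af_age`: replaces the rare-disease hazards by
  exact Weibull distribution functions `F = 1 - exp(-H0(t) e^eta)`. It is
  nonincreasing in `t` for harmful exposures and converges to the
  age-independent value as `H0(t) -> 0`.
* **Pairwise fraction** `af_pairwise`: `1 - exp(eta_x1 - eta_x2)` comparing
  two interventional settings; reduces to the conventional relative-risk
  form because the confounder sums cancel.
* **Treated-only (ETT) fraction** `af_ett`: `(R - 1)/R` with
  `R = exp(eta_x1)`. Within the model this is invariant to confounding
  strength, unlike the population fraction, because the confounder
  integrals condition on the exposed and cancel.
* **Attributed cases**: `N_Af = round(A_f * N_obs)`, rounded half away from
  zero so protective (negative) fractions give symmetric counts.
* **Sign conventions**: harmful exposures give `A_f in (0, 1]`; protective
  ones give negative values, re-expressible on the `(P0 - P)/P0` scale by
  `af_flip` (exact value `-A_f/(1 - A_f)` plus the first-order form
  `-A_f(1 + A_f)`). Fractions below -0.5 trigger a warning: large negative
  values have no useful interpretation because `P` can be arbitrarily
  small.
* **Rare binary exposure**: for prevalence `p` and relative risk `R`
  uncorrelated with `W, Z`, `A_f = 1 - 1/(1 + p(R-1)) ~= p(R-1)`; the
  linear form halves exactly when `p` halves.

Uncertainty is by nonparametric subject-level bootstrap (percentile
interval; replicates that fail to converge are dropped, more than 10%
dropped is an error). No delta-method variance is attempted because the
estimator mixes fitted coefficients with empirical sums over the same
subjects.

## Model fitting

`fit_ph` maximises the Cox partial likelihood with Efron's tie correction,
with subjects at risk on `(entry_age, exit_age]` (left truncation by late
entry, right censoring at the administrative study end). The solver is a
damped Newton iteration whose risk-set sums are computed with two sorted
suffix-sum passes (one over exit ages, one over entry ages), so fits scale
linearly in `n`; its coefficients and standard errors are cross-checked
against lifelines' `CoxPHFitter` in the test suite. Constant design columns
are dropped with a warning (they arise when, e.g., a sex-specific covariate
is degenerate in a sex stratum). Men and women are fitted separately rather
than via a stratified joint fit.

The Weibull baseline `H0(t) = (t/b)^a` is estimated by maximum likelihood
with each subject's total linear predictor as a fixed offset, under the same
truncation and censoring. Useful closure property (asserted in tests):
adding `ln k` to every offset leaves the shape unchanged and multiplies the
fitted scale by exactly `k^{1/a}`.

The rare-disease approximation is policed by `rare_disease_check`: the
default warning threshold is a subject-level cumulative hazard of 0.1,
which bounds the relative error `|H - F|/H` by about 5%. `F <= H <=
-ln(1 - F)` holds identically and is property-tested.

## Covariate model

Covariates are categorical with one declared baseline level each; the
design matrix has one indicator per non-baseline level, so the baseline
subject has a zero linear predictor. The BMI baseline is deliberately the
*middle* tertile (non-extreme baselines are fully supported). Tertiles use
linear-interpolation (type-7) empirical quantiles computed within group
(e.g. per sex); values tied with a cut point go to the lower tertile — a
deterministic rule chosen for reproducibility, since no canonical tie rule
exists. Missing covariate values are handled by complete-case deletion.
Walking pace is not part of the default covariate set (it appears in some
descriptions of baseline levels but not in the adjustment set; we follow
the adjustment set).

## Synthetic cohorts and ground truth

The simulator draws `Z` from independent categorical marginals, `X`/`W`
conditionally on `Z`, an entry age from Uniform(40, 70) years, and a latent
event age `T = b(-ln u · e^{-eta})^{1/a}` from the inverted Weibull-PH
survival curve. Left truncation is imposed by rejection: subjects whose
latent event precedes entry are discarded and redrawn, mirroring a design
that excludes prevalent cases. Follow-up ends at age 80. The default
baseline (shape 5, scale 161 years) puts cumulative incidence by 80 near
3%, i.e. inside the rare-disease regime the estimators assume; the default
effect sizes (hazard ratio 2 for current smoking, 1.3 for previous, modest
socio-economic and education gradients on both exposure prevalence and
hazard) are chosen as typical of strong established risk factors.

Interventional cohorts force exposure levels *after* the confounder draw,
so `P(Z)` is untouched — this is the definition of `do(X=x)` for this
diagram. Counterfactual pairs share the uniform draw and the `(Z, W)`
pattern between the two exposure settings (monotone coupling), giving sharp
per-subject potential outcomes.

Ground truth comes from two independent routes that share no code with the
estimators: exact summation of the adjustment formula over the discrete
joint distribution induced by the generative model (`af_exact`,
`do_probability`, `do_rate_ph`), and paired Monte-Carlo simulation
(`af_counterfactual_mc`, `ett_mc`) with binomial standard errors propagated
by the delta method (conservatively ignoring the positive pairing
correlation, so quoted errors are slight overestimates).

What the simulator does *not* emulate: competing-risk dependence between
outcomes (latent times are independent given covariates), informative
censoring, time-varying exposures, measurement error in covariates, and
continuous covariates. Passing tests therefore demonstrate correctness of
the estimators under the assumed causal diagram and proportional hazards —
not robustness to violations of those assumptions in real data.

## Landscape survey

The survey emulates a biobank-wide design on a subjects table plus a
long-format diagnosis table. For each disease code: the outcome is the
first incidence in the code's ICD-10 chapter; subjects whose chapter-first
event precedes entry are excluded, as are subjects with a qualifying prior
diagnosis (default: any `C` code except `C44`, non-melanoma skin cancer);
follow-up is censored at death, at the first qualifying post-entry
diagnosis, or at the study end. Two conventions the source design leaves
open are fixed here: a chapter-first event of a *different* code censors
follow-up at that age (the subject can no longer have the target code as
chapter-first), and when ages tie, censoring causes take precedence over
events (death > exclusion diagnosis > study end > event).

Each code x sex stratum with at least 140 cases (ten cases per adjusted
parameter, with margin for a two-parameter baseline) is fitted once; the
three reported contrasts — smoking-only, BMI-only, and smoking+BMI jointly
as the exposure set with everything else moved to `W` — are decompositions
of that single fit, so the joint fraction propagates the smoking–BMI
correlation through the confounder weights. Inclusion in the reported
landscape requires a Benjamini–Hochberg-significant Wald test (level 0.05
by default) for current-vs-never smoking or top-vs-middle BMI tertile;
jointly reported diseases are those included by either screen. Records are
tiered at A_f thresholds 0.5 / 0.35 / 0.2 (and -0.2 for protective
associations) and ranked both by A_f and by |attributed cases|, with ties
broken by code string. Chapter summaries report the median A_f over member
diseases with A_f > 0.2, for chapters with at least five such diseases.
The sensitivity re-run repeats the survey under stricter exclusion
prefixes and summarises the per-disease shift in the joint fraction
(mean/median/SD).

## Problem sizes and numerical choices

The bundled synthetic studies use cohorts of 20,000–200,000 subjects and a
20-outcome landscape at 100,000 subjects (10 repeat seeds at 20,000 for the
selection error-rate study); these sizes give Monte-Carlo errors comfortably
below the tolerances being asserted while keeping a full run in minutes on
one core. Newton iterations stop when the log partial likelihood is stable
to a relative 1e-9 with a small gradient; the Weibull MLE uses Nelder–Mead
on `(ln a, ln b)`. All simulation entry points take explicit integer seeds
and are byte-reproducible.

## Known limitations

* The attribution fractions are causal only under the assumed diagram; if
  exposures influence confounders, or an adjusted covariate is a mediator,
  the estimates lose their interpretation.
* The rare-disease approximation degrades for high-risk subjects at ages
  where `H` approaches 0.1–1; use `af_age` (exact `F`) there.
* The ETT fraction relies on the proportional-hazards form; it is exact in
  the rare limit and acquires an `O(H)` bias otherwise.
* Bootstrap intervals ignore uncertainty in the survey's selection step
  (post-selection inference is out of scope).
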