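# Methods

## The model

`densityjm` couples two submodels for a screening cohort of women observed
from age 40 to at most age 80 (all internal time is *model time*
t = age − 40 years; user-facing files carry ages).

**Longitudinal submodel.** The square root of dense breast area (√cm²),
measured at each screen, is

    y_ij = m_i(t_ij) + e_ij,          e_ij ~ N(0, σ²),
    m_i(t) = x_i(t)'β + z_i(t)'b_i + u_i'δ,      b_i ~ N(0, D),

where the time design is a 3-column natural cubic spline basis with
interior knots at ages 50 and 55 and boundary knots at ages 43 and 65
(linear extrapolation beyond the boundaries, zero second derivative at
them).  The 13 fixed effects are the intercept, the three spline terms, and
spline-by-MHT (never/former/current) and spline-by-menopausal-status
(pre/post) interactions, which let the shape of the age trend differ by
hormone treatment and menopause — an approximate stand-in for individual
menopause timing.  δ holds baseline effects of BMI, MHT and menopausal
status; the random effect b_i (intercept + three spline coefficients, the
same basis as the fixed trend) gives each woman her own trajectory.
Measured values are recorded untruncated: the Gaussian error model permits
small negative observations on the square-root scale, and we keep fidelity
to the model rather than to physical plausibility.

**Event submodel.** Time to breast-cancer diagnosis follows a proportional
hazards model

    h_i(t) = h0(t) · exp( γ'w_i + f(m_i(·), b_i, α) ),

with w_i = (BMI, MHT former, MHT current, FH yes, FH missing) and log h0(t)
a penalized cubic B-spline (P-spline): 8 basis columns on equally spaced
knots over ages 40–80 with a second-order difference penalty whose weight τ
gets a Gamma(1, 0.005) prior.  Three association structures are supported:

* **current value** f = α·m_i(t);
* **current value and slope** f = α₁·m_i(t) + α₂·m_i′(t), with the raw
  (uncentred, unscaled) derivative;
* **cumulative** f = α·∫_{t0}^{t} m_i(s) ds, with t0 defaulting to 0 (age
  40, the screening lower limit), aligning the accumulation origin with the
  risk time origin; it is configurable.

Women enter the risk set at their **second screen** (delayed entry); the
likelihood conditions on survival to entry, i.e. the event contribution is
`event·log h_i(exit) − ∫_entry^exit h_i(s) ds`, so the hazard before entry
never enters.  Measurements taken before risk entry (the first screen) do
enter the longitudinal submodel.  Covariates are fixed at baseline.

## Numerics

* The trajectory basis is built from cardinal natural cubic splines stored
  as piecewise polynomials, so derivatives and integrals are closed-form —
  the cumulative association needs no inner quadrature.
* The cumulative hazard uses fixed-order Gauss–Legendre quadrature, 15
  nodes per segment, with the integration interval split at the spline
  knots where the integrand loses smoothness.  A 10,000-panel trapezoid
  oracle bounds the error below 1e-6 relative in the tests.
* Event times are simulated by inverting the same cumulative-hazard code
  the likelihood uses (exponential draw, root bracketing to 1e-8 years),
  so simulator–likelihood consistency is certified jointly by the
  probability-integral-transform uniformity test.
* Baseline-basis evaluation clamps to ages [40, 80]; the trajectory basis
  extrapolates linearly as the natural constraints dictate.

## Inference

Metropolis-within-Gibbs over (β, δ, σ, D, γ, α, baseline coefficients, τ,
{b_i}).  Distinctive choices, each addressing a slow direction found while
profiling mixing:

* (β, δ) is proposed from its exact Gaussian conditional under the
  longitudinal submodel and accepted with the survival-factor ratio
  (independence MH; acceptance is near 1 because the event process carries
  little information about 17 trajectory coefficients).
* Random effects are proposed for all subjects at once from their exact
  per-subject Gaussian conditionals given the longitudinal data and the
  N(0, D) prior (batched 4×4 solves), corrected by the survival factor.
* An interweaving translation move shifts the four shared fixed-effect
  directions against all random effects; the likelihood is invariant, so
  the shift has an exact Gaussian conditional under the priors.  This
  breaks the classic mean/random-intercept coupling.
* The hazard linear predictor is evaluated internally with mean-centred
  covariates and *linearly detrended* association functionals, the removed
  constant-plus-linear part being absorbed into the baseline coefficients
  (exactly, via the Greville abscissae).  Without this, the cumulative
  structure's α is nearly collinear with the baseline trend and mixes an
  order of magnitude more slowly.  Recorded baseline draws are shifted back
  to the plain parametrization; the smoothness prior is placed on the
  centred coefficients.
* γ, α and the baseline coefficients get adaptive random-walk updates —
  singly and as one joint block whose empirical proposal covariance learns
  the γ–α–baseline correlations.  Initial proposal scales are inverse-
  Fisher-style, 1/(√events · sd(covariate)), so rare categories (e.g.
  family history "missing") mix from the first sweep.
* D is a conjugate inverse-Wishart Gibbs draw (default prior: df 5, scale
  I).  A scales + LKJ(2) alternative is provided, updated by a random walk
  on log-scales and tanh-transformed D-vine partial correlations.
* σ uses a log-scale random walk (Half-Normal(10) prior); τ is a conjugate
  Gamma draw (the difference penalty leaves rank 6 of 8).

Defaults: 2 chains, 5,000 iterations with 2,500 burn-in, thinning 1.
Adaptation (Robbins–Monro scales, Haario empirical covariances) runs during
burn-in and is then frozen.  Convergence is flagged — not silently ignored
— when any split-R̂ exceeds 1.1.  Priors on regression coefficients are
Normal(0, 100²).  A `temperature` parameter multiplies the data
log-likelihood; temperature 0 samples the prior, which the tests use to
validate the sampler against known prior quantiles.

**DIC** uses the hierarchical (conditional) deviance, −2 × the data log
likelihood given the sampled random effects: DIC = mean(D) + pD,
pD = mean(D) − D(posterior means), with the posterior mean of each b_i
plugged into the second term.  This matches common joint-model software
practice; a marginal-deviance DIC would require integrating over b and is
out of scope.  **Bayes p-values** are two-sided tail probabilities,
2·min{Pr(θ>0), Pr(θ<0)}, capped at 1 — the reading we adopt for the
ambiguous "tail probabilities for containing zero" convention.

## The synthetic cohort generator

The generator is first-class, tested code that defines the study
conditions.  Defaults emulate a large Swedish screening cohort: baseline
ages uniform on 40–74; screens every 18–24 months (gaps uniform on
1.5–2.0 years), starting at baseline and stopping at min(age 80, baseline +
6 years); administrative censoring at that same horizon, giving a mean
follow-up from baseline near 5.4–6 years; risk entry at the second screen;
women whose window cannot hold a second screen are redrawn.  Covariate
marginals: MHT never/former/current = 0.821/0.142/0.037; menopausal status
pre/post = 0.486/0.514; family history no/yes/missing = 0.840/0.134/0.026;
BMI truncated normal on [15, 50] with the location calibrated so the
post-truncation mean is 25.2 (SD 4.2).  Menopausal status is drawn
independently of age by default, matching the model; an optional
age-linked mode (logistic in age, centred at 51) exists for realism
experiments.

Truth parameters for recovery tests are order-of-magnitude choices shaped
like what such a cohort produces (declining spline means near −2.2 to −2.7,
BMI effect −0.179, σ = 0.547, a random-effects covariance with large
spline variances and negative intercept–spline covariances, hazard
coefficients like γ_FH-yes = 0.518, and association coefficients 0.130 /
(0.120, −1.160) / 0.008 per structure).  They are fixtures, not estimates.
The default baseline log hazard is linear in t (slope 0.03/year, rising
with age) with its level calibrated once so the default conditions yield an
event fraction near 1.3% — roughly 518 diagnoses in a cohort of 40,087.

What the generator does **not** emulate: raw mammograms or the image
measurement pipeline; informative visit processes (visits are ignorable by
construction); tumour onset-versus-detection latency; staggered calendar
enrolment (a single administrative horizon stands in for it); and the
exact screens-per-woman distribution (cases do have fewer screens than
non-cases, but only qualitatively).  Passing recovery tests therefore shows
the estimation machinery is correct under the stated model, not that the
model is correct for any particular real cohort.

## Problem sizes in the test tier

Recovery and coverage experiments run at reduced scale as the package's own
test design: single recovery fits use n = 800 subjects; interval-coverage,
DIC-selection and null-recovery suites use 20 replicates at n = 600, 300
and 400 with shortened chains (≈1,000–2,200 iterations); the null suite is
sized so each replicate carries ~60–90 events, the regime in which the
credibility interval's frequentist coverage is near nominal.  The recovery
fixtures use a
baseline level of exp(−5) instead of the cohort-scale exp(−8) so the event
submodel is informative at these sizes (15–25% events rather than 1.3%).
At the cohort-scale event rate a desk-sized n would carry only a handful of
events and the association parameters would be prior-dominated.  One
consequence of small strata is worth knowing: when a rare category (family
history "missing", 2.6%) happens to contain zero events in a replicate, its
log hazard ratio drifts to the diffuse prior's negative range and the
credibility interval can exclude the truth — a separation effect, not a
sampler defect; the chosen suite sizes keep its probability low.

## Known limitations

* No lagged association, time-varying α(t), competing risks,
  interval-censoring between screens, cure fractions, or multivariate
  longitudinal outcomes.
* Frequentist standard errors are not provided; inference is posterior
  summaries, Bayes p-values and DIC.
* The Metropolis-within-Gibbs sampler targets the exact posterior but
  variance components of weakly identified spline directions (late-age
  random effects in short follow-up windows) converge slowly; the split-R̂
  flag should be heeded for D entries.
* DIC magnitudes depend on cohort size and composition; only comparisons
  between association structures on the same data are meaningful.
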