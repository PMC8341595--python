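# Methods

## Data model

The unit of observation is one cone: `(house, wall type, treatment, age
group, visit month, cone height)` with the number of mosquitoes exposed and
the cumulative number dead at each post-exposure holding hour (24, 48, 72,
96, 120 h). Cumulative dead counts are non-decreasing in hour by definition
(dead mosquitoes stay dead); the reader rejects rows violating this or any
count bound, reporting row numbers rather than dropping rows. Missing reading
hours are represented as absent keys, never zeros, and survive CSV
round-trips as empty cells.

Visits are scheduled on a half-month grid (1.5, 2.5, …, 12.5 months
post-spray). A visit that slipped more than 0.5 month past its scheduled slot
is regrouped into the subsequent grid month; the 0.5-month cutoff is the
natural midpoint of the monthly grid, makes regrouping idempotent, and every
reassignment is logged. Visits at or before the spray date are errors.

Cone heights (~0.4/1.0/1.6 m) are aggregated per house visit before analysis
— the package's own Poisson contrast of heights on generated data finds none,
and the height contrast remains available for real data where the decision
should be re-checked.

## Control gating and Abbott's correction

Per wall type, age group and month, control mortality is pooled across the
(up to two) unsprayed houses; per-house matching is impossible because
controls are distinct houses. Gates, applied as a partition (every point
receives exactly one):

- pooled control mortality at 24 h > 20% → the arm-month is **discarded**
  (all hours); the discard signal is defined at 24 h because that is the
  standard bioassay validity check;
- control ≥ 5% at the observation hour → **Abbott-corrected**,
  `(observed − control)/(1 − control)`, clamped below at 0 (negative
  corrected mortality has no biological meaning at this scale);
- control < 5% → **raw**;
- control = 100% at a delayed hour → **uncorrectable** (the formula is
  undefined); the observed mortality is reported uncorrected and flagged.

Each delayed hour is corrected against *that hour's own* control mortality,
because background mortality grows substantially with holding time (and with
mosquito age); correcting 120 h exposed mortality with 24 h control mortality
would leave most of the background in. The alternative (gate and correct
everything on the 24 h control) is available via
`control_hour_mode="h24"` for sensitivity analysis. Months with no matched
control cannot be gated; they are flagged, excluded and logged.

Mortality is carried as fractions throughout; percent formatting happens only
at report time.

## Residual-efficacy duration

WHO's criterion for effective IRS is mortality ≥ 80%. Field series of
slow-acting products routinely dip below the threshold for a month and
recover, so the duration is defined as the **last** observed grid month at or
above threshold, with all earlier sub-threshold months reported as dips. A
strict variant (duration ends before the first dip) is available via
`rule="strict"`. The comparison is made after rounding mortality to one
decimal in percent — the reporting precision — so 79.95% counts as 80%. When
the final observed month is still at/above threshold the duration is
right-censored at the end of follow-up and flagged as such. No interpolation
between grid months is attempted.

## Time–mortality model

For one stratum (wall type × age group × hour), pooled monthly counts are

    Ndead_i ~ Binomial(Ntotal_i, m(t_i)),   m(t) = expit(β₁ + β₂ t),

with `t` in months post-spray. β₁ sets the initial kill level on the logit
scale and β₂ the monthly depreciation (negative for a decaying deposit).
Abbott correction produces fractional dead counts; these are rounded to the
nearest integer per pooled month for the binomial likelihood. A
control-background term in the likelihood would avoid the rounding but is out
of scope here.

Priors are weakly informative and configurable: β₁ ~ N(0, 10²),
β₂ ~ N(0, 2²) on the logit/month scale. They regularise separable months (0%
or 100% dead) without materially informing lethal times at campaign sample
sizes (~200-300 mosquitoes per month per arm).

Sampling uses four independent adaptive random-walk Metropolis chains of
1000 iterations with the first 500 discarded as burn-in (retained draws =
chains × (iterations − burn-in) = 2000 by default; the run shape is
configurable). Chains start overdispersed around the posterior mode with a
proposal covariance from the Laplace approximation scaled by 2.38²/d; the
proposal scale adapts toward ~30% acceptance in blocks of 25 iterations
during burn-in only, so the retained chain is a valid time-homogeneous
Metropolis sample. Convergence is assessed with the rank-normalised split-R̂
and effective sample size (arviz); a fit with max R̂ > 1.05 is returned
flagged with a warning, never silently. Seeded runs are bit-reproducible
(per-chain seeds are spawned from one seed sequence). The test suite
cross-checks the sampler against an independent ensemble sampler (emcee) and
the MLE against a statsmodels binomial GLM; a 100-replicate
simulate–correct–fit study at the field design size verifies nominal 90%
credible-interval coverage and sub-half-month LT50 bias.

Lethal times invert the curve per draw, `LT_p = (logit(p) − β₁)/β₂`, and are
summarised by the median and central 90% interval. Draws with β₂ ≥ 0
(non-decaying) or a negative lethal time are excluded and their fraction
reported; the estimate is flagged undefined when they exceed half the
posterior mass, or when the posterior-median curve never attains `p` within
`[0, horizon]` (default horizon 36 months). For β₂ < 0, LT90 ≤ LT50 ≤ LT10 on
every draw where all are attained.

`fit_mle()` provides the maximum-likelihood point estimate by direct
numerical optimisation of the same log-likelihood, as an internal
cross-check; it raises on single-time-point (non-identifiable) or separable
data rather than returning a diverged estimate.

## Poisson group comparisons

Observed mortality over the study period is compared across design factors on
monthly Abbott-adjusted dead counts with a log-link Poisson GLM and
`log(houses)` offset — the number of houses contributing to the cell is the
exposure, so `exp(β)` is a per-house-visit mortality rate ratio. Fitting is
statsmodels IRLS to the MLE; contrasts are Wald-based. Cells from discarded
arm-months are dropped; a design matrix that is rank-deficient raises an
error naming the columns, and an all-zero group triggers a separability
warning. The exact design (which interactions, which strata pooled) is the
caller's choice; the package defaults to additive main effects.

## Synthetic campaign generator

The generator is the analysis model run forward with the field design
geometry: per wall type, 6 sprayed and 2 control houses; 3 cones × 10 females
per house visit; monthly visits on the 1.5–12.5 grid, with old (13–26 d,
previously blood-fed) mosquitoes entering from month 4.5 as colony logistics
allow. A sprayed cone mosquito dies by hour `h` with probability

    P_h(t) = 1 − (1 − m_h(t)) · (1 − c_h),

where `m_h` is the stratum logistic and `c_h` the control background —
independent competing risks, chosen deliberately so that Abbott's correction
is exactly unbiased in expectation and the correction module's recovery is a
testable property. Control-house mosquitoes die with `c_h` alone. Per-cone
counts are drawn by cumulative thinning: survivors of hour `h` face the
incremental hazard `(P_{h+1} − P_h)/(1 − P_h)`, guaranteeing monotone dead
counts by construction. Equal seeds give bit-identical campaigns.

Defaults (chosen once as a realistic slow-acting IRS campaign, and what
passing tests do and do not show):

- Per-stratum `(β₁, β₂)`: a common slope per wall × age (−0.45 to −0.55
  /month) with per-hour intercepts rising from ~1.3–1.6 (24 h) to ~6.5–7.2
  (120 h). These place 24 h mortality below the 80% threshold throughout
  (the delayed-action signature), 72 h durations at roughly 6.5–9.5 months
  depending on wall and age, and 120 h durations up to beyond the end of
  follow-up. Wall differences are intentionally small: real campaigns show
  slightly different per-wall durations without statistically significant
  overall contrasts, so the significance of the wall contrast in any single
  simulated campaign fluctuates.
- Control background grows with holding hour and age: young 2→10%, old
  5→25% across 24→120 h, reflecting senescence of held mosquitoes.
- Missed-visit probability 0.18 per sprayed house-month, reproducing the
  ~54 house-visits and ~1.6 thousand mosquitoes per young arm typical of a
  real 11-month campaign; late-visit probability 0.15 with a slip of
  0.25–0.9 month, so that both regrouped and non-regrouped late visits
  occur (a slip past the cutoff replaces the house's next scheduled visit).

The generator emulates the statistical structure of a campaign, not its
biology: no house-level heterogeneity in spray quality, no insectary batch
effects, no drift in control-colony fitness, and the decay truly is logistic.
Passing recovery tests therefore demonstrate that the estimation chain is
correct and calibrated under the model's own assumptions — not that real
campaigns follow the model.

## Problem sizes and numerics

The recovery study uses 100 replicates of the single-stratum design
(6 houses × 3 cones × 10 females × 10 monthly visits) with β₁ = 5.2,
β₂ = −0.55 — enough replicates to bound 90% coverage within ±3 binomial
standard errors (±9 points) and LT50 bias below 0.5 month, while the whole
suite stays fast. The likelihood is evaluated on the logit scale
(`log_expit`) so it is finite and accurate for all finite parameters; the
Laplace covariance uses a central-difference Hessian with eigenvalue
clipping; lethal-time inversions guard division by β₂ = 0. Duration
tie-breaks (rounding to reporting precision, inclusive ≥) are described
above.

## Known limitations

- Abbott-corrected counts are rounded before the binomial likelihood; for
  small cells this loses a little information.
- No hierarchical house effects: months are pooled, as is standard for cone
  bioassay reporting, so between-house variance inflates the binomial
  dispersion slightly and credible intervals can be mildly optimistic on
  strongly heterogeneous data.
- The Poisson comparison ignores overdispersion; rate-ratio p-values on real
  data should be read qualitatively.
- Lethal times extrapolate the logistic beyond the observation window
  whenever LT_p exceeds the last visit month; the `defined` flag and horizon
  make this explicit but cannot make extrapolation data-driven.
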