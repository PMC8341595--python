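# irsefficacy

Residual-efficacy analysis for indoor residual spraying (IRS) campaigns
monitored with WHO cone wall bioassays.

Malaria control programmes spray interior walls with residual insecticides and
track, month by month, how long the deposit keeps killing mosquitoes. The
standard monitoring instrument is the WHO cone bioassay: ~10 susceptible
female *Anopheles* are held under a plastic cone against the wall for 30
minutes and mortality is scored afterwards. For slow-acting actives such as
the neonicotinoid clothianidin, mortality read at the standard 24 h
post-exposure badly understates the product's effect, so readings are extended
to 48–120 h ("delayed mortality"). This package implements the full analysis
chain that field entomology / M&E teams need for such data:

- **Campaign data model & I/O** — one CSV row per cone per house visit, with
  validation (dead counts non-decreasing across holding hours, counts within
  exposure totals), regrouping of late visits into the subsequent half-month
  slot (1.5, 2.5, … months post-spray), and aggregation over cone heights.
- **Control gating & Abbott's correction** — per month and arm, exposed
  mortality is pooled and set against the pooled unsprayed-control mortality
  of the same wall type and age group: control > 20% at 24 h discards the
  bioassay; control ≥ 5% triggers Abbott's correction
  `corrected = (observed − control) / (1 − control)`; 100% control mortality
  makes the correction undefined and the point is flagged and left raw.
- **Residual-efficacy duration** — the number of months mortality stays at or
  above the WHO 80% threshold, tolerating interior sub-threshold "dip" months
  (reported separately), with censoring when the last observed month is still
  above threshold.
- **Bayesian time–mortality model** — dead counts are binomial with kill
  probability `m(t) = 1 / (1 + exp(−(β₁ + β₂ t)))` over months `t` since
  spraying. The posterior of (β₁, β₂) under weakly-informative normal priors
  is sampled with 4 adaptive random-walk Metropolis chains (1000 iterations,
  500 burn-in each), checked with split-R̂ and ESS, and inverted draw by draw
  into lethal times `LT_p = (logit(p) − β₁)/β₂` for p = 90/50/10% mortality
  with central 90% credible intervals.
- **Poisson group comparisons** — monthly Abbott-adjusted dead counts compared
  across wall surfaces, mosquito age groups and cone heights with a log-link
  Poisson GLM using the number of contributing houses as offset (rate ratios,
  Wald CIs, p-values).
- **Synthetic campaign generator** — the model run forward with the field
  design geometry (6 sprayed + 2 control houses per wall type, 3 cones × 10
  females, monthly visits, late/missed visits, hour- and age-dependent control
  background), so the whole pipeline is testable end to end with no external
  data, including credible-interval calibration studies.

## Worked example

```python
import irsefficacy as ie

# a complete synthetic campaign with the default field design
records, truth = ie.simulate_campaign(ie.SyntheticConfig(seed=1))
records = ie.regroup_months(records)

# corrected 72 h series for young mosquitoes on cement walls
series = ie.build_corrected_series(records, "cement", "young", 72)
d = ie.residual_duration(series)
print("duration:", d.duration_months, "censored:", d.censored)

res = ie.TimeMortalityModel.from_corrected_series(series).fit(seed=1)
print(res.summary().round(3))
for p in (0.9, 0.5, 0.1):
    lt = res.lethal_time(p)
    print(f"LT{int(p*100)}: {lt.median_months:.1f} months "
          f"(90% CI {lt.ci_low:.1f}-{lt.ci_high:.1f})")
```

prints

```
duration: 6.5 censored: False
           median  ci_low  ci_high   rhat      ess
parameter
beta1       5.418   5.031    5.870  1.018  258.556
beta2      -0.575  -0.620   -0.533  1.016  272.472
LT90: 5.6 months (90% CI 5.3-5.9)
LT50: 9.4 months (90% CI 9.3-9.6)
LT10: 13.3 months (90% CI 12.9-13.7)
```

Read: 72 h mortality on this arm stayed at/above the WHO 80% threshold through
month 6.5; the fitted curve starts near `expit(5.4) ≈ 99.6%` kill and loses
about 0.58 logits per month; mortality is expected to fall through 90% around
month 5.6, 50% around month 9.4 and 10% around month 13.3. The duration for
this seed matches the generator's true 80%-crossing month (6.5) and the LT50
matches the true value `−β₁/β₂ = 9.45` of the generating parameters.

The same pipeline is available from the shell:

```sh
irs-efficacy simulate --seed 1 --out campaign.csv --manifest truth.json
irs-efficacy correct  --input campaign.csv --out corrected.csv
irs-efficacy efficacy --input campaign.csv --out durations.csv
irs-efficacy fit      --input campaign.csv --hours 72 --seed 1 --out fits.json
irs-efficacy compare  --input campaign.csv --covariates wall_type --out contrasts.csv
irs-efficacy report   --input campaign.csv --out-dir report/
```

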