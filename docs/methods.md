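# Methods

## Model structure and assumptions

The model is a proportional multistate life table over a closed cohort
population: every sex × ethnicity × single-year-of-age (18–110) stratum of
the 2011 baseline adult population is followed until the closure age of 110,
with no births or migration.  A main life table carries all-cause mortality
and a prevalent-morbidity utility decrement (pYLD); fourteen disease life
tables run in parallel as proportions of each cohort, independent of the
main table's survival except through the mortality/morbidity linkage
("proportional" design).  Comorbidity interactions are not modelled.

The intervention is a one-off, one-year campaign.  Its only modelled
pathway is a mean BMI shift in the eligible sub-population; diet-quality or
physical-activity benefits beyond BMI are excluded by design.  The full
pooled trial effect is applied in the intervention year (year 0), since the
trials pooled into the effect estimate ran at most nine months, within one
annual cycle.

## Key equations and numerical choices

* **PIF**: `PIF = p·(1 − e^{βδ})` with `β = ln RR` per kg/m².  A location
  shift of a sub-population factorises out of the risk integral under a
  log-linear RR, so this form is exact for any BMI distribution — this is
  the module's central modelling commitment, and the test suite verifies it
  against numerical integration over normal mixtures to 1e-8.  PIFs modify
  incidence only, never case fatality or remission.
* **Lags**: incidence changes are spread uniformly over integer-year
  windows, 0–5 years (cardiovascular, diabetes, osteoarthritis) and 10–30
  years (cancers), implemented as a uniform moving average of the raw PIF
  series with zero history before year 0.
* **Regain trajectory**: δ(0) equals the full effect; from `regain_delay`
  years on, δ(t) = clip(effect + max(0, t − delay)·rate·12, effect, 0),
  evaluated at integer years.  At the default rate of 0.03 kg/m²/month an
  effect of −0.36 kg/m² is fully eroded at t = 1; the base case starts
  regain immediately after the intervention year (delay 0).
* **Disease step**: annual cycles with exponential rate→probability
  conversion; cases incident within a cycle face half a cycle of case
  fatality/remission exposure; exits from the case compartment split
  proportionally between death and remission.  This tracks daily ODE
  integration to better than 1e-4 per cycle at realistic rates, and
  conserves S + C + D to machine precision.
* **Main table**: survival `e^{−m}` per year, forced to zero beyond the
  closure age; life-years by half-cycle correction; QALYs = life-years ×
  (1 − pYLD).  The intervention arm's all-cause mortality is the BAU rate
  minus the summed difference in disease-death flows; its pYLD is the BAU
  value minus Σ (prevalence difference × disability weight); both are
  clipped to valid ranges with clipping logged (clipping signals
  implausible inputs, it never occurs on the default synthetic bundle).
* **Costs**: per disease, incident×(first-year cost) + (prevalent −
  incident)×(subsequent-year cost) + death-flow×(last-6-months cost), plus
  an unrelated annual cost for everyone alive.  Disease-state proportions
  are weighted by the arm's alive person-years, so people dead of other
  causes stop accruing costs; this also captures the extra unrelated costs
  of people living longer.  The campaign's implementation cost is booked
  once, in year 0, undiscounted; in subgroup reporting it is apportioned by
  baseline population share.
* **Discounting**: present value at 2011, `Σ v(t)/(1+r)^t`, default r = 3 %
  for both QALYs and costs; 0 % and 6 % as scenarios.  The first 10-year
  horizon is t ∈ [0, 9], the 20-year horizon t ∈ [0, 19].
* **NZ$ → US$**: a single configurable factor (0.673), reporting only.

## Uncertainty analysis

Parameters are sampled independently: beta for the three cascade
proportions (smartphone ownership SD 5 % of central, recognition and uptake
20 %), normal for the pooled effect with SD from its 95 % CI
((upper − lower)/3.92 ≈ 0.232 kg/m²), log-normal for the regain rate (20 %),
gamma for the campaign cost (20 %); beta/log-normal/gamma are
moment-matched to (mean, SD).  Lag-window endpoints are sampled per draw as
normal with SD 20 % of the central value, rounded to non-negative integers
with min ≤ max enforced.  Draw *d* uses the seed-sequence substream
`(seed, d)`, with the six parameters sampled first and then the lag
windows, so any draw is reproducible in isolation.  Uncertainty intervals
are empirical 2.5th/97.5th percentiles over the draws (default 2000;
the test suite uses 200 and the acceptance script 500 to keep runtimes in
seconds-to-minutes on one CPU — one paired run takes ~70 ms).

Because the effect's 95 % CI crosses zero, some draws sample a harmful
(positive) BMI change.  The public trajectory function rejects positive
effects — the intervention's central estimate must not increase BMI — but
the Monte Carlo path mirrors the trajectory (the same regain dynamics pull
a BMI increase back to zero), so sampled harm propagates honestly rather
than being truncated, and uncertainty intervals can legitimately cross
zero.

Uncertainty intervals are attached to the aggregate rows only (overall, by
ethnicity, by sex); the finest sex × ethnicity × age-band cells report
expected values.

## Equity adjustment

Māori strata receive the same-age-same-sex non-Māori all-cause mortality
and pYLD schedules in both arms; Māori BMI, disease relative risks and the
uptake cascade are untouched.  This removes the ethnic gap in background
life expectancy so that health gains accruing to Māori are no longer cut
short by earlier background death; non-Māori results are bitwise unchanged.
Which schedules to substitute is a genuine design choice; substituting
mortality + pYLD is the interpretation implemented here.

## Synthetic population

The generator emulates the structure of the national parameterisation this
model class is normally fed, not its values:

* Gompertz all-cause mortality `m(a) = m₀·e^{g(a−18)}` with m₀ = 2×10⁻⁴,
  g = 0.10, a male factor of 1.4 and a Māori gap factor of 1.5 (applied
  multiplicatively, so the ethnic ratio is exact at every age and
  monotonicity is preserved).  These give remaining life expectancies at 18
  of roughly 50–57 years (expected ages at death of 68–75), deliberately on
  the realistic side for a high-income adult population.
* pYLD rising linearly with age (0.02 at 18, ~0.22 at 110), Māori ×1.15.
* Mean BMI rising from 26 toward ~29 kg/m² in midlife with a slight old-age
  decline, Māori +1.5 kg/m², SD 4.2; overweight/obesity proportion 0.73 in
  every stratum (configurable; whether it varies by stratum is exposed as a
  knob because the base analysis treats it as uniform).
* Disease incidence exponential in age with disease-specific levels and
  slopes, sex factors (including female-only cancers), case fatality with a
  mild age slope, remission for the ten cancers only, log-linear RRs per
  BMI unit that taper linearly to 1 between ages 45 and 95 (standard
  old-age attenuation), and per-phase costs of plausible magnitude.
* Mild deterministic jitter per stratum (uniform ±5–8 %) driven by the
  seed, so distinct seeds give distinct but structurally identical bundles.

What it does **not** emulate: real age-specific rate shapes (no mortality
"accident hump", no screening-driven cancer incidence bumps), correlations
between diseases, stratum-specific overweight prevalence, cohort trends
(rates are fixed at their 2011 values for life), or the actual levels of
any national dataset.  Passing tests therefore demonstrate the model's
internal correctness, identities and orderings — not the published
headline magnitudes, which depend on the unreleased national inputs.

## Known limitations

* Annual resolution; no sub-annual dynamics or microsimulation.
* BMI enters only as a mean shift — no change in variance or shape.
* The cascade treats its stages as independent of BMI status after the
  first; social diffusion of app uptake is not modelled.
* The legacy-effect scenario converts a weight effect (kg) to BMI units by
  dividing by a configurable mean height squared (1.69 m → 2.856 m²).
* Scenario expected values use pure central-value propagation (no fixed
  Monte Carlo seed).
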