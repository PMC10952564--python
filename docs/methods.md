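# Methods

## Model structure

`donorsim` is an individual-level discrete event simulation. Each simulated
donor has an index donation at day 0 with an analyzer hemoglobin
measurement, then cycles through invitation → attendance → outcome events
until the next invitation would fall on or after day 365 or the strategy's
annual invitation cap is reached (4 for fixed recall, 6 for personalized
recall). The clock runs in integer days; intervals are resolved on a
whole-week grid (reports are in weeks) with 1 week = 7 days. Invitations
issued before day 365 are simulated to completion even when attendance
falls after the horizon; such events carry an `after_horizon` flag but are
included in the yearly accounting, matching the convention that a year's
recalls are everything *invited* within the year.

Per visit, the order of stochastic steps is fixed: lapse (per-invitation
dropout; a lapsed donor is treated as withdrawn for the rest of the year) →
attendance delay (whole weeks) → non-hemoglobin deferral → realization of
the donor's true hemoglobin → on-site screen where the strategy requires
one → classification. Under pure post-donation strategies every attendee
not deferred for other reasons donates; donors under threshold become
inappropriate bleeds by design. After a donation the realized true
hemoglobin (the post-donation analyzer value) becomes the anchor of the
next recovery trajectory; after a deferral the previous anchor is kept and
the trajectory clock continues from the prior donation.

### Hemoglobin recovery

Return hemoglobin is linear in time since the anchoring donation with a
common slope per sex stratum, adjusted for the anchor measurement, age,
ethnicity and blood group, with a donor-level random intercept (persistent
across that donor's visits) and fresh residual noise per visit. The
policy-facing probability of being over the donation threshold uses the
*marginal* predictive distribution — latent plus residual variance — since
the blood service observes only the last analyzer measurement, never the
donor's latent offset.

The personalized interval is the smallest whole week `t` in
`[floor, 52]` with `P(over threshold at t) ≥ p_min`. It is computed in
closed form by inverting the linear predictor at
`threshold + z(p_min)·σ_pred`, rounding up to a whole week, then nudging by
at most a step so the result agrees *exactly* with a week-by-week scan of
the probability function under floating point (the property suite checks
this equivalence on 1000 randomized donors). Donors who never reach the
certainty level by 52 weeks are invited at the cap and flagged; with
non-positive slope the probability is non-increasing, so a donor not
eligible at the floor is capped directly.

### On-site screening error

A donor whose true hemoglobin is at or above threshold always passes the
on-site screen. A donor `d` g/L below threshold still passes
("false pass" → inappropriate bleed) with probability
`1/(1 + exp(d/σ_m − c))`, a non-increasing logistic in the deficit;
defaults σ_m = 4 g/L, c = 2 give ≈0.88 near the threshold and ≈0.5 at an
8 g/L deficit, producing false-pass mixes in the range published screening
comparisons report. Setting σ_m = 0 disables false passes entirely.

### Costs

Money is held in integer pence, so total cost is an exact integer
combination of unit costs and event counts. Donations cost £26.49; under
post-donation strategies every donation adds the £0.79 off-site analyzer
test. Under the current strategy the £1.08 venous-HemoCue cost applies to
the slice of attendances that would fail the initial gravimetric screen —
modeled as all truly-under donors plus a configurable 10% of over-threshold
donors. Low-hemoglobin deferrals (£9.21) and other deferrals (£0.97) carry
their own bundled costs; lapses cost nothing. Under strategies B–D the mean
cost per donation therefore collapses to
`27.28 + 0.97·(other deferrals / donations)` exactly, which is why those
three strategies share one cost figure.

## Synthetic population

No individual-level donor records ship with the package; the generator
stands in for a returning-donor cohort. Defaults (all overridable in
`defaults.yaml`, flagged `assumed: true`):

- index hemoglobin: Normal(134, 10) g/L women, Normal(149, 11) g/L men,
  truncated below at 100 g/L — plausible analyzer values for donors who
  passed screening at their index donation;
- age Normal(43, 13) truncated to [18, 75]; ethnicity
  {White .88, Black .04, Asian .05, Mixed/Other .03}; eight ABO/RhD
  groups at typical England frequencies; covariates drawn independently;
- recovery model: slope 0.3 g/L/week, anchor coefficient 0.6, age
  coefficient 0.05 g/L/year, small category effects, between-donor sd
  4 g/L, residual sd 6 g/L;
- behavior: per-invitation dropout 0.098 (women) / 0.066 (men) and
  per-attendance other-deferral 0.054 / 0.040 — calibrated to published
  first-return event counts per 1000 invited donors — applied identically
  at every recall (no visit-order dependence); attendance delay geometric
  on weeks with mean 2, capped at 36.

The recovery intercepts (49.0 women, 52.0 men) were fixed once, jointly
against two published patterns that a single linear model cannot both
reproduce exactly: the interval-band structure (most donors eligible at
the floor under high certainty) and the first-return adverse-event counts.
The chosen values sit where the expected qualitative strategy orderings
(highest certainty maximizes donations per adverse event; early recall
maximizes donations; B–D share one cost) are stable, at the price of
under-predicting women's first-return under-threshold donations and
low-hemoglobin deferrals by roughly half. Men's first-return counts match
the published figures closely.

What the generator does **not** emulate: correlation between covariates
and index hemoglobin beyond the model terms, seasonal and venue effects,
informative observation (donors with low unobserved hemoglobin returning
later), non-linear early recovery (<8 weeks), ferritin/iron stores, and
donor-behavior responses to policy changes. Passing tests therefore
demonstrate correctness of the simulation machinery and internal
consistency of the method, not calibration to any real cohort.

## Fitting

`HbRecoveryModel.from_dataframe(table).fit()` estimates the recovery
regression with statsmodels. With one return per donor (the two-visit
design: index as covariate, single return as outcome) it is OLS, and the
between-donor and residual variances are not separately identifiable — the
total predictive sd is reported as the residual component. When donors
contribute repeated returns, a donor-level random intercept is added
(linear mixed model, REML) and the two components separate. Rank-deficient
designs raise an error naming the collinear terms. Category effects are
identified relative to the first level in sort order; the packaged
generating model uses a different reference, so recovered intercepts and
category effects agree with the truth up to that reparameterization (the
parameter-recovery tests compare contrasts).

## Uncertainty

Bootstrap intervals follow a parametric-perturbation design: per draw, the
data-informed parameters are sampled on their natural scales — normal for
coefficients, log-normal for standard deviations, logit-normal for
probabilities, using stored standard errors (packaged defaults are
assumption-scale) — a cohort of `size` donors is resampled with
replacement from the reference (latent offsets redrawn under the perturbed
between-donor sd), simulated for a year and summarized. The point estimate
is the median across draws; the 95% interval the 2.5th/97.5th percentiles.
Parameters without standard errors stay fixed, with a warning. The full
published design (1000 draws × 1000 donors) runs in a few minutes from the
CLI; the test suite and the acceptance script use scaled-down bootstraps
(tens to hundreds of draws of a few hundred donors) as their default
problem sizes.

## Internal validation mode

`first_return_mode` restricts the current-strategy simulation to one
invitation cycle per donor and lowers the women's floor to 12 weeks,
reflecting that in practice a meaningful fraction of women returned
between 12 and 16 weeks when regulations permitted. Its per-1000 counts
are compared category-by-category against the packaged published
observed counts, with percent differences rounded to the nearest integer;
the ratio row uses the donations-per-adverse-event formula
`(over + under) / (under + low-Hb deferrals)`.

## Numerical and design choices

- Random numbers: every donor gets an independent `SeedSequence(master,
  spawn_key=(donor_id,))` substream, so results are invariant to
  population size and iteration order, and runs are byte-identical given a
  seed.
- Strategy E's medium-certainty band membership is evaluated at the actual
  attendance time (late attendance raises the modeled probability), since
  the on-site decision happens in session.
- Invitation caps count all invitations, including post-deferral
  re-invites (the conservative reading).
- Ratios are reported to 1 d.p., money to 2 d.p. (pence), percent
  differences to the nearest integer. Zero-denominator ratios are NaN
  sentinels, never raised.
- Default problem sizes: 10,000 donors for headline runs, 5,000 for
  parameter recovery, 1000 donors for solver-equivalence sweeps.

## Known limitations

The linear common-slope recovery model understates heterogeneity at the
tails, which is precisely where adverse events live — the synthetic
first-return validation under-predicts women's adverse counts (see above),
mirroring the direction (though not the size) of the misfit the original
modeling study reported for men. Lapse is absorbing within the year;
re-engagement after a missed invitation is not modeled. The cost model is
blood-service-side unit costing only (no donor time, no health-economic
outcomes).
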