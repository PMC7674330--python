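# Methods

This note documents the models implemented in `hospeff`, the assumptions
behind them, the synthetic data-generating process used to exercise them,
and the numerical and design choices a maintainer should know about.

## The analysis in one paragraph

Hospitals are modelled as decision-making units (DMUs) transforming four
inputs — beds and three staffing groups in full-time equivalents (FTEs):
physicians, registered nurses, nurse assistants — into two outputs:
severity-adjusted inpatient discharges and outpatient cases. Technical
efficiency is estimated nonparametrically by input-oriented data envelopment
analysis (DEA) under variable returns to scale against a pooled
(intertemporal) frontier. The second stage asks how a hospital's
case-composition urgency — the urgency score UrS and the within-hospital
urgency dispersion UrD — relates to efficiency, controlling for ownership,
teaching status, market concentration, location type, and year. Because DEA
scores are biased and serially dependent by construction, inference uses the
Simar–Wilson double bootstrap (algorithm #2): an inner loop bias-corrects
the scores, an outer loop delivers valid bootstrap standard errors and
percentile confidence intervals for the truncated-regression coefficients.

## Case-composition measures

* **Case-mix weights.** Each diagnosis group g has a mean length of stay
  LOS_g; its weight is `pi_g = LOS_g / ((1/G) * sum_g LOS_g)`, so the G
  weights average exactly 1 (an algebraic identity the tests assert at
  1e-12). Adjusted inpatient volume is `sum_g pi_g * inpatients_{g,j}`,
  linear in the counts.
* **Urgency score.** Each 4-digit diagnosis code d carries an urgency value
  `u_d in [0,1]` (the probability that a case with this primary diagnosis is
  an emergency). `UrS_j` is the case-weighted mean of u over hospital j's
  inpatient cases; UrS < 0.5 marks an elective-dominated composition, UrS
  >= 0.5 an emergency-dominated one (the boundary counts as emergency).
* **Urgency dispersion.** `UrD_j` is the case-weighted sample standard
  deviation of u around UrS_j with denominator n−1. It is undefined for
  single-case hospitals and the package raises rather than reporting 0
  (the n−1 denominator would be 0). Codes without an urgency value are
  excluded from the UrS/UrD denominators and the excluded share is logged;
  they still count toward adjusted volume.

## Market concentration

Competition is proxied by a Herfindahl–Hirschman index inside a fixed
great-circle catchment (default radius 32 km, inclusive, haversine distance
on a sphere of radius 6371.0088 km). A separate HHI is computed per chapter
of the diagnosis classification from squared shares of inpatient discharges
of all hospitals in the catchment — the focal hospital included, as in any
market-concentration measure — and the chapter HHIs are averaged with the
focal hospital's own patient shares as weights. Markets are built within
each observation year. Each competitor enters with its total chapter volume
(not only the volume attributable to the focal catchment's population); this
is the simplest consistent reading and is noted as an assumption.

## First stage: DEA

For DMU o, `theta_o = min {theta : X'lam <= theta x_o, Y'lam >= y_o,
sum(lam) = 1, lam >= 0}` — the standard input-oriented envelopment form
under variable returns to scale (VRS), one linear program per DMU, solved
with HiGHS at default tolerances (~1e-9). Shephard distance is
`delta = 1/theta`. Implementation notes:

* All evaluation LPs against one reference set are stacked into a single
  block-diagonal sparse LP, and the reference set is first reduced to its
  non-dominated subset (a dominated reference point can never be needed in
  an optimal basis). Both transformations are exact; the test suite checks
  the scores against an independent multiplier-form (dual) implementation
  to 1e-7 and against hand-solved instances.
* Zero inputs: a radial input measure is undefined at zero. Scattered zero
  FTE cells are floored at a configurable epsilon (default 0.01 FTE) with a
  logged warning. An input column that is zero for *every* DMU is dropped
  instead — flooring it would create a constant column, which forces
  theta = 1 for all DMUs under input orientation.
* Free disposal hull (FDH) scores (dominance only, no convexification) and
  the share of FDH-efficient DMUs feed the curse-of-dimensionality
  diagnostic, together with the effective sample size `n^(2/(p+q+1))` (the
  parametric-rate equivalent of the nonparametric convergence rate). The
  warn threshold on the FDH-efficient share defaults to 0.5.
* Andersen–Petersen super-efficiency removes the evaluated DMU from its
  reference set; under VRS the program can be infeasible, which is reported
  as a per-DMU status rather than raised. DMUs with score > 1.2 (or an
  infeasible program, which indicates an even more extreme position outside
  the support of the remaining data) are flagged as outliers for the
  trimming sensitivity analysis.
* Constant returns to scale (drop the convexity constraint) exists only to
  test the nesting `theta_CRS <= theta_VRS <= theta_FDH`.

## Second stage: truncated regression and the double bootstrap

The model is `delta_i = z_i'beta + eps_i`, `eps_i ~ N(0, sigma^2)` left-
truncated so that `delta_i >= 1`. The MLE maximizes
`sum_i [-log sigma + log phi((delta_i - z_i'beta)/sigma)
- log Phi((z_i'beta - 1)/sigma)]` by BFGS with the analytic score, started
from OLS, with sigma parametrized as log sigma; convergence requires
gradient norm < 1e-6 (a Nelder–Mead polish is attempted before declaring
failure). Frontier observations (delta = 1) carry no information about the
inefficiency distribution in this model and are excluded from the initial
fit, as the double-bootstrap algorithm prescribes. Pushing the truncation
point to −infinity recovers OLS exactly; the tests use this closed-form
limit and a dense grid search as oracles.

Algorithm #2 proceeds as documented in `hospeff.bootstrap`: inner loop
(L1 draws) builds pseudo frontiers by rescaling each DMU's inputs to a
simulated distance (`x*_i = x_i * delta*_i / delta_hat_i`) and re-evaluates
the original DMUs against them; `bias_i = mean_b(delta_hat*_{i,b}) -
delta_hat_i` is subtracted from delta_hat (bias-corrected Farrell scores
are then strictly below 1); the refitted model seeds the outer loop
(L2 draws) of parametric simulate-and-refit, from which bootstrap SEs,
percentile CIs, and significance stars (1/5/10% by CI inversion) come.
Replication counts default to L1 = 100 and L2 = 2000; the scaled-down
studies in the tests and the acceptance script use L2 = 500, at which
point doubling L2 moves the focal bootstrap SEs by well under 10%.
A replication whose DEA or MLE step fails is retried with a fresh draw up
to 5 times, then counted and reported.

**Reporting scale.** The estimation runs on the Shephard scale (delta >= 1,
higher = less efficient), the canonical formulation of the algorithm.
Tables are reported by default on the efficiency (Farrell) scale by sign
flip, so positive coefficients read "more efficient"; both scales are
available via `scale=`. The sign flip applies to the intercept too, so the
reported intercept lives on the Shephard-gap scale; only signs and the
focal-coefficient geometry (e.g. the quadratic turning point, which is
invariant under the flip) are comparable across scales.

**Predictive margins.** Margins for Model II are linear-predictor margins:
for each outer-bootstrap coefficient draw, the Shephard linear predictor is
evaluated over a UrS grid with all other covariates at sample means and
mapped to the efficiency scale as its reciprocal (a monotone transform, so
the turning-point location is preserved); the curve and pointwise 95%
bands are the mean and 2.5/97.5 percentiles across draws. Whether margins
should be computed on the bias-corrected-score scale instead is genuinely
open; the linear-predictor convention is used and stated here.

**Model ladder.** Model I: UrS + controls; Model II: + UrS²; Model III:
+ UrD. Controls: ownership dummies (public reference), teaching status,
HHI, location dummies (large-city reference), year dummies with 2017 as the
reference year (configurable). Dummy columns whose level is absent from the
sample are dropped; designs with condition number > 1e10 are rejected with
the column list.

## Synthetic data-generating process

The generator (`hospeff.synthetic`) emulates the structure of a national
acute-care hospital census and runs the two-stage model in reverse so every
estimate has a known target:

* **Catalogue.** Urgency values from a three-component mixture — mass near
  0 (Beta(2,8)), mass near 1 (Beta(8,2)), and a uniform component, weights
  0.45/0.30/0.25 — so both dominance regimes are reachable. The true
  empirical distribution of u over the diagnosis catalogue is not public;
  the mixture is a configurable stand-in. Group lengths of stay are
  log-normal (median 6 days, log-SD 0.45).
* **Case mixes.** Each hospital has a latent urgency target t (Beta, mean
  0.46, SD 0.18) and draws code probabilities from a Dirichlet whose base
  measure tilts toward codes with u near t (Gaussian tilt, bandwidth 0.30)
  with concentration 30; counts are multinomial given the hospital's
  volume (log-normal, median 5,500 cases). The tilt bandwidth and the
  concentration are the two knobs behind UrD. These values were calibrated
  once so the pooled UrS mean/SD (≈0.44/0.14) and the elective-dominated
  share (≈2/3) sit at the descriptive scales typical of such hospital
  populations; UrD comes out somewhat lower (≈0.23) than observed samples,
  a known compromise of the bimodal stand-in mixture.
* **Geography.** Hospitals are placed in clusters (one per ~14 hospitals,
  jitter ≈5 km) with a 20% isolated remainder over a country-sized
  bounding box, so the HHI spans from near 0 to exactly 1.
* **Truth.** The realized UrS, UrS², UrD, HHI and the categorical
  covariates form z; `delta = z'beta + eps` with eps drawn by inverse CDF
  from the left-truncated normal (sigma = 0.15). The default beta encodes
  the efficiency u-shape in UrS (Shephard-scale +2.4 UrS, −2.7 UrS², vertex
  ≈0.44), an urgency-dispersion penalty (+0.8), and control effects an
  order of magnitude smaller.
* **Frontier.** Efficient bundles lie exactly on a monotone convex
  input-requirement frontier: Cobb–Douglas aggregate in inputs (exponents
  0.30/0.20/0.35/0.15) equal to a CES-type aggregate of the two outputs
  (kappa = 1.3, decreasing returns rho = 1.2), with the input mix
  randomized along the isoquant (log-SD 0.10) and levels calibrated to
  realistic bed/FTE magnitudes. Inputs are then scaled radially by delta,
  so the generated bundle's true input-oriented Shephard distance is
  exactly delta. Beds are rounded to integers, a ≤0.5-bed perturbation
  that is negligible at the generated scales.

What the generator does **not** emulate: patient-level admission dynamics,
real diagnosis frequency profiles, reporting errors and missingness,
cost/price data, correlated panel structure of inefficiency within a
hospital over years (delta is redrawn independently per year), or
non-separability between the covariates and the frontier. Passing tests
therefore demonstrate that the estimators recover the truth *under the
model's own assumptions* at desk scale, not that those assumptions hold in
any real hospital census.

## Problem sizes

The standard study population used throughout tests and the acceptance
script is 67 hospitals × 3 years = 201 DMUs with L1 = 100 and L2 = 500;
the parameter-recovery study for the truncated MLE alone uses n = 2000.
These sizes keep a full five-seed double-bootstrap study in the minutes
range on a single core while leaving the estimators' finite-sample
behavior clearly visible (conventional DEA at n = 201 in 4+2 dimensions is
noticeably optimistic, which is exactly what the bias correction is for).

## Known limitations

* Percentile-CI coverage of the generating coefficients at n ≈ 200 in six
  dimensions is around, not at, the nominal level — the DEA convergence
  rate in p+q = 6 dimensions is slow and some first-stage bias leaks into
  the intercept; the tests assert ≥ 0.80 pooled coverage.
* The exact-equality bin ("TE = 1.00") uses a 1e-9 numerical tolerance.
* Exclusion rules (minimum beds, facility types) act on fields the
  synthetic generator mostly leaves benign; they are exercised by
  constructed fixtures rather than by the default population.
* `run_study` is deterministic given its config; byte-identical reruns are
  part of the test suite. Sensitivity variants reuse the base seed for the
  trimming variant so an empty trim reproduces the base run exactly.
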