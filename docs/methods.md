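# Methods

## Information regime and scope

The package implements a population-adjusted indirect treatment comparison
for the two-trial, one-IPD setting: full individual patient data (IPD) for an
index randomized trial, and only published aggregates — a baseline table and
per-timepoint effect summaries with 95% intervals — for a comparator trial.
Index-trial visits are labeled in months; comparator weeks are paired through
a fixed bijective timepoint map (month 9 ↔ week 36, 12 ↔ 48, 24 ↔ 106) and
never interpolated. Multi-trial networks, random-effects meta-analysis,
entropy balancing, outcome-regression (simulated treatment comparison)
adjustment and weight trimming are out of scope.

## Weight estimation

Matching covariates are the seven used in this class of IgAN comparisons:
age, male sex, White race, baseline eGFR, baseline UPCR, and two strict
threshold indicators — UACR > 1.1 g/g and 24-h urinary protein > 1.8 g/day
(a value exactly at a threshold scores 0, following the published ">" row
labels). In unanchored active-vs-active matching the UACR threshold is
1.0 g/g, driven by the `MatchSpec`/target configuration. Proportion targets
may be entered on the 0–100 scale; internally everything is fractional.
Subjects missing any matching covariate are excluded complete-case with a
logged count (the source analyses do not describe their missingness
handling). The covariate set is configurable per endpoint because the
original per-endpoint subsets are not fully public.

With columns centered at the targets, weights are `w_i = exp(c_i' beta)`
where `beta` minimizes the convex tilting objective `sum_i exp(c_i' beta)`.
The solver is damped Newton with backtracking line search from `beta = 0`,
stopping when the gradient norm falls below `1e-10 * n` (cap 200
iterations); near the optimum a non-increasing full Newton step is accepted
even when the objective decrease is below float precision, so the quadratic
phase can finish. At the optimum every weighted moment equals its target
(first-order condition), typically to ~1e-12 relative. Feasibility is
pre-checked: each target must lie strictly inside the observed range of its
column (both levels present for binaries); centered columns with pairwise
correlation above 1 − 1e-10 are dropped with a warning (threshold indicators
can coincide). Reported weights are rescaled to sum to n — presentation
only; ESS `(Σw)²/Σw²` and all downstream models are invariant to rescaling.
Anchored mode pools both randomized arms into one fit; unanchored modes fit
each arm against its counterpart arm's targets.

## Outcome models

Longitudinal endpoints: absolute change from baseline for eGFR, natural-log
post/baseline ratios for UPCR and UACR (subjects with zero baseline are
excluded from ratio endpoints with a log entry). The repeated-measures model
has fixed effects treatment, visit, baseline, baseline×visit and
treatment×visit, and an unstructured within-subject residual covariance
estimated by restricted maximum likelihood: iterated generalized least
squares with an EM covariance update (conditional residual expectations and
variances for unobserved visits plus the REML design adjustment),
convergence at relative log-likelihood change ≤ 1e-8, cap 100 iterations.
If the covariance degenerates (e.g. deterministic outcomes), the fit falls
back to a compound-symmetry projection with a warning. Missing post-baseline
values enter implicitly through the observed-visit likelihood; no
imputation. MAIC weights enter as fixed subject-level frequency weights in
both the REML objective and the GLS normal equations; whether the original
analysts used weighted REML or frequency weights is not public, so the
choice is recorded in the run manifest.

Standard errors for contrasts and LS means use a cluster (subject) sandwich
treating weights as fixed, with the Bell–McCaffrey CR2 leverage adjustment
(each cluster's transformed residual is rescaled by `(I − P_i)^{-1/2}`);
uncertainty in the estimated weights is not propagated (no bootstrap — a
known extension). LS means are evaluated at the MAIC-weighted mean baseline
of the analysis population. With one post-baseline visit and complete data
the model reduces exactly to weighted ANCOVA, which the tests assert to
1e-8. Single-arm fits (needed for unanchored arm-level summaries) drop the
treatment terms.

The composite endpoint is time to the first of: confirmed 40% eGFR
reduction (eGFR ≤ 0.6 × baseline at a visit *and* at the next
eGFR-measured scheduled visit, dated at the first qualifying visit — the
sources say "confirmed" without a rule, so the confirmation convention is
ours), recorded ESKD, or death; otherwise censoring at the last visit. The
hazard ratio comes from a weighted Cox partial likelihood with Efron tie
handling and robust SEs (lifelines); a run with zero events in one arm is
returned flagged degenerate rather than crashing.

## Indirect synthesis

Published intervals are converted to SEs as `(upper − lower)/(2 × 1.959964)`
after log-transforming ratio scales; that z-multiplier is used for every
interval in the package (normal theory, no df refinements — the sources
report plain 95% intervals). Anchored results are produced two ways that
must agree: Bucher's difference with variances summed (confidence
interval), and a conjugate Bayesian fixed-effects model — normal likelihoods
on the two relative effects, independent N(0, prior_sd²) priors on the two
basic parameters, default prior_sd = 100 (credible interval). The closed
form is always the reference; an optional Monte-Carlo sampler must agree
within 3 simulation SEs. With the vague default prior the posterior equals
the Bucher estimate/SE to well under 0.1%. Unanchored results difference
two arm-level summaries with SEs combined in quadrature. Sign convention:
positive mean differences on eGFR change denote benefit of the index active
treatment; log-GMR/log-HR results are exponentiated (optionally to percent
change) for reporting, preserving interval order.

## Synthetic trial generator

The generator emulates the structure the analysis assumes, calibrated to the
published baseline columns of the two trials (shipped as
`nefigard_like.yaml` / `protect_like.yaml`):

- **Baselines.** Seven covariates from a Gaussian copula. Marginals: age and
  eGFR truncated normal (location solved so the truncated mean equals the
  target exactly), sex/race Bernoulli at the published proportions, UPCR
  log-normal with `mu = ln(mean) − sigma²/2`, UACR and 24-h protein
  log-normal pinned by threshold exceedance, `mu = ln(t) − sigma·z(1−p)`.
  When a mean and a threshold are both given, sigma is solved from the pair
  (failing with a diagnostic if no positive root exists) and the threshold
  takes precedence in exact-moment mode. Log-normal sigmas (0.55–0.70) and
  the correlation matrix (proteinuria measures strongly positive, 0.70–0.85;
  eGFR mildly negative with proteinuria, −0.2; age–eGFR −0.35) are
  assumptions — the joint distributions are not published.
- **Exact-moment mode.** For the 364-subject reproduction fixture the finite
  sample is adjusted to hit the printed column exactly: binary counts by
  top-k latent-rank thresholding (every printed index-trial percentage is an
  integer count over 364), continuous means by additive (age, eGFR) or
  multiplicative (UPCR) recentering, threshold covariates by a monotone
  multiplicative rescale putting exactly k subjects above the threshold.
  All adjustments are monotone per covariate, preserving copula dependence.
- **Trajectories.** eGFR visit value = baseline + arm-by-visit mean effect
  (+ optional effect-modification slope in baseline eGFR, off by default) +
  subject intercept (SD 4) + residual from an exchangeable covariance (SDs
  5–7, correlation 0.55) treated as unstructured by the analysis; UPCR/UACR
  visit value = baseline × exp(arm-by-visit log effect + intercept (SD 0.25)
  + noise (SD 0.35)). Zero SDs are allowed for degenerate checks.
- **Events.** Weibull proportional hazards (shape 1.4, scale 180 months)
  with log HRs for treatment (−0.5 index, −0.35 comparator), baseline eGFR
  (−0.03 per unit) and log UPCR (+0.5), administrative censoring at the
  last visit; event components split 70/30 ESKD/death. eGFR-derived
  confirmed-reduction events arise separately from the trajectories.
- **Randomness.** One integer seed per trial, split by `SeedSequence` into
  covariate / trajectory / event streams; no global RNG state.

`make_paired_scenario` generates both trials, computes the comparator's
aggregate moments and its own within-trial effects (fitting the same outcome
models to its IPD with uniform weights), then discards the comparator IPD —
exactly the aggregate-data information regime. What the generator does *not*
emulate: dropout and intercurrent events, titration schedules, non-Gaussian
dependence, measurement rounding. Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to those real-data features.

## Verification choices and problem sizes

- Weight solver vs an iteratively refined grid-search oracle on 100 random
  small instances (n ≤ 20, ≤ 3 covariates), agreement ≤ 1e-4 in beta and
  ≤ 1e-8 relative in matched moments.
- Cox fit vs a brute-force Efron partial-likelihood grid on a 4-subject
  fixture, ≤ 1e-4.
- Bayesian-vs-Bucher agreement ≤ 1e-3 relative over 100 random instances;
  sampler vs closed form within 3 Monte-Carlo SEs.
- Anchored recovery: paired trials with a true cross-trial eGFR difference
  of +3 at one visit, 200 subjects/arm. The single-visit design makes each
  replicate a weighted-ANCOVA collapse, so the calibration check runs at
  1000 replicates (binomial SE of the coverage estimate ≈ 0.7%, comfortably
  inside the 93–97% acceptance band); measured coverage is ~95% with
  z-scores of unit variance.
- MMRM parameter recovery uses 30 replicates at 200/arm against known
  treatment-by-visit effects and a known unstructured covariance; the
  effect-modification stress test uses 40 replicates and asserts direction
  (unadjusted bias ≫ adjusted bias).

## Known limitations

- Weight-estimation uncertainty is not propagated into outcome-model SEs
  (fixed-weight sandwich only); at the simulated sizes the CR2-adjusted
  intervals are nevertheless calibrated to ~95%.
- The real trials' weighted effect estimates and the published effective
  sample size (208 of 364) are not reproducible from synthetic data: ESS
  depends on the full joint covariate distribution, which is proprietary;
  the synthetic fixture yields ESS ≈ 245 under the assumed copula.
- The composite-event confirmation rule and the generator's joint
  distributions are package conventions, stated above, not published facts.
- The Bayesian synthesis is the closed-form conjugate model; no MCMC over
  more elaborate network structures is attempted (two trials, one anchor).
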