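# Methods

## The question the designs encode

A dynamic risk factor is rated over a past window; violence is observed per
window. Two pairings of exposure and outcome are possible on a
baseline/6-month/12-month schedule with two 6-month outcome windows:

| design    | window w1 (0–6 m)       | window w2 (6–12 m)   |
|-----------|-------------------------|----------------------|
| lagged    | baseline ratings → w1   | 6-m ratings → w2     |
| proximity | 6-m ratings ↔ w1        | 12-m ratings ↔ w2    |
| static    | baseline historical → w1| baseline historical → w2 |

Because each assessment rates the *past* six months, this is the only
wave↔window mapping consistent with the schedule. Rows are emitted only when
both the exposure wave and the window-closing wave were observed. Within a
window, temporal ordering of exposure and outcome is unknown, so proximity
associations are *compatible with* causation, never proof; no mediation
estimand is computed.

Ordinal 0/1/2 scores enter models numerically (one OR per 1-point increase),
scale totals per point. Published analyses of such instruments rarely state
the coding; numeric entry is the simplest reading and the item tables expose
the raw scores so any recoding can be applied upstream.

## Clustered discrimination

The AUC is the Mann–Whitney statistic P(score_case > score_control) + ½P(tie)
= (Somers' D + 1)/2, pooled over windows. Subjects contribute up to two rows,
so the SE is a delete-one-subject (grouped) jackknife; the 95% CI is
estimate ± 1.96·SE truncated to [0, 1] (no transformation — the estimates of
interest sit well inside the interval), and the test of AUC = 0.5 uses the
normal approximation. CI comparison between designs uses closed intervals:
touching endpoints count as overlapping (the conservative reading of
"the CIs did not overlap"). Measured type-I error at the default cohort size
(409 subjects, ~14% prevalence) is 5.1% (2000 null replicates); at half that
size the normal approximation is visibly anti-conservative (~6.7%), which is
why the calibration study runs at full size.

## Nested random-intercept logistic regression

The association model is
logit P(y=1) = x'β + u_subject (+ u_trust), u ~ independent Gaussians.
The marginal likelihood integrates the random intercepts by **adaptive
Gauss–Hermite quadrature** (default 7 nodes per level): per subject, nodes
are recentred at the conditional mode (Newton iterations on the concave
integrand) and rescaled by the curvature; per Trust, the mode search uses the
posterior-expectation first and second derivatives of the inner integrals.
With a variance at zero the level collapses *exactly* to the unintegrated
likelihood, so a 3-level fit with var_trust = 0 equals the 2-level fit, and
both-zero equals pooled logistic regression. Optimisation is L-BFGS-B over
(β, σ_subject, σ_trust) with σ ≥ 0, warm-started from a pooled GLM; a fixed
iteration budget inside the quadrature keeps the objective smooth for
finite-difference gradients. Standard errors come from the central-difference
observed information at the optimum, with boundary variances excluded from
the information matrix; inference is Wald throughout (matching the OR /
95% CI / p reporting style), α = 0.05. Adjustment covariates: baseline age
(centred), gender (ref. male), ethnicity collapsed to white/black/asian/
mixed-other (ref. white), diagnosis collapsed to schizophrenia-spectrum vs
other — collapsed because finer categories produce near-empty cells at
n ≈ 400. Non-convergence is flagged, never silent; |β| > 8 or SE > 50
triggers a separation warning.

The likelihood at the optimum is *not* exactly monotone in the node count
(adaptive quadrature error is not one-sided); from 7 to 15 nodes the change
is below 1e-3 on test fixtures and estimates move by < 1e-3, which is the
stability property the tests assert. The 2-level path agrees with
`lme4::glmer` at nAGQ = 15 to four decimals; for the 3-level model glmer
offers only the Laplace approximation, and on our fixtures the adaptive
nested quadrature attains a higher maximised likelihood.

## Explanatory variables and attenuation

A candidate qualifies as explanatory when it is associated at α < 0.05 with
(i) violence and (ii) the other factors. Leg (i) is judged in the
simultaneous-entry multilevel model (all candidates together), i.e. an
*independent* effect — a marginal test would pass every distal item, since
distal factors associate with violence through the proximal ones; a
`mode="marginal"` switch implements the one-at-a-time reading. Leg (ii) is a
pairwise Spearman test against each other candidate on the design rows.
With 7–14 candidates screened at 5%, occasional false inclusions are
expected; the screen's evidence table is always emitted for audit.

Attenuation of a base factor is computed on the log-odds scale,
`100·(β_u − β_a)/β_u`, with β_u from the factor's own covariate-adjusted
proximity model and β_a from the same model plus the explanatory set (singly:
models 1…k; jointly: the fully adjusted model). Only the log scale reproduces
published percent-change values from published OR pairs, which is how the
worked examples in the tests are verified. The formula is sign-preserving
for protective (negative-β) factors and exceeds 100 when the adjusted OR
crosses 1.

## The synthetic cohort generator

The generator emulates the longitudinal structure the analysis assumes, with
defaults calibrated once to the descriptive statistics of the motivating
cohort (409 subjects in 26 Trusts; age 37.8 ± 9.7; 11.1% female; 80.9%
schizophrenia-spectrum; window prevalences 14.0%/12.5%; retention 95% at 6 m
and 89% at 12 m conditional, monotone, missing-at-random).

* **Latent dynamics.** Each dynamic item carries a stationary N(0,1) latent
  value, AR(1) across waves with autocorrelation ρ (default 0.4), split into
  a scale-group common factor (cross-item correlation 0.3, itself AR(1)) and
  an item-specific factor. Thresholds map latents to {0,1,2}. The instruments
  publish no per-item rating prevalences, so the default thresholds are an
  arbitrary calibration: historical items skew high (forensic histories are
  dense), clinical/risk items low-to-middle, protective items mid-scale.
* **Causal wiring.** Distal items act on violence only through proximal
  items: the standardised mean of the distal latents enters each proximal
  latent with coupling δ (default 1.0, then re-standardised). Violence in a
  window depends on the proximal *scores* at the window-closing wave with
  log-odds effects γ (defaults 1.20 violent ideation, 0.85 instability, 1.15
  stress/coping, −1.50 self-control — the ballpark of published conditional
  causal estimates), plus subject (σ = 0.5) and Trust (σ = 0.3) intercepts.
  The protective side mirrors the construction with self-control as the sole
  proximal protective factor. This gives the attenuation stage a known
  ground truth: fully adjusted distal percent changes should approach 100.
* **Intercepts.** baseline_logit = −2.90 and a window-2 shift of −0.22 were
  fixed by bisection at n = 120 000 against the 14.0%/12.5% targets.

What the generator does **not** emulate: rater effects and inter-rater
error, informative dropout, within-window timing of acts, distal→violence
direct paths, cross-instrument correlation between risk and protective
common factors, and any real-data item distributions. Passing tests
therefore demonstrate that the *methods* recover known structure under the
assumed model, not that the substantive findings generalise.

## Study battery (sizes and why)

* Null calibration: 1000 replicates at the full default size (see above);
  both the jackknife-AUC test and the Wald test must reject in 5% ± 2%.
* Coverage: 60 replicates at 250 subjects/12 Trusts, fitting the generating
  model (all proximal items + window term, 3 levels); 240 CIs at nominal
  95% must cover within ±4.5 points.
* Lagged-vs-proximity contrast: 50 replicates at 250 subjects; the lagged
  log-odds for a proximal item should be attenuated toward zero relative to
  proximity in ≥ 90% of replicates (with ρ = 0.4 the attenuation is large,
  ~0.6 vs ~2.1 mean log-odds).
* Distal attenuation: 6 replicates at full size; per-factor mean fully
  adjusted percent change must lie in [80, 120] and ≥ 80% of adjusted CIs
  must cover OR = 1. Replicate counts keep the battery within a few minutes
  on one CPU while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Wald inference only; no likelihood-ratio or profile CIs, no random slopes,
  no GEE alternative, windows no finer than 6 months.
* The jackknife AUC test needs ~50 case subjects for nominal size; smaller
  cohorts over-reject slightly.
* Percent-change attenuation is a descriptive decomposition, not a mediation
  estimand; with unknown within-window ordering no causal direction between
  co-occurring factors is claimed.
* The Hessian is numeric; on near-boundary variance components the reported
  variance-component uncertainty is omitted rather than approximated.
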