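# Methods

This note documents the models the package fits, the generative model the
synthetic-data module samples from, the numerical choices made where the
design was genuinely open, and what the tests do and do not establish.

## Study design encoded in the trial model

A session presents at most 48 trials in 6 blocks; blocks 1–3 run with the
infant's hands uncrossed, blocks 4–6 crossed. Four stimulus conditions —
tactile-only, auditory-only, audiotactile-congruent (both cues on one
hand) and audiotactile-incongruent (cues on opposite hands) — each occur
12 times, 6 per posture. Auditory-only and the two audiotactile conditions
are interleaved in blocks 1, 2, 4 and 5; tactile-only trials fill blocks 3
and 6. The schedule generator reproduces this structure by rejection
sampling over block-wise permutations under the run-length constraint that
no hand receives the same sensory cue on more than 2 consecutive trials
(checked across block boundaries). The published order itself is not
reproduced — only its stated constraints — which affects no statistic
computed here.

The coded outcome of a trial is the first orienting response: its modality
(arm/hand, eye/head, both, or null), side, and latency (RT, seconds,
within an 8 s response window). The binary direction outcome is 1 when the
response went to/toward the stimulated limb; on incongruent trials, where
both limbs are stimulated, it is 1 when the response went toward the
*auditory* stimulus. Latency analyses use responses to the stimulated limb
(either limb on incongruent trials). An RT cutoff, when enabled, is strict:
responses *longer than* 4 s are excluded, 4.00 s is retained.

## Mixed models

**Direction (GLMM).** For participant *i*, trial *j*:

    logit P(y_ij = 1) = x_ij' beta + u_i,   u_i ~ N(0, sigma_u^2)

The marginal likelihood integrates `u_i` per participant with adaptive
Gauss–Hermite quadrature: the integrand's mode is found by a damped Newton
iteration (vectorized over participants, warm-started between likelihood
evaluations), nodes are rescaled by the conditional curvature, and
`n_quad = 1` recovers the Laplace approximation — the conventional default
for binomial mixed models, and the package default. L-BFGS-B maximizes over
`(beta, sigma_u >= 0)` from fixed starts (zeros, 0.5) with a log-likelihood
tolerance of 1e-8; the coefficient covariance is the beta block of the
inverse observed information (finite-difference Hessian), conditioning on
`sigma_u` when it sits on the boundary. Against `lme4::glmer` on common
data the fit agrees to ~4 decimals at both 1 and 9 quadrature nodes.
Complete separation is detected heuristically (extreme coefficients or
fitted probabilities) and reported as a warning on the fit.

**Latency (LMM).** The same design with Gaussian errors. Because the model
has a single variance ratio `lambda = sigma_u^2 / sigma_e^2`, the fit is
exact rather than iterative in high dimensions: at each `lambda` the GLS
coefficients, the residual variance and the (restricted) likelihood have
closed forms via the per-cluster Sherman–Morrison inverse, leaving a 1-d
criterion minimized by bounded scalar search over `log lambda` with an
explicit boundary check at `lambda = 0`. REML is the default (ML
available); results match `statsmodels MixedLM` to ~6 decimals where the
latter converges. One-observation-per-participant data are detected and
refused as non-identified rather than returning arbitrary variance splits.

**Type III Wald tests.** All factors are sum-to-zero coded (Type III tests
are meaningless under treatment coding) and age in months enters centered
at the sample mean, so lower-order terms are evaluated at the factor
average and the mean age. For each term, `chi2 = b' V^{-1} b` over the
term's coefficient block with `df` its size. Wald tests are computed on the
REML fit for LMMs, mirroring the standard `car::Anova` behaviour.

**EMM contrasts.** Estimated marginal means average the linear predictor
over unlisted factor levels with equal weights, at the centered mean age.
Pairwise contrasts of one factor within each cell of the conditioning
factors use normal reference distributions for GLMMs and a t reference
with approximate error df `n_obs - p - n_participants + 1` for LMMs;
p-values are Bonferroni-multiplied by the family size the caller states
(2 for two-way follow-ups; 6/6/12 for the three-way families). Effect
sizes standardize the contrast by the model sigma: the residual SD for
LMMs, `pi/sqrt(3)` (the logistic scale SD) for GLMMs.

## Race-model analysis

Empirical CDFs use the type-1 (inverse step-CDF) quantile estimator: the
quantile at `q` is the smallest observed RT whose empirical CDF reaches
`q`. The race bound `G(t) = min(1, F_A(t) + F_T(t))` is a step function on
the pooled A∪T support and is inverted the same way, so bound and data
quantiles are commensurable; a linearly interpolated estimator exists
behind a flag but is not the default. Capping at 1 cannot affect deciles
≤ 0.9. The gain at decile `q` is the *horizontal* difference
`RT_bound(q) − RT_AT(q)` (positive = bimodal faster than the bound); the
vertical CDF-difference reading is deliberately not used, as only the RT
formulation is operationally complete. Quantities are computed within
participant first and aggregated across participants; participants lacking
any of the three cells (A, T, AT) in a posture are dropped listwise from
that posture and logged. One-sample tests are one-tailed for gain > 0 with
Bonferroni ×9 per group × posture family; group comparisons use Welch t
tests (no variance homogeneity assumed, fractional df) with Bonferroni ×9.

## The synthetic-data generator

The generator samples the world the analysis assumes, with defaults at
the study's stated scale: 10 participants per group, ages uniform in 5–35
months, full 48-trial schedules truncated by attrition (latent
normal(46, 3.5²) clipped to [10, 48], matching reported completion of
~45.5 trials, SD ~3), ~5% null responses, and two raters (rater 2 flips 3%
of sides; RT jitter SD 0.04 s ≈ 1 video frame, quantized to 1/25 s —
coding video runs at 25 fps).

* **Direction** follows the logistic random-intercept model above with
  default fixed effects (0/1 coding): intercept 1.0, group(SVI) −0.2,
  posture(crossed) −0.8, group×posture +0.9, age 0 — a crossed-hands
  deficit in sighted infants that the visually impaired group largely
  escapes — and `sigma_u = 0.5`.
* **Latency** is a two-channel race: each channel draws a shifted
  lognormal `t0 + exp(N(mu, sigma^2))` (defaults: t0 0.3 s, mu 0.30/0.40
  for auditory/tactile, sigma 0.45 — medians ~1.6–1.8 s with right tails
  to 3–4 s, the infant orienting scale). Unisensory trials return their
  channel's draw. Congruent trials return `min(A, T) − violation_v`
  (floored at 0.08 s): with `violation_v = 0` the race-model inequality
  holds by construction (`P(min ≤ t) = F_A + F_T − F_A F_T ≤ F_A + F_T`);
  positive values produce genuine violations. The subtractive form is a
  phenomenological stand-in for coactivation — the analysis only tests the
  summed-CDF bound, so no mechanistic coactivation model is attempted.
* **Incongruent trials** orient to the tactile side with probability
  `tactile_pref` (default 0.5) and take the winning channel's latency; no
  interference term by default. Because this mechanism — not the logistic
  model — sets the incongruent response side, parameter-recovery checks of
  the direction GLMM exclude incongruent trials.

What a green simulation test establishes: the estimator machinery is
calibrated for data that satisfy the model's assumptions. What it does not:
anything about real infants — the generator has no serial dependence,
no fatigue or block-order effects, no heteroscedastic coding noise, and
its distributional families are conventions, not measurements.

## Known limitations and open edges

* The GLMM covariance comes from the full observed information; `lme4`
  conditions on the variance parameter, so standard errors can differ
  slightly in small samples (test tolerances reflect this).
* `sigma_u` is ML-estimated and biased slightly downward at 10–100
  clusters (textbook behaviour); recovery checks therefore target the
  fixed effects.
* The LMM error df for contrasts is the containment-style
  `n − p − k + 1`, not Satterthwaite/Kenward-Roger.
* Kappa CIs use the Fleiss–Cohen asymptotic SE with normal quantiles;
  exact/bootstrap methods can differ in the third decimal at n ≈ 900.
* With ~6 trials per cell, per-participant decile estimates are coarse;
  the race-gain tests at n = 10/group have limited power per posture
  (≈0.3–0.9 at central deciles for a 0.5 s violation under the default
  generator), so a null result there is weak evidence of no integration.
* Trials coded as simultaneous eye/head + hand/arm ("both") carry one
  side and one RT and enter all analyses except the hand/arm-only
  sensitivity mode, which keeps strictly `arm_hand` responses.
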