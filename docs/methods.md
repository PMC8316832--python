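# Methods

## The estimation problem

A trial-level surrogate endpoint is judged by how well the treatment effect
it measures predicts the treatment effect on overall survival (OS) across
randomized comparisons. Each comparison contributes one observation: the OS
hazard ratio (HR_OS) and the surrogate's effect measure, both oriented
experimental / control. The package quantifies surrogacy two ways:

1. the Spearman rank correlation r between the surrogate effect and HR_OS
   (Pearson correlation of mid-ranks; two-sided p from the t approximation
   with n − 2 degrees of freedom, or an exact permutation p for n ≤ 10
   behind a flag), and
2. a weighted least-squares regression of log(HR_OS) on the log surrogate
   effect, weighted by the combined randomized n of the two arms, with the
   weighted coefficient of determination
   R² = 1 − Σwᵢeᵢ² / Σwᵢ(yᵢ − ȳ_w)² and a two-sided t test of the slope
   (equivalent to the overall F test in this single-regressor model).

Both sides of the regression use base-10 logarithms. The slope, R² and all
p-values are invariant to the shared base; only the intercept changes, and
the base is configurable. Weights enter as relative weights, so rescaling
them leaves every reported quantity unchanged.

Candidate surrogates: the 12-month OS milestone-rate ratio, the 12- and
24-month OS restricted-mean (RMST) ratios, the PFS hazard ratio, and the
ORR/DCR relative risks. Missing-data handling is per-surrogate complete
case: a comparison lacking one surrogate's value drops out of that
surrogate's fit only, so the per-surrogate n varies with data availability
and every exclusion is logged. A fit requires at least 3 usable comparisons.

Effect orientation is uniformly experimental / control for every measure.
Under this convention any benefit-oriented ratio (milestone rate, RMST — a
value > 1 favours the experimental arm) must correlate *negatively* with
HR_OS (< 1 favours it), and the simulator-based tests assert exactly that
sign structure. Published analyses of this design sometimes report mixed
signs across surrogates, which can arise only from a per-table orientation
choice that the source text does not always state; with this package the
orientation is a single documented convention.

## Subject-level statistics

* **Kaplan–Meier.** Standard product-limit estimate over distinct event
  times; censored subjects leave the risk set without a step. Greenwood's
  formula gives Var Ŝ(t); once the curve reaches zero the increment is
  undefined and the variance is reported as 0 there. The curve is the usual
  right-continuous step function, S(t) = value just after the last event
  time ≤ t.
* **Milestone rate.** Ŝ(τ) with a 95% interval computed on the
  log(−log S) (complementary log-log) scale, which respects [0, 1]; a
  plain-scale interval is available behind a flag. Evaluating beyond the
  last observed follow-up time is an error unless extrapolation (carry the
  last value forward) is explicitly requested.
* **RMST.** The exact step-function integral of Ŝ from 0 to τ, so
  RMST(τ) ≤ τ with equality iff S ≡ 1, and RMST is non-decreasing in τ. Its
  standard error uses the usual variance of the integrated KM curve,
  Σ_{tᵢ≤τ} Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)) with Aᵢ the remaining area from tᵢ to τ.
* **Hazard ratio.** Cox partial likelihood for a single binary treatment
  covariate with Efron tie handling, maximised by Newton–Raphson with step
  halving to relative tolerance 1e−8 (max 100 iterations; a monotone
  likelihood — all events in one arm — is reported as non-convergence with
  diagnostics). Wald 95% interval on the log scale. The implementation
  agrees with an independent established fitter to ~1e−4 on the log-HR in
  the test suite's randomized comparisons.

## Curve reconstruction

Digitized figure coordinates are noisy: cleaning sorts by time, clamps
survival to [0, 1], collapses duplicate times to the lower survival value
(a drop at that time, matching KM step semantics), enforces monotone
decrease by a running minimum, and anchors the curve at (0, 1). Cleaning is
idempotent. Input whose every coordinate sits at time zero is rejected.

Milestones and RMSTs are then read off the cleaned step curve. Step
integration is the default: a KM curve *is* a step function, so coordinates
digitized at step corners reproduce the subject-level RMST exactly (tested
to machine precision). A trapezoid mode exists as a sensitivity option for
digitizations that sampled slanted segments; because the step rule keeps
each interval's left (higher) value on a non-increasing curve, step ≥
trapezoid always — the difference brackets the digitization-geometry
uncertainty. Curve-derived estimates carry no standard error: coordinates
alone contain no at-risk information. No pseudo-individual-patient-data
reconstruction is attempted.

## The trial simulator

`TrialScenario` defaults describe an ES-SCLC-like first-line population:

| parameter | default | meaning |
|---|---|---|
| `rates` | ln 2 / 10 per month | single-piece control hazard → control median OS 10 months |
| `delay_months` | 6 | treatment-effect onset; curves coincide before it |
| `hr_post_delay` | 0.70 | conditional hazard ratio after onset |
| `cure_fraction` | 0 | optional long-survivor mixture in experimental arms |
| `accrual_months` / `admin_cutoff_months` | 12 / 36 | uniform entry; administrative censoring at cutoff |
| `dropout_rate` | 0.005 / month | exponential loss to follow-up |
| `orr`, `dcr` | 0.60/0.68, 0.85/0.88 | per-arm response probabilities (control/experimental), typical of platinum–etoposide ± checkpoint inhibition |
| `pfs_fraction` | 2.0 | PFS hazard = 2 × OS hazard → median PFS ≈ 5 months |

OS times are drawn by inverse-transform sampling from the
piecewise-exponential law (H(T) ~ Exp(1) inverted through the piecewise
cumulative hazard); the experimental hazard equals the control hazard
before `delay_months` and is multiplied by `hr_post_delay` after — the
simplest mechanism producing early-overlapping, late-separating curves.
The cure fraction is a mixture (event time = ∞, observed as administrative
censoring), not a hazard plateau. PFS reuses the arm's hazard scaled by
`pfs_fraction` and is clipped to be no later than OS; only that ordering,
not a joint dependence model, is claimed. Disease control is sampled as
responders plus a binomial draw among non-responders, guaranteeing
ORR ≤ DCR. One scenario seed drives all arms via `SeedSequence` spawning
(arm order: control, exp1, exp2), so suites are reproducible as a whole.

`simulate_trial_suite` spans a grid of post-delay hazard ratios across
trials (three-arm trials add a sibling arm with the hazard ratio scaled by
1.1 toward the null) and attaches the analytic true RMST/milestone ratios
of the generative law for recovery checks.

What the simulator does **not** emulate: between-trial heterogeneity in
control-arm survival, non-uniform accrual, informative censoring,
response–survival dependence within subjects, and reporting artefacts of
published figures other than additive Gaussian digitization jitter
(sd on the survival scale, default 0.005 in tests). Passing tests therefore
demonstrate internal statistical correctness and recoverability under the
stated generative law, not agreement with any particular published trial.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 50,000 subjects for
closed-form recovery of exponential RMST/milestone values (2% relative
tolerance, fixed seeds); 1,000 per arm for Cox hazard-ratio recovery (10%);
100 digitized coordinates with jitter sd 0.005 for the round-trip check
(2%); and 10-trial suites at 300 subjects per arm for end-to-end surrogacy
recovery (weighted R² ≥ 0.9 with a negative slope for the 24-month RMST
ratio). Exhaustive product-limit validation runs over every tie pattern of
n ≤ 8 uncensored subjects against the empirical survival function. WLS is
solved in closed form from the weighted normal equations and checked
against an independent implementation to 1e−10.

## Known limitations

- Trial-level surrogacy only; no patient-level association is estimated.
- Curve-derived effect measures carry no uncertainty, so the
  meta-regression weights by sample size rather than by inverse variance.
- The Cox model is unstratified with a single binary covariate by design.
- Spearman p-values use the t approximation by default, which is crude at
  very small n; the exact permutation option exists for n ≤ 10.
- With delayed effects the overall HR_OS is not the post-delay hazard
  ratio; the simulator reports the latter as the generative truth and the
  fitted Cox HR as the trial's observed effect, as in real trials.
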