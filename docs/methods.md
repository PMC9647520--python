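# Methods

`esmlag` estimates the calendar-day lag structure between once-daily
self-reported variables — sleep quality, sleep duration and symptom
composites in people living with psychosis — and tests lag-space mediation
hypotheses. This note documents the statistical model, the estimation
machinery, the synthetic-data generator, and the design choices made where
the procedure left genuine freedom.

## The two-stage lag model

All analyses operate on person-centred z-scores: for each subject and
variable, `z = (value − subject mean) / subject sd` over that subject's
observed days (n−1 denominator). The unit of time is one calendar day; a
predictor at lag `l` is its value exactly `l` days before the outcome day,
and a day skipped in the diary yields a genuinely missing lagged value,
never an index shift.

**Exploratory stage (screen).** On the long-stacked design with rows
`(subject, day t, lag l, y_t, x_{t−l})` for `l = 1..L` (default `L = 20`),
we fit the varying-coefficient model

    y_t = f(l) · x_{t−l} + subject intercept + error,

where `f` is a penalized cubic B-spline in the lag index with basis
dimension `k` (default 19, i.e. lag window − 1) and a second-order
difference penalty. The subject intercepts enter as a ridge-penalized dummy
block — the penalized-regression form of a mixed-model random intercept.
Pointwise Wald statistics at the integer lags use cluster-robust standard
errors clustered on (subject, day), because each outcome day is reused
across the `L` stacked rows. Lags with pointwise `p < α` (default 0.05)
become the candidate set; the empty set is a meaningful outcome ("n.s.").

*Smoothing-parameter selection.* The smoothing parameter λ and the
subject-ridge τ are selected on a log-spaced grid by a BIC-type criterion,
`n·log(RSS/n) + log(G)·edf`, with `G` the number of distinct outcome days
(clusters). Ordinary GCV — even with the customary γ = 1.4 inflation of the
effective degrees of freedom — undersmooths this design under the null:
with a near-saturated basis it happily spends degrees of freedom on noise
wiggles, and the ~20 pointwise tests then flag some lag in 20–35% of
null panels. Charging degrees of freedom at `log(G)` makes the null fit
collapse to a flat curve, so the pointwise tests become one effective test
and the family-wise false-flag rate drops to a few percent, while bumps of
realistic magnitude (per-lag |β| ≥ ~0.05 at study scale) still open the fit
up. GCV (with γ configurable) remains available via `selector="gcv"`.

**Confirmatory stage.** Candidate cross-lags (and auto-lags of the outcome,
screened the same way on the outcome's own design) enter a discrete-lag
linear dynamic model

    y_t = Σ_{l∈cross} β_l x_{t−l} + Σ_{m∈auto} φ_m y_{t−m}
          + subject intercept + ε_t,

estimated by Gaussian maximum likelihood in a state-space formulation. The
state stacks each modelled variable's current and lagged values; observed
diary entries are exact observations of the corresponding state slots, and
the predictor carries its own nuisance AR(`x_order`, default 1) equation, so
the Kalman filter marginalizes over unobserved days instead of discarding
incomplete rows. This matters: at 31% missing days, a listwise design for a
five-lag model would keep only ~0.69⁶ ≈ 11% of outcome days, whereas the
marginalized likelihood uses every observed day.

*Estimation.* EM with closed-form M-steps: the E-step is a Kalman filter
plus disturbance (backward r/N) smoother batched over subjects, the M-step a
set of regressions on smoothed moments with subject intercepts absorbed by
within-subject centering. EM is warm-started from complete-row OLS (or from
the screen's coefficient curve inside the two-stage loop) and is fully
deterministic. The likelihood conditions on each subject's first `L` days:
the initial state is assembled from the observed history, with unit variance
(the stationary variance of standardized data) on unobserved entries. With
complete data this makes the ML coefficients and the reported log-likelihood
*exactly* equal to OLS-with-subject-dummies and the closed-form Gaussian
regression log-likelihood — the package's primary correctness oracle.

*Reported fit.* The log-likelihood and BIC refer to the outcome variable's
innovation terms only (parents are updated before the outcome at each filter
step, so the outcome term is a genuine prediction-error decomposition);
`BIC = −2·loglik + n_params·log(n_obs)` with `n_params` = retained
coefficients + subject intercepts + innovation variance and `n_obs` the
observed outcome days in the conditioning window.

*Inference.* Wald standard errors come from the observed-data information,
obtained by one-sided finite differences of the Fisher-identity score (one
smoother pass per coefficient). During backward elimination a cheap bound is
used first: the complete-data information never understates precision
(Louis decomposition), so a term non-significant under it can be dropped
without computing the exact information.

*Retention rule.* Backward elimination drops the least significant
coefficient with `p ≥ α` and refits until all retained coefficients have
`p < α`. A BIC refinement then follows: the weakest remaining coefficient is
removed whenever removal lowers the outcome BIC (models compared on a common
conditioning window). Both stages read the same data, so a noise lag that
survives the screen tends to survive an α-level re-test as well; requiring
each retained lag to also pay its `log(n)` complexity price (≈ |z| > 2.95 at
study scale) is what keeps the family-wise error of the whole pipeline low
(measured ≤ a few percent over null panels) while leaving genuine effects
(|z| ≳ 6 even for per-lag β ≈ 0.08) untouched.

**Iteration.** The two stages alternate: after a confirmatory fit, the
screen is re-run on the model residuals to catch lags masked in the first
pass; newly flagged lags join the candidate set and the cycle repeats until
the retained set repeats (typically 1–2 cycles; cap 10). Oscillation between
two solutions resolves to their intersection — the conservative reading —
and is flagged in the trace. Auto-regression analysis is the special case
predictor = outcome. The summed effect of a path is the exact sum of its
retained β coefficients (zero, flagged n.s., for the empty set).

## Mediation in lag space

For a triple (predictor X, mediator M, outcome Y), the Baron–Kenny logic
with the joint significance test:

1. *Path a* — two-stage model X→M; no significant lags short-circuits to
   "no mediation".
2. *Total effect* — two-stage model X→Y.
3. *Path b lags* — M's predictive lags on Y re-screened with a two-stage
   M→Y model: the mediator enters the joint model at its own lags relative
   to Y, the only alignment that keeps each path's lag semantics coherent.
4. *Joint model* — X (at its total-effect lags) and M (at its path-b lags)
   predict Y simultaneously, with Y's auto-lags and with M given a
   structural nuisance equation (path-a lags of X plus AR(1)) so its missing
   days are marginalized coherently. Elimination and BIC refinement prune
   both paths. Direct effect = summed retained X coefficients; indirect =
   total − direct (the difference method — with distinct lag sets per path a
   product over lag pairs is ill-defined), so total = direct + indirect holds
   exactly by construction.
5. *Verdict* — "full" if the direct path is eliminated entirely, "partial"
   if it survives with |direct| < |total|, otherwise "no mediation"; claimed
   only when paths a and b are both non-empty (joint significance).
6. *Comparison* — the mediated and unmediated outcome models are refitted on
   the same conditioning window so their BICs are comparable; the
   oppositional model (X and M exchanged) is preferred only if it shows an
   indirect pathway where the forward model does not, with lower BIC as the
   tie-break and ties (|ΔBIC| < 1e−6) declared inconclusive.

## Synthetic diary generator

The generator emulates the sampling design under study: 33 subjects, 323
days, once-daily diaries with a 69% response rate, sleep quality on 1–5,
sleep duration in hours on a 15-minute grid, fourteen 1–7 Likert items
feeding six composites, short-memory within-person autocorrelation,
cross-lagged coupling over 1–12 day windows with summed standardized
coefficients of roughly ±0.1–0.5, and subject heterogeneity as random
intercepts.

Latent dynamics are a linear Gaussian lagged recursion over six
composite-level variables whose kernels β(l) are the target of recovery.
Innovation variances are calibrated through the companion-form discrete
Lyapunov equation so that every variable has unit stationary variance;
the configured kernels are therefore exact per-SD (standardized)
coefficients and "recover β" is well-posed. Construction fails for
non-stationary kernel sets (companion spectral radius ≥ 1) and for kernel
sets whose dynamics alone push a variance to 1. A burn-in of 3·L_max days
removes initialization transients.

Diary scales: Likert items are the composite latent plus item-specific
Gaussian noise (sd 0.5, a typical item-specificity share), person-
standardized and cut at fixed equal-probability normal quantiles; sleep
duration is `8.0 + 1.25·latent` hours (plausible for antipsychotic-treated
outpatients), clamped to [0, 16] and rounded to 0.25 h. Missingness is MCAR
by default (the study reports only a marginal response rate), with a
symptom-dependent mode — drop probability `logistic(a + b·psychosis z)`,
`a` calibrated so the marginal rate matches — for sensitivity work.

What the generator does *not* emulate: time-of-day effects within the
notification window, duplicate submissions, slow trends or regime changes
(the estimated lag functions are assumed stable over study time, an
assumption the method itself makes), item-level response styles, and
wearable sensor channels. Passing recovery tests therefore demonstrate
correctness of the estimator under the model family it assumes, not
robustness to every feature of real diaries.

Monte-Carlo evaluations of estimator behaviour (recovery bias, error rates)
run on the latent continuous series with missingness applied, because
7-level equal-probability discretization attenuates standardized
coefficients by ~5–10% on both sides of a regression; the Likert path is
exercised end-to-end in the pipeline runs and analysis scripts, where mild
attenuation of weak per-lag effects (e.g. per-lag β = 0.025) is visible as
reduced detection, exactly as it would be in a real diary study.

## Numerical choices

- Kalman/smoother passes exploit the stacked-lag structure: the transition
  matrix is stored row-sparse (shift rows plus one sparse equation row per
  variable), observations are exact scalar reads handled sequentially, and
  the smoothed covariance is computed on the "active" slots whose underlying
  days are unobserved. The kernel is JIT-compiled (numba).
- EM tolerance 1e−8 relative (1e−6 with a 6-iteration cap during
  elimination rounds, followed by a tight warm refit); innovation variances
  floored at 1e−10; information matrices symmetrized and eigenvalue-floored
  before inversion.
- Finite-difference step for the score: `1e−4·(1 + |coef|)`, one-sided
  against the converged-moments baseline.
- λ grid `10^−4..10^8` (25 points), τ grid `10^−1..10^4` (6 points).
- Degenerate inputs: constant subject-variables are dropped from
  standardization with a warning; subjects shorter than the conditioning
  window are excluded from likelihoods; empty candidate sets raise, empty
  *retained* sets are valid results reported as "n.s.".

## Known limitations

- **Person-centring bias.** Standardizing with each subject's full-series
  mean induces a Nickell-type bias of order (summed β)/T in the *reverse*
  association when one variable drives another: with summed forward effect
  −1.5 and T ≈ 300 the spurious flat-in-lag reverse coefficient is ≈ +0.008
  per lag, which pooled over the lag window becomes detectable. At the
  summed effects typical of daily-diary psychopathology data (|Σβ| ≤ 0.5)
  the artifact is an order of magnitude below detection thresholds, but
  directionality conclusions for very strong couplings on short panels
  should be treated with care. This is a property of person-centred
  z-scoring itself, not of the estimator.
- Wald inference holds nuisance parameters (variances, subject intercepts,
  predictor dynamics) fixed at their MLE; measured null calibration of the
  resulting z-statistics is compatible with N(0, 1) at study scale.
- The nuisance AR(`x_order`) for the predictor is a working model for
  marginalizing its missing days; gross misspecification of the predictor's
  own dynamics at high missingness degrades (but in our checks did not
  visibly bias) the cross-coefficient estimates.
- BIC comparisons across mediated/unmediated models condition on the same
  outcome observations but, as always with incidental subject intercepts,
  the parameter count is a convention; only BIC *differences* within a
  comparison are meaningful.

## Problem sizes used in the test and acceptance runs

Monte-Carlo properties are evaluated at the study scale of 30 subjects ×
300 days with 31% missing diaries: parameter recovery over 30 replicate
panels (20 in `scripts/acceptance.py`), type-I control over 30 (20) null
panels, directionality over 15 panel pairs, mediation over 10 triples.
Replicate counts are the package's choice of Monte-Carlo precision; the
thresholds they are checked against (≥85% coverage, ≤10% false-positive
rate, ≥80% full-mediation verdicts, bias bands) do not depend on the counts.
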