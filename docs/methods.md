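# Methods

## Scope and model assumptions

The package implements a sequential phase I–II dose-finding design for
binary efficacy and toxicity endpoints measured over a common window.
Patients accrue in cohorts of size c (default 3) up to a maximum sample size
N (default 45, i.e. 15 decision points); the trial starts at the lowest dose
(configurable). Efficacy and toxicity are modeled independently — there is
no copula or association term — with a quadratic logistic curve for efficacy
and a linear logistic curve for toxicity on the centered-log-dose scale.
Outcomes are assumed observable before the next cohort is assigned (no
late-onset modeling, no accrual/dropout model, no adaptive randomization).

## Utility

Marginal utilities are two-branch power functions around a reference point,
normalized to [0, 1], combined multiplicatively under mutual utility
independence. Parameters, units and defaults of the primary preset
(`R2DT1`):

| parameter | meaning | default |
|---|---|---|
| π̄_E | efficacy reference (standard-of-care response probability) | 0.50 |
| π̄_T | toxicity reference (target toxicity probability) | 0.35 |
| λ_E, λ_T | loss aversion (≥ 0; > 1 weights losses more than gains) | 2.0 |
| α_GE, α_LE, α_GT, α_LT | risk exponents per branch (> 0) | 0.7 |
| k_E | joint utility at (π_E, π_T) = (1, 1) | 0.25 |
| k_T | joint utility at (π_E, π_T) = (0, 0) | 0.15 |

Numerical choices:

* The gain branch is closed at the reference (π_E ≥ π̄_E and π_T ≤ π̄_T are
  gains). Both branches agree at the reference, so the convention is
  value-irrelevant but applied consistently.
* Exponents are restricted to (0, ∞). The exponent → 0 limit is a step
  function and involves 0⁰; it is rejected with a configuration error rather
  than approximated.
* λ = 0 is accepted (the loss branch collapses to the reference value) but
  triggers a warning, since loss aversion above 1 is the intended regime.
* Utilities are computed in double precision; comparisons against tabulated
  values use round-half-even at 2 decimal places.
* One narrative caveat: the loss-branch exponent below 1 makes the loss
  segment convex ("risk prone" in the usual curvature vocabulary) while the
  surrounding discussion of framing describes the same behavior as
  effectively risk averse once outcomes are reframed relative to the
  reference. The implementation follows the formulas; the vocabulary tension
  is left to the user's interpretation.

## Posterior computation

The reference sampler is a hand-rolled adaptive random-walk Metropolis,
vectorized across 8 parallel chains. Warmup (default 500 iterations) adapts
a global proposal scale toward ~30% acceptance on a prior-sd-shaped diagonal
proposal for the first half, then re-estimates the proposal covariance from
warmup states and adapts the scale again. Sampling retains `n_draws`
(default 2000) thinned draws pooled across chains. All randomness flows
through a `numpy.random.Generator`; identical seeds give bit-identical
draws, and replicate studies spawn independent `SeedSequence` substreams so
split runs pool exactly. The mean acceptance rate is recorded in the draw
provenance; runs outside [0.1, 0.7] are flagged as non-converged, retried
once inside a simulated trial with a fresh substream, and the trial is
marked failed (excluded from aggregation but counted) if the retry also
fails. A deterministic Laplace approximation (BFGS mode finding plus
Gaussian draws from the inverse numerical Hessian) is available as
`method="laplace"` for large exploratory sweeps; the Metropolis sampler is
the reference implementation and all correctness checks run against it or
against a dense-grid quadrature oracle.

The likelihood is evaluated from per-dose sufficient statistics
(numbers of efficacy/toxicity events per dose), which makes the sampler
cheap enough (~tens of milliseconds per interim fit at reduced settings)
to drive full replicate studies.

## Priors

Priors are direct normal (mean, sd) inputs per coefficient. The published
calibrated hyperparameters for the worked example are not part of this
package's inputs, so the defaults are the package's own construction:
prior means are a least-squares fit of the two logistic curves to the
average dose-response of the first six built-in scenarios (the same
averaging used to center the original prior), giving
(μ_E, β_E1, β_E2, μ_T, β_T) ≈ (0.424, 1.409, −0.233, −1.244, 1.258), with a
common sd of 2.0 on the logit scale as a weakly informative choice. These
defaults were fixed once, before any operating-characteristics run, and are
not tuned. Operating characteristics are sensitive to prior informativeness;
with these defaults the dominant-dose selection percentages are lower than
the published figures obtained under effective-sample-size-calibrated
priors, while the qualitative ordering (which dose wins, when trials stop)
is preserved. Users reproducing a specific study should supply its priors
through the `prior` block of the configuration.

## Decision rules

* Conventional admissibility: a dose is admissible iff
  Pr(π_E > 0.5 | y) > 0.075 and Pr(π_T < 0.4 | y) > 0.075 (defaults). The
  direction convention — small probabilities acting as evidence floors — is
  the standard one for this rule family; the printed constants (0.075) only
  make sense as floors, and this is the adopted reading.
* Utility-contour rule: a dose is unacceptable iff Pr(u < u_ref | y) > 1 − p_u
  with p_u = 0.1 by default and u_ref the joint utility at the elicited
  contour point. Strictness at the threshold (> vs ≥) is value-irrelevant
  for continuous posteriors; strict inequality is used.
* The argmax is restricted to admissible doses (variants
  `conventional_admissibility`, `utility_admissibility`) or taken over all
  doses with a trial-level stop when every dose violates the contour rule
  (`utility_trial_stop`). The two contour variants stop under exactly the
  same condition on the same posterior.
* No-skip: an interim recommendation more than one level above the highest
  dose tried so far is capped at that level plus one. The cap does not apply
  to the final recommendation, which treats no further patients.
* Ties in expected utility break to the lowest dose index (safety first).
* Rules are evaluated after each cohort's outcomes, before the next
  assignment; the final selection applies the same rule set.

## Elicitation solvers

Risk exponents solve the weighted power-mean equation implied by a one-sided
lottery; the power mean is strictly increasing in the exponent, so the root
is unique and found by bracketed root search on log-exponent in
[log 10⁻³, log 10³] (tolerance 1e-10, evaluated in log space to avoid
underflow at extreme exponents). Answers at the risk-neutral mean return
exponent 1 exactly; answers outside the lottery support, or below the
weighted geometric mean (unrepresentable by a positive power), raise an
inconsistency error. Loss aversion enters the unnormalized utility linearly
and is recovered in closed form from a reference-straddling lottery; implied
negative values raise an error. Corner weights come either from directly
stated corner utilities or from two bivariate equivalences via a 2×2 linear
system (condition number above 1e10 raises a singular-system error naming
the equivalences). Because clinicians realistically answer at 2-decimal
granularity, `risk_exponent_band` reports the exponent interval implied by
±half a rounding unit on the stated answer.

## Simulation and what it does (and does not) show

Replicate trials draw independent Bernoulli efficacy and toxicity outcomes
from fixed per-dose scenario probabilities — matching the independence
assumption of the probability model. The ten built-in scenarios span steep
and flat efficacy, escalating toxicity, plateaus, an all-toxic case and an
all-inefficacious case; each records its target answer (the best dose after
excluding true toxicity > 0.4 or true efficacy < 0.5, or no-dose-selected).
Operating characteristics report per-dose selection percentage, mean
patients treated (averaged over all replicates, including early-stopped
trials) and the percentage of trials with no dose selected.

Because the generator matches the model's independence and Bernoulli
assumptions exactly, passing simulations demonstrate the decision machinery
and its calibration under the stated model — not robustness to outcome
correlation, late-onset toxicity, non-Bernoulli heterogeneity or model
misspecification, none of which the generator emulates.

Default problem sizes in the shipped tests are scaled to desk hardware:
replicate studies use 60–200 replicates with 1000 retained draws per interim
(400 warmup, thinning 2), and sampler-correctness checks use 4000–6000
draws. These sizes are the package's own verification choices; full-scale
studies (thousands of replicates, 2000+ draws) use the same code paths via
`run_study`.

## Known limitations

* No trade-off-contour (vector-norm desirability) comparator design; the
  linear-marginal utility comparator presets cover the sensitivity analyses.
* Priors must be given as normal (mean, sd) pairs; effective-sample-size
  calibration is out of scope.
* The Laplace fallback is a mode-centered Gaussian and can misstate tail
  probabilities for very small samples or skewed posteriors; it is not used
  by any correctness check.
* Binary endpoints only; continuous, ordinal and time-to-event extensions
  would require new marginal utilities and likelihoods.
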