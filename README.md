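# r2dt — reference-dependent decision-theoretic dose finding

`r2dt` implements a Bayesian decision-theoretic phase I–II dose-finding
design for early-phase oncology trials with binary efficacy and toxicity
endpoints. It is aimed at trial statisticians who want to design, elicit and
simulate a dose-finding study in which the dose decision at every stage
maximizes a posterior expected utility grounded in von Neumann–Morgenstern
(VNM) utility theory, rather than a point-estimate desirability score.

## The model and the utility

Doses d₁ < … < d_k are transformed by centering the log dose,
f(d) = log d − (1/k)Σ log d_r. Efficacy and toxicity are modeled
independently by logistic regressions

    π_E(d) = logit⁻¹(μ_E + β_E1 f(d) + β_E2 f(d)²)
    π_T(d) = logit⁻¹(μ_T + β_T f(d))

with independent normal priors on θ = (μ_E, β_E1, β_E2, μ_T, β_T); the
quadratic term allows non-monotone efficacy. After each cohort of c patients
the posterior p(θ | y) is updated and the next cohort is treated at the dose
maximizing E[u(π_E, π_T) | y, d], subject to a no-skip rule in escalation.

The utility is reference dependent. Each attribute has a two-branch power
utility around a clinical reference point (π̄_E the standard-of-care response
rate, π̄_T a target toxicity level); outcomes better than the reference are
gains, worse are losses, with risk exponents α_G, α_L and a loss-aversion
multiplier λ on losses:

    u_E(π_E) = g[(π_E − π̄_E)^α_GE]            for π_E ≥ π̄_E
               g[−λ_E (π̄_E − π_E)^α_LE]       for π_E < π̄_E

(toxicity mirrored), normalized to [0, 1] by the affine map g. Mutual
utility independence combines them multiplicatively:

    u(π_E, π_T) = k_E u_E + k_T u_T + k_ET u_E u_T,    k_ET = 1 − k_E − k_T.

The linear-marginal special case (λ = 1, all exponents 1) is the familiar
patient-outcome (EffToxU-style) utility with corner weights k₁₁ = k_E,
k₀₀ = k_T; the package ships it as a comparator preset.

Doses can be excluded by conventional admissibility rules
(Pr(π_E > π̄_addE | y) and Pr(π_T < π̄_addT | y) evidence floors) or by a
single utility-contour rule: a dose is unacceptable when
Pr(u(π_E, π_T) < u_ref | y) > 1 − p_u, where u_ref is the utility of an
elicited contour point. The contour rule can act per dose (admissibility)
or as a trial-level stop; both call a stop under the same condition.

Elicitation solvers recover all utility parameters from stated certainty
equivalents of simple lotteries: risk exponents from one-sided lotteries
(unique root of a weighted power-mean equation), loss aversion from a
reference-straddling lottery (closed form), and the corner weights from two
bivariate equivalences (2×2 linear system).

## Worked example

Evaluate the primary utility stack (references 0.5/0.35, λ = 2, exponents
0.7, corner weights 0.25/0.15) at a 50% response rate and 35% toxicity rate:

```bash
$ r2dt evaluate-utility --pe 0.5 --pt 0.35
0.5820
$ r2dt evaluate-utility --pe 0.5 --pt 0.35 --preset EffToxU2
0.4175
```

The reference-dependent stack scores this borderline outcome 0.58: the
efficacy marginal sits at its reference value (u_E = 2/3 with λ = 2) and the
toxicity marginal at 0.755, combined with strong positive interaction
(k_ET = 0.6). The linear comparator scores the same outcome 0.42.

Simulate a small replicate study under the built-in scenario with a clearly
dominant highest dose (true probabilities (0.85, 0.15) at 50 mg/kg):

```bash
$ r2dt simulate --scenario 1 --design R2DT1 --reps 50 --seed 11 --out scratch/s1
design R2DT1, scenario 1, 50 reps
  dose 20 mg/kg: selected 0.0%, mean patients 3.2
  dose 30 mg/kg: selected 8.0%, mean patients 8.6
  dose 40 mg/kg: selected 26.0%, mean patients 10.6
  dose 50 mg/kg: selected 66.0%, mean patients 22.6
  no dose selected: 0.0%
wrote scratch/s1/oc.csv
```

The 50 mg/kg dose is selected most often and treats the most patients, as it
should in this scenario; the exact percentages depend on the prior (see
`docs/methods.md` on the package's default priors). `oc.csv` holds the
operating characteristics, `trials.csv` the per-replicate records (which
`r2dt oc-table` re-aggregates), `trace_rep1.csv` a per-cohort decision trace
and `manifest.json` the seed and configuration hash of the run.

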