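# Methods

## Model

The moderated ACE model treats each twin's standardized polygenic score
(PGS) as a *definition variable*: an observed quantity entering that pair's
expected moments rather than a random variable of the model. Writing
A = A_P + A_L for the additive genetic factor split into the part captured
by the PGS (path `aP`) and a latent residual (path `aL`), the phenotype is

    y_i = b0 + aP·PGS_i + aL·A_L,i + (c0 + bc·PGS_i)·C + (e0 + be·PGS_i)·E_i

with C shared within a pair and E independent per twin, all latent factors
standard normal. Conditional on the two scores a pair is bivariate normal:

    mu_i  = b0 + aP·PGS_i
    v_i   = aL² + (c0 + bc·PGS_i)² + (e0 + be·PGS_i)²
    cov12 = ρ_AL·aL² + (c0 + bc·PGS1)(c0 + bc·PGS2)

with ρ_AL = 1 for MZ and 0.5 for DZ pairs. Conditioning moves the
`aP·PGS` main effect into the mean; marginalizing back over a unit-variance
PGS (with PGS1 = PGS2, always true for MZ) recovers the familiar
`aL² + aP² + (c0 + bc·PGS)² + (e0 + be·PGS)²` decomposition. For DZ pairs
with unequal scores the cross-twin moderated-C term is the product of the
two moderated paths, which the equal-scores form is a special case of.
This conditional formulation is exact for the definition-variable design;
the PGS correlation within DZ pairs (0.5 in expectation) is a property of
the data, not a model parameter.

Identification: the likelihood is invariant to the reflections
(c0, bc) → (−c0, −bc), (e0, be) → (−e0, −be) and aL → −aL, so `aL, c0 ≥ 0`
and `e0 > 0` are imposed; `bc`, `be`, `aP` are unconstrained in the default
fit. Dominance, sex-limitation, covariates and multivariate phenotypes are
out of scope.

## Censored likelihood

Floor effects are modeled by left-censoring at a user-declared floor (the
reader flags values equal to the floor; `infer_floor` proposes the dataset
minimum when ≥1% of values tie there). Pair contributions:

- both observed — bivariate normal density at the implied moments;
- one censored — marginal density of the observed twin × the conditional
  normal CDF of the censored twin below the floor;
- both censored — bivariate normal CDF at (floor, floor).

The bivariate CDF uses Owen's T-function identity (vectorized over pairs;
the generic multivariate-normal CDF is far too slow inside an optimizer
loop and serves only as the test oracle). Exact zeros of the standardized
bounds are nudged by 1e-12 to sidestep the removable singularity of the
T-function ratios; the induced error is ~1e-12, far below the 1e-6 level
verified against quadrature.

## Estimation

`-2 log L` is minimized by L-BFGS-B with finite-difference gradients over
the free parameters of a `ModelSpec` (fixed parameters are held at their
values; fixing `bc = be = 0` gives the no-interaction model, additionally
`aP = 0` the plain ACE model). Starting values come from the classic
Falconer-style decomposition of the MZ/DZ phenotypic covariances
(a² = 2(covMZ − covDZ), c² = 2covDZ − covMZ, clipped to an admissible
range), the pooled phenotype–PGS covariance for `aP`, and 0 for the
interaction terms. Non-convergence triggers up to 5 retries with
N(0, 0.1²) jitter on the starts, then a `converged = False` result (never
an exception in batch runs). After the line search succeeds the optimizer
is restarted once from its own solution — resetting the Hessian
approximation recovers from stalls near ridges (e.g. c0 ≈ 0). Within the
Monte-Carlo engine, any restricted fit that beats its full fit (a logical
impossibility at the exact optima) triggers a refit of the full model from
the restricted solution. Inadmissible parameter points (non-positive-
definite implied covariance) surface as a penalty value to the optimizer.
Convergence tolerance is ~1e-8 on −2LL (`ftol` 1e-11 relative).

Likelihood-ratio tests compare nested fits: χ² is the difference in −2LL
(floored at 0, with a warning if meaningfully negative), df the difference
in free-parameter counts, and `lrt` reports the plain two-sided upper-tail
χ² probability — the convention used for reported model-comparison tables.
Boundary estimates (c0 → 0) are legal; no boundary correction is applied
to these reported p-values. The attenuation correction divides an
interaction estimate by √RA² and is valid only for a same-trait PGS; a
cross-trait PGS understates RA² and inflates the corrected value.

## Synthetic data generator

`simulate_pairs` implements the generating process the simulation study
assumes: random mating, equal environments, no gene–environment
correlation, and moderation by the **total** standardized genetic factor
A = A_P + A_L:

    y_i = √a²·A_i + (√c0² + βc·A_i)·C + (√e0² + βe·A_i)·E_i

The PGS component A_P (variance RA², correlation 1 in MZ / 0.5 in DZ) is
emitted, standardized by its generating SD, as the observed score; A_L
(variance 1 − RA²) stays latent. Because the fitted moderator is the PGS
while the true moderator is A, fitted coefficients are attenuated:
E[b̂] ≈ β·√RA², which the paired power/estimate results reproduce. Effect
sizes are parameterized as δ = b² + 2·b·base — the phenotypic variance
contributed by the interaction per SD of the moderator — inverted in
closed form (positive root) by `effect_size_to_coef`: δc = 0.10 at
c0² = 0.10 gives βc = 0.131; at e0² = 0.50, βe = 0.067.

Default scenario: a² = 0.55, c0² = 0.10, e0² = 0.35, RA² = 0.10,
δc = δe = 0.10, 2000 MZ + 2000 DZ pairs — the reference condition of the
simulation grid, with variance settings spanning a² ∈ {.35,.55},
c0² ∈ {.10,.35}, e0² ∈ {.35,.50}, RA² ∈ {.10,.20} available through the
`Scenario` fields. Floor effects are emulated by collapsing the lowest
`floor_prop` (default experiments use 15%) of the *pooled* phenotype values
(both twins, both zygosity groups — one common floor) onto the empirical
quantile at that proportion, flagging them censored. Replication r of a
scenario runs at seed + r, so grids and parallel runs are reproducible and
independent of worker count.

What the generator does **not** emulate: SNP-level genotypes (the PGS is a
Gaussian factor component, not a sum of alleles), assortative mating,
gene–environment correlation, measurement non-normality other than the
floor transform, or missingness (complete pairs only). Passing tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to real-data violations beyond left-censoring.

## The power engine and the directional test

`run_scenario` simulates each replicate, fits the full model plus the three
restrictions (no-bc, no-be, no-interaction) with warm starts from the full
fit, and records rejections. By default the engine tests **directional**
moderation: the simulated alternatives are variance amplifications
(δ ≥ 0 ⇒ b ≥ 0), so the interaction coefficients are constrained to be
non-negative and the LRT statistic is referred to its chi-bar-square null
distribution — the mixture ½χ²₀ + ½χ²₁ for one coefficient (critical value
2.706 at α = 0.05) and ¼χ²₀ + ½χ²₁ + ¼χ²₂ for the omnibus (4.231). This is
an exact α-level test: the measured null rejection rate sits in the
0.03–0.07 band at α = 0.05, and it is the rejection rule under which the
engine's power values for the reference grid (bc ≈ .45, be ≈ .90,
om ≈ .98 at RA² = .1; bc ≈ .73 at RA² = .2) are calibrated. Passing
`one_sided=False` switches to unconstrained fits with plain two-sided
critical values (power ≈ .34/.82/.94 in the reference scenario — the
noncentrality there, ~2.4 for the bc test at 4000 pairs, is what the
two-sided sample-size extrapolation consumes). Non-converged replicates
are excluded from rate denominators; a convergence rate below 90% flags
the result. Each rate carries its binomial Monte-Carlo SE.

`false_positive_rate` runs the same engine under δc = δe = 0. With
`floor_prop = 0.15` and the default *uncensored* fit it reproduces the
distortion experiment: the conditional-normality violation drives the
omnibus false-positive rate from ~0.05 to ≥0.5 (typically ~1 at 4000
pairs); fitting the censored likelihood on the same seeds restores it to
the nominal level.

`required_n` extrapolates the pair count for a target power from a pilot
run's mean LRT statistic: mean χ² − df estimates the noncentrality, which
scales linearly in n; the returned n solves the noncentral-χ² power
equation with the plain two-sided critical value. It is an approximation
(labeled as such), unreliable when the pilot power is near 1 or near α.

## Numerical and design choices

- Monte-Carlo sizes: power experiments default to 1000 replicates; the
  packaged reproduction runs (acceptance script, acceptance tests) use 250
  (500 for the null-size check) with three-binomial-SE tolerances, which
  keeps the full study a few minutes on one CPU.
- α = 0.05 throughout, configurable.
- AIC is emitted in fit reports with the degrees-of-freedom penalty
  (−2LL − 2·(2n − k)) for parity with conventional twin-model tables; it is
  not used for decisions.
- Twin tables are wide CSV (one row per pair) because the likelihood is
  pair-wise; the floor is declared in a `# floor=` header comment and the
  writer emits 17-significant-digit floats for lossless round trips.
- MZ rows must have identical PGS values (tolerance 1e-6); violations name
  the offending row. Complete pairs only.

## Known limitations

- The censored likelihood assumes the floor is known and shared; interval
  or right censoring is not implemented.
- Standard errors of estimates are not reported (tests are LRT-based); no
  sandwich or Bayesian machinery.
- `required_n` ignores the finite-sample excess of the empirical rejection
  rate over the noncentral-χ² approximation, so it is conservative for the
  weakly identified C-moderation test.
- The attenuation correction propagates no uncertainty in RA²; with a weak
  PGS the corrected coefficients can be implausibly large.
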