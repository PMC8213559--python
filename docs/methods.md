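# Methods

## The measurement problem

Magnitude estimation asks an observer to rate test stimuli relative to a
reference stimulus carrying the modulus rating 10.  Under Stevens' power law
the latent perceived intensity is psi(I) = k·I^a, so the noiseless rating in
the standard format is 10·f with f = psi(I_test)/psi(I_ref) = (I_test/I_ref)^a
— the proportionality constant k cancels in the ratio.  Two alternative
formats probe whether observers can actually use this asymmetric scale: a
*reversal* format (rating 10/f, the scale inverted) and a *unidirectional*
format (a binary "higher/lower" judgment followed by a rating
10·max(f, 1/f) ≥ 10, so the observer never divides).

## Scale conventions

All modelling happens on a 0–1 scale for both axes:

- predictor x: luminance as Y/100 (fraction of the 100 cd/m² maximum, so the
  10 cd/m² reference maps to 0.1); red saturation as the nominal fraction
  (0.15…0.85, reference 0.50).  Nominal values drive simulation and fitting;
  measured colorimetry (CIE XYZ, L*, h*, S) is stored alongside.
- response y: rating/100.

With ratio-anchored responses this convention ties the power-law intercept to
the exponent, b0 = 1/(10·x_ref^a): e.g. a = 0.44 with x_ref = 0.1 implies
b0 ≈ 0.275, and a = 1.99 with x_ref = 0.5 implies b0 ≈ 0.40 — the parameter
magnitudes the fitted models report.

The saturation formula is implemented as S = C*/(C*² + L*²)^½ · 100, the
standard CIE LCh saturation: it is scale-invariant, bounded by 100, and
reproduces the stored S column from (back-computed) chroma and lightness.
(A squared-chroma numerator would be dimensionally inconsistent with a
percentage bound.)

## Synthetic observers

`PopulationSpec` draws participant (k, a) pairs from normal distributions
truncated at zero (defaults per study arm follow the fitted per-condition
posteriors: luminance 0.44 ± 0.18 standard / 0.55 ± 0.30 unidirectional with
residual SD 0.03/0.05; red saturation 1.99 ± 1.01 and 1.73 ± 0.91 with
residual SD 0.04; 8 test stimuli × 5 repetitions = 40 trials per condition;
sample sizes 20, 16/18 and 18/18).  Response noise is additive normal on the
normalised y scale — exactly the likelihood the hierarchical models assume —
then mapped to rating units and truncated at the format's lower bound (0, or
the modulus 10 for the unidirectional format, whose scale does not extend
below the reference).  Direction judgments derive from the noiseless latent
ratio; a configurable error rate flips a fraction of them to exercise the
exclusion logic.

The anchoring-bias transform operationalises difference-thinking: for
below-reference trials in the standard format the rating becomes
λ·r + (1−λ)·max(0, 10 − c·(1/f − 1)), a blend between the ratio response and
a responder who reports the perceived *difference* on the 0–10 sub-scale.
λ = 1 (the default) is unbiased; λ and c are free simulator knobs, not
estimates — no quantitative bias model is implied by the hypothesis itself.

What the generator does *not* emulate: adaptation, trial-order and
range/location effects, idiosyncratic number preferences (round-number
clumping), and any heteroscedasticity of response noise.  Passing tests
therefore demonstrate correctness of the analysis chain under its own
assumptions, not validity of those assumptions for human data.

## Preprocessing

Fixed order: floor exact zeros to 0.001 (the reciprocal recode and the log
transform are undefined at zero), drop directed-format trials whose binary
judgment contradicts the objective intensity relation to the reference (the
single documented erroneousness criterion), recode reversal trials (all) and
unidirectional below-reference trials with r′ = 100/r, then take natural
logs.  Recoded values are kept at full precision.  Trials rated exactly at
the modulus in a directed format are retained with their stated direction.

## ANOVA

The 2 × 8 designs are analysed on cell means (one mean log rating per
participant × method × stimulus; repeated-measures practice, and balanced by
design — unbalanced cells are rejected rather than approximated).  Sums of
squares are the classical sequential decomposition, exact here because cell
frequencies are proportional.  Greenhouse–Geisser epsilon is Box's estimate;
in the mixed design it is computed from the covariance pooled *within*
groups (group means removed — the convention of SPSS and of
`pingouin.epsilon` applied to group-centered data), and in the fully-within
design per effect from the effect's orthonormal contrast covariance (the
car/afex convention).  Generalized eta squared follows Olejnik–Algina/
Bakeman: SS_effect / (SS_effect + all subject-level error SS), which is
invariant to shifting or rescaling the response.  F statistics for
within-subject effects use their own error strata; p values are reported
both uncorrected and at GG-corrected degrees of freedom.

## Hierarchical models and priors

Power law: y_ij ~ N(b0_j·x^(b1_j), σ_e²), b0_j = b0 + u0_j,
b1_j = b1 + u1_j, with priors b0 ~ N(0, 5), b1 ~ N(1, 0.5) truncated to
positive support, u's ~ N(0, σ_u²), and half-Student-t(3, 0, 2.5) on every
standard deviation ("N(m, s)" second arguments are standard deviations
throughout).  Linear: y_ij ~ N(β0_j + β1_j·x, σ_e²) with β0 ~ N(0, 5),
β1 ~ N(0, 1), correlated random effects (u0, u1) ~ MVN(0, Σ) with an LKJ(1)
prior on the correlation — uniform on (−1, 1) in the 2 × 2 case — giving the
linear model one extra random-effect parameter.  Models are fitted per
condition separately; a joint two-condition model is out of scope.

### Sampling

No gradient-based PPL is used: the posterior is sampled with the
affine-invariant ensemble sampler (emcee; 80% differential-evolution moves,
20% snooker moves) on the unconstrained scale — log transforms for σ's and
the positive exponent, atanh for the correlation, with the corresponding
Jacobians in the joint density.  Participant effects are parameterized
*centered* (b0_j, b1_j sampled directly): with 320–640 informative
observations per fit the random effects are well identified and the centered
geometry mixes markedly better in the ensemble sampler than the non-centered
one (no funnel arises because the σ_u posteriors are bounded away from
zero); the contract is the correct posterior, not a particular
parameterization.  Walkers are initialised around per-participant
least-squares fits.  The conventional "chains × draws" interface is mapped
onto the ensemble: after `warmup` discarded moves, draws are thinned (default
5) until `total_draws` are retained across all walkers; split-R-hat and ESS
(arviz) treat walkers as chains, and R-hat > 1.01 on any population
parameter raises a ConvergenceWarning and marks the fit non-converged rather
than failing silently.  Defaults mirror the conventional 4 chains / 2,000
warmup / 20,000 retained draws; reduced settings (4 × 1,000) are used in
tests and the acceptance script.

In the linear model fitted to power-law-generated data the random-effect
correlation piles up near −1 (intercept and slope are both functions of the
same latent exponent); this is a genuine posterior feature, and the atanh
parameterization lets the sampler reach it, at the cost of slow mixing in
that one coordinate.

## Marginal likelihoods and Bayes factors

Log marginal likelihoods use the iterative optimal-bridge identity (Meng &
Wong) on the unconstrained scale, which is simultaneously the scale the
sampler works on: the proposal is a moment-matched multivariate normal
fitted to the first half of the posterior draws, the second half enters the
bridge, and the iteration runs in log space (logsumexp, median-shifted) to a
relative tolerance of 1e-10 or 1,000 iterations.  The estimate is repeated
10 times, re-drawing the proposal sample while reusing the posterior draws;
the mean is reported with the repetition SD as the precision statement.  Log
Bayes factors are pairwise differences of per-repetition log marginal
likelihoods and are antisymmetric by construction.  On a conjugate
normal–normal test model the estimator is accurate to ~1e-4 log units at
20,000 draws.

## WAIC and LOO

WAIC = −2·(lppd − p_waic) with p_waic the summed posterior variance of the
pointwise log densities.  LOO uses Pareto-smoothed importance sampling
(smoothing via arviz.psislw); shape diagnostics are reported but never used
to refuse a result.  Degenerate point posteriors short-circuit to uniform
weights, so a single-draw posterior gives p_waic = 0 and LOOIC = WAIC
exactly.  Standard errors are observation-wise on the deviance scale:
SE = sqrt(n · var of the per-observation −2·elpd contributions) — the
convention of the loo ecosystem; reported "(SE)" values follow it.

## Posterior predictive checks

Each of the (default 10) replicates takes one posterior draw and simulates
the full response vector from the likelihood at the observed design points,
reported in rating units.  The headline summary pools over stimuli (the
check asks whether the overall rating distribution is reproduced);
per-stimulus replicate means are available for finer diagnostics, and the
optional density overlay uses a fixed Silverman-bandwidth Gaussian KDE so
graphical output is deterministic.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to exercise the claims without
waste: parameter-recovery checks use 16 participants × 40 trials at
4 × 1,000 draws (20 seeded experiments, both compressive a = 0.45 and
expansive a = 1.7 regimes); model-selection sign-consistency uses 20
power-generated and 20 linear-generated datasets of 8 participants each —
the evidence at 320 trials is already an order of magnitude away from the
decision boundary, so the smaller panel loses nothing; ANOVA type-I
calibration uses 1,000 null simulations of a mixed 2 × 4 design with a
strongly non-spherical covariance (epsilon ≈ 0.55).  Exponent overflow in
x^b is guarded by clipping b·log x at ±60 (far outside any region of
posterior mass); covariance fits for the bridge proposal add a 1e-10 ridge.

## Known limitations

- R-hat treats ensemble walkers as chains; they are not independent, so the
  diagnostic is approximate (it reliably flags gross non-convergence, which
  is its role here).
- The retained draw count is rounded up to a multiple of the walker count.
- The anchoring-bias transform is one concrete operationalisation of
  difference-thinking among many; conclusions about the bias mechanism are
  conditional on it.
- Default Bayes factors for the ANOVA designs (Cauchy-prior BF-ANOVA) are
  not implemented; the classical GG-corrected ANOVA is reported and BF-ANOVA
  is noted as an extension.
- Whether cell means or trial-level responses enter the ANOVA, and the exact
  axis normalisation of the hierarchical models, are fixed here (cell means;
  /100) as documented conventions.
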