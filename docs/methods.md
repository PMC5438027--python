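# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `lvpet`.

## The structural model

Seven regional [11C]DASB BP_ND outcomes per subject load on one latent
variable (5-HTT_LV) that captures their shared correlation:

    eta_i = beta' x_i + zeta_i,        zeta_i ~ N(0, psi)
    y_ij  = nu_j + lambda_j eta_i + delta_j' x_i + eps_ij,  eps_i ~ N(0, Theta)

Identification: the thalamus loading is fixed at 1 and the latent
intercept at 0, region intercepts and the latent residual variance psi
are free.  Latent-path coefficients are therefore interpretable as
effects on thalamus BP_ND; age enters in centred decades so its
coefficient is per decade.  Theta is diagonal plus explicitly modelled
residual covariances (caudate–putamen, midbrain–thalamus,
amygdala–hippocampus in the final specification).  PET and MRI scanner
indicators act as direct paths on every region: scanner differences are
region-specific (resolution-dependent spill-in), so routing them through
the latent variable would misattribute them.  With both scanners on all
seven regions, genotypes and age as latent predictors, a direct
genotype→neocortex and a direct sex→caudate path, the final model has 43
free parameters.

The marginal likelihood is Gaussian, y_i ~ N(nu + (lambda beta' + Delta)
x_i, psi lambda lambda' + Theta), maximised over all free parameters
simultaneously.

### Saturated reference and fit indices

The saturated model regresses each region on the union of covariates
appearing anywhere in the structural model (unrestricted 7 x (1 + K) mean
coefficients) with an unstructured 7x7 covariance — 77 parameters for the
final specification, making the likelihood-ratio comparison a 34-df test.
Its ML solution is closed-form (multivariate least squares; covariance
R'R/n), so the LRT needs no second optimisation.

RMSEA = sqrt(max(chi2 - df, 0) / (df * d)).  Both denominator conventions
d = n - 1 (default) and d = n are computed and reported, because the two
round identically (0.059) at the study size yet published software
differs in convention; a published value of 0.058 from the same
chi2/df/n is therefore a convention difference, not a reproducible
quantity, and the package flags rather than asserts it.  The 90% CI
inverts the noncentral chi-square CDF in its noncentrality parameter
(Brent root-finding; lower bound 0 when the central CDF already exceeds
0.95).

### Estimation

Optimisation is quasi-Newton (L-BFGS-B) on a transformed scale — log
variances, atanh of residual correlations (each pair covariance is
rho * sqrt(theta_a theta_b), keeping every 2x2 residual block positive
definite) — with an analytic gradient, followed by Newton refinement on
the natural scale until the step falls below 1e-11, so estimates reach
near-machine precision (the one-outcome degenerate model reproduces the
closed-form least-squares solution to 1e-8).  Moment-based starting
values (loadings from covariances with the reference region, half the
reference variance as psi); up to five jittered restarts on
non-convergence, with an honest `converged` flag.  Standard errors come
from the inverse observed information (negative Hessian by central
differences of the analytic score); a non-invertible information falls
back to a pseudo-inverse with a warning and a flag.  Wald intervals use
the normal quantile 1.959964.  Total covariate effects on a region are
direct + indirect (beta * lambda) with a delta-method CI from the joint
parameter covariance.

### Model search

The build loop mirrors the study design: (1) backward pruning of latent
predictors — repeatedly drop the largest Wald p above alpha = 0.05 and
refit; the genotype terms are protected because they are the scientific
question; (2) greedy forward search — every absent covariate→region
direct path (covariates pruned in step 1 remain eligible; paths from
current latent predictors onto the reference region are excluded to
protect the reference scale) and every absent residual-covariance pair is
fitted as a single addition, the added parameter Wald-tested in the
augmented fit, p-values Benjamini–Hochberg-adjusted across all
candidates, and the smallest-p candidate added while its q-value is
below 0.05.  One addition per iteration, refitting after each; all
remaining candidates are re-tested every iteration.  Non-converged
candidate fits are recorded as missing but still count in the BH
denominator.  Greedy single addition is the conservative reading of an
iterative procedure and keeps the trace replayable.

## Synthetic cohort generator

The generator is the package's study stand-in: genotypes are drawn from
Hardy–Weinberg proportions at met-allele frequency 61/288, with 5-HTTLPR
carrier status independent Bernoulli (P(L_A L_A) = 42/144); age is a
truncated normal on [18, 51] whose *truncated* mean and sd equal
26.7/7.1 (the parent parameters are solved numerically, since the
configured moments describe the observed, range-restricted cohort); sex,
scanner and the remaining covariates match the cohort table
(male 59/144, HRRT 101/144, Verio 60/144, BMI 23.6±2.9, daylight
669±219 min, injected mass 0.044±0.043 μg/kg).  BP_ND values follow the
structural model above with generating values set to the fitted
estimates the model can recover:

- latent paths: genotype (met-carrier) +0.085, 5-HTTLPR -0.05 (not
  significant by design), age -0.098 per decade;
- direct paths: sex→caudate +0.14; genotype→neocortex
  -(0.085 * lambda_neo) - 0.004, so the total neocortex effect is -0.004
  (direct and indirect cancel); PET scanner effects on every region
  (+0.04 to +0.25, larger where HRRT resolution matters most); MRI
  scanner on midbrain only (+0.05);
- loadings/intercepts calibrated to realistic [11C]DASB levels
  (neocortex lowest ~0.3, thalamus/midbrain highest ~1.9) such that
  met-carrier percent differences land in the published 2–7% subcortical
  band; psi = 0.06, region residual variances 0.004–0.03, pair residual
  covariances 0.008.

Region loadings and intercepts are not publicly reported for the
emulated study, so these are calibrated, not transcribed.  Continuous covariates are
centred at their configured population means inside the generator
(deterministically), dummies enter raw; the fitting side centres at
sample means — the O(n^-1/2) difference moves only the intercepts.

One master seed drives everything; per-stage substreams are spawned
deterministically so cohort, covariate and noise draws are individually
reproducible.  The generator emulates the *statistical* structure only:
no voxel images, no hemispheres (bilateral values are drawn directly),
no partial-volume effects, no genotype-covariate confounding.  Passing
tests therefore demonstrate correct recovery under the assumed model,
not robustness to real-data violations of it.

## Kinetics

Reference (cerebellar) curves are gamma variates A t^a e^(-t/b)
(A = 388 Bq/ml, a = 1.5, b = 4 min), calibrated so the 0–90-min AUC is
near the cohort-mean 16,494 Bq/ml·min; target curves follow the
simplified reference tissue model, computed by convolution on a 1-second
grid and averaged over the 36-frame schedule (6x10, 3x20, 6x30, 5x60,
5x120, 8x300, 3x600 s).  Integrating the one-tissue ODE gives the exact
multilinear relation C_T(T) = k2 ∫C_ref - k2a ∫C_T + R1 C_ref(T), so
MRTM is ordinary least squares on {∫C_ref, ∫C_T, C_ref} with
BP_ND = -(g1/g2) - 1 and k2' = g1/g3; MRTM2 fixes k2' (estimated per
subject from the volume-weighted caudate+putamen curve) and drops to two
regressors.

Numerical choices: cumulative integrals use frame sums (activity x
duration, half the current frame to its midpoint) — exact for curves
linear within a frame and accurate to <0.7% BP_ND on the default
schedule, where a trapezoid between frame midpoints loses >2% on the
long late frames; t* defaults to 0 (all frames) and is configurable;
least squares is unweighted by default with optional per-frame weights;
optional noise is zero-mean Gaussian with sd proportional to
sqrt(activity / frame duration), emulating counting statistics.  A
target exactly proportional to the reference (c C_ref) makes the MRTM
design collinear; the identifiable limit BP = c - 1 is returned with
k2' = NaN, and an all-zero target raises.

## Univariate companion analyses

Per-region OLS of BP_ND on the genotype dummy plus age, PET and MRI
scanner (sex additionally for caudate), with t-based inference on
residual degrees of freedom (at n = 144 the difference from normal
inference is negligible).  Percent difference = 100 x estimate /
intercept; it is computed for all seven regions but the 2–7% band is a
subcortical statement and the output labels regions accordingly.
Family-wise correction across the seven regions is Holm step-down on
unrounded p-values; the Hardy–Weinberg test is the Pearson chi-square
without continuity correction (df = 1), which reproduces the published
statistic from the printed counts.  Balance tables use Welch t-tests
(continuous) and 2x2 chi-square without continuity correction
(categorical), skipping degenerate groups with a note.

## Problem sizes used in validation

Simulation-based checks run at deliberately chosen desk scales: moment
convergence at n = 100,000; parameter recovery over 200 replicates and
null calibration over 500 replicates of n = 144; single-step search
power and false-positive checks with 9–12 replicates at n = 1,000; full
structure recovery (prune + search) on one n = 2,000 cohort.  The
recovery script reports means over 200 replicate cohorts of n = 144.

## Known limitations

- Complete-case Gaussian ML only: no missing-data handling, no robust
  (sandwich) errors by default (available behind a flag in the results
  covariance computation path), no ordinal outcomes, single factor only.
- Wald-based search inherits the usual greedy-selection caveats;
  q-values control the per-iteration FDR across candidates, not a
  path-wise error over the whole search.
- The kinetic stage models one-tissue reference kinetics with a shared
  frame schedule; no arterial input, no scatter/attenuation modelling,
  no voxelwise estimation.
- RMSEA conventions differ across published software (see above); both
  denominators are reported.
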