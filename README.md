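# lvpet

Latent-variable modelling of regional serotonin-transporter PET binding.

Molecular imaging genetics studies ask whether common polymorphisms — here
BDNF val66met (rs6265) and 5-HTTLPR — shift serotonin-transporter (5-HTT)
availability, indexed by the non-displaceable binding potential (BP_ND) of
[11C]DASB PET in a set of brain regions.  Because regional BP_ND values
are strongly intercorrelated, testing one region at a time wastes shared
information; modelling a single latent variable that generates the shared
correlation pools it instead, and small genotype effects become
detectable.  `lvpet` implements that analysis end to end, exercised
entirely on a synthetic-cohort generator that emulates the statistical
structure of a 144-subject [11C]DASB study, so every stage is testable
without access to the original (non-public) data.

## The model

For subject *i* with covariates *x_i* (genotype dummies, age in centred
decades, scanner indicators, ...), the seven regional outcomes
*y_i* = (amygdala, caudate, hippocampus, midbrain, neocortex, putamen,
thalamus) follow a one-factor structural model

    eta_i = beta' x_i + zeta_i,          zeta_i ~ N(0, psi)
    y_ij  = nu_j + lambda_j eta_i + delta_j' x_i + eps_ij,   eps_i ~ N(0, Theta)

with the thalamus loading fixed at 1, so latent-path coefficients beta are
read in thalamus BP_ND units.  Theta is diagonal apart from residual
covariances for caudate–putamen, midbrain–thalamus and
amygdala–hippocampus.  Marginally *y_i* ~ N(mu(x_i), Sigma) with
mu(x_i) = nu + (lambda beta' + Delta) x_i and
Sigma = psi lambda lambda' + Theta; the model is estimated by full
maximum likelihood with standard errors from the observed information.

Around the core model the package provides:

- **`lvpet.cohort`** — seeded synthetic cohorts: Hardy–Weinberg genotypes,
  study-matched covariate distributions, and BP_ND draws from the forward
  model above.
- **`lvpet.kinetics`** — frame-sampled time–activity curves from the
  simplified reference tissue model, and BP_ND quantification via the
  multilinear reference tissue models (MRTM, and MRTM2 with an
  individually estimated reference clearance k2').
- **`lvpet.sem`** — `LatentFactorModel` / `LatentFactorResults`
  (statsmodels-style): ML fitting, Wald tests, the likelihood-ratio
  comparison against a saturated model, RMSEA with a noncentral-chi-square
  90% CI, and direct/indirect/total effect decompositions.
- **`lvpet.search`** — the data-driven model-building loop: pruning of
  unsupported latent predictors, then greedy forward addition of paths
  gated by Benjamini–Hochberg FDR (q < 0.05) over all candidate paths.
- **`lvpet.univariate`** — per-region regressions, percent differences,
  Holm family-wise correction, Hardy–Weinberg and group-balance tests.
- **`lvpet.pipeline` / `lvpet` CLI** — one-command orchestration with
  byte-reproducible output bundles.

## Worked example

```python
from lvpet import CohortConfig, LatentFactorModel, ModelSpec, simulate_cohort

cohort = simulate_cohort(CohortConfig(seed=7))          # n = 144
results = LatentFactorModel.from_cohort(cohort, ModelSpec.final()).fit()
w = results.wald_test("beta_bdnf_group")
print(f"met-carrier effect on the latent variable: "
      f"{w.estimate:.3f} ({w.ci95[0]:.3f}, {w.ci95[1]:.3f}), p = {w.p:.3f}")
fi = results.fit_indices()
print(f"LRT vs saturated: chi2 = {fi.chi2:.1f}, df = {fi.df}, p = {fi.p_value:.3f}; "
      f"RMSEA = {fi.rmsea:.3f}")
```

prints

```
met-carrier effect on the latent variable: 0.077 (-0.008, 0.162), p = 0.075
LRT vs saturated: chi2 = 45.6, df = 34, p = 0.089; RMSEA = 0.049
```

The first line is the genotype contrast on the latent variable in
thalamus BP_ND units (generating value 0.085 for this seed's cohort of
144); the second compares the 43-parameter structural model against the
77-parameter saturated model (34 df).  The same analysis runs from the
shell:

```bash
lvpet simulate --seed 7 --out cohort.csv
lvpet fit --cohort cohort.csv
lvpet run-all --seed 7 --out results_dir/     # full pipeline + report.md
```

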