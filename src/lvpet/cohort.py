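"""Synthetic cohort generation for regional [11C]DASB binding studies.

Generates seeded cohorts whose genotypes, covariates and seven regional
non-displaceable binding potentials (BP_ND) follow a single-latent-factor
structure: a serotonin-transporter latent variable (on the thalamus BP_ND
scale) driven by genotype and age, with region-specific scanner effects,
a caudate-specific sex effect, a direct neocortex genotype effect that
approximately cancels the indirect one, and three residually correlated
region pairs (caudate-putamen, midbrain-thalamus, amygdala-hippocampus).

Forward model, per subject i with covariate row x_i:

    eta_i = beta . x_i + zeta_i,        zeta_i ~ N(0, psi)
    y_ij  = nu_j + lambda_j * eta_i + delta_j . x_i + eps_ij

with eps_i jointly normal, covariance Theta (diagonal plus the three pair
covariances).  lambda_thalamus is fixed at 1 so eta is in thalamus BP_ND
units.  Continuous covariates enter centred at their configured population
means (age additionally divided by 10, so the age coefficient is per
decade); dichotomous covariates enter as raw 0/1 dummies so coefficients
are group contrasts.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "RESIDUAL_PAIRS",
    "CohortConfig",
    "GeneratingParameters",
    "CohortError",
    "generate_genotypes",
    "generate_covariates",
    "generate_bpnd",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Regions quantified in the study, alphabetical; thalamus is the reference.
REGIONS = (
    "amygdala",
    "caudate",
    "hippocampus",
    "midbrain",
    "neocortex",
    "putamen",
    "thalamus",
)

#: Region pairs sharing residual correlation beyond the latent factor.
RESIDUAL_PAIRS = (
    ("caudate", "putamen"),
    ("midbrain", "thalamus"),
    ("amygdala", "hippocampus"),
)

#: Covariate column order used throughout (dummies first, then continuous).
COVARIATE_COLUMNS = (
    "bdnf_group",
    "shttlpr_group",
    "age",
    "sex",
    "pet_scanner",
    "mri_scanner",
    "bmi",
    "daylight",
    "injected_mass",
)

CSV_COLUMNS = (
    "subject_id",
    "bdnf_genotype",
    "bdnf_group",
    "shttlpr_group",
    "age",
    "sex",
    "pet_scanner",
    "mri_scanner",
    "bmi",
    "daylight",
    "injected_mass",
) + tuple(f"bpnd_{r}" for r in REGIONS)


class CohortError(ValueError):
    """Invalid cohort configuration, parameters or file format."""


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for genotypes and covariates.

    Defaults reproduce the demographic composition of the 144-subject
    cohort: met-allele frequency 61/288, L_A L_A frequency 42/144, age
    26.7 +/- 7.1 years truncated to [18, 51], 59/144 male, 101/144 HRRT
    PET scans, 60/144 Verio MRI scans, BMI 23.6 +/- 2.9 kg/m^2, daylight
    669 +/- 219 min, weight-adjusted injected mass 0.044 +/- 0.043 ug/kg.
    """

    n_subjects: int = 144
    met_allele_freq: float = 61 / 288
    shttlpr_LALA_freq: float = 42 / 144
    age_mean: float = 26.7
    age_sd: float = 7.1
    age_min: float = 18.0
    age_max: float = 51.0
    sex_male_prob: float = 59 / 144
    pet_hrrt_prob: float = 101 / 144
    mri_verio_prob: float = 60 / 144
    bmi_mean: float = 23.6
    bmi_sd: float = 2.9
    daylight_mean: float = 669.0
    daylight_sd: float = 219.0
    injected_mass_mean: float = 0.044
    injected_mass_sd: float = 0.043
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("met_allele_freq", "shttlpr_LALA_freq", "sex_male_prob",
                     "pet_hrrt_prob", "mri_verio_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"{name}={p!r} is not a probability in [0, 1]")
        if self.n_subjects < 10:
            raise CohortError("n_subjects must be at least 10")
        if not (0.0 < self.age_min < self.age_max < 120.0):
            raise CohortError(
                f"age range ({self.age_min}, {self.age_max}) must be increasing and within (0, 120)"
            )
        for name in ("age_sd", "bmi_sd", "daylight_sd", "injected_mass_sd"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be non-negative")


def _default_loadings() -> dict[str, float]:
    return {
        "amygdala": 0.55,
        "caudate": 1.05,
        "hippocampus": 0.25,
        "midbrain": 1.00,
        "neocortex": 0.20,
        "putamen": 1.10,
        "thalamus": 1.0,  # reference scale, fixed
    }


def _default_intercepts() -> dict[str, float]:
    # BP_ND means in realistic [11C]DASB ranges: neocortex lowest,
    # thalamus/midbrain highest.
    return {
        "amygdala": 1.25,
        "caudate": 1.45,
        "hippocampus": 0.65,
        "midbrain": 1.90,
        "neocortex": 0.30,
        "putamen": 1.50,
        "thalamus": 1.90,
    }


def _default_latent_coeffs() -> dict[str, float]:
    # Thalamus-BP_ND units per covariate unit; age is per decade.
    return {"bdnf_group": 0.085, "shttlpr_group": -0.05, "age": -0.098}


def _default_direct_effects() -> dict[tuple[str, str], float]:
    # (covariate, region) -> BP_ND units.  The neocortex genotype path is
    # chosen so the total effect 0.085*lambda_neo + delta is -0.004.
    effects: dict[tuple[str, str], float] = {
        ("bdnf_group", "neocortex"): -(0.085 * 0.20) - 0.004,
        ("sex", "caudate"): 0.14,
        ("mri_scanner", "midbrain"): 0.05,
    }
    # HRRT resolves small structures better, so binding reads higher there,
    # by region-dependent amounts.
    pet = {
        "amygdala": 0.15,
        "caudate": 0.20,
        "hippocampus": 0.08,
        "midbrain": 0.25,
        "neocortex": 0.04,
        "putamen": 0.20,
        "thalamus": 0.25,
    }
    for region, value in pet.items():
        effects[("pet_scanner", region)] = value
    return effects


def _default_resid_vars() -> dict[str, float]:
    return {
        "amygdala": 0.030,
        "caudate": 0.020,
        "hippocampus": 0.010,
        "midbrain": 0.030,
        "neocortex": 0.004,
        "putamen": 0.015,
        "thalamus": 0.020,
    }


def _default_resid_covs() -> dict[tuple[str, str], float]:
    return {pair: 0.008 for pair in RESIDUAL_PAIRS}


@dataclass(frozen=True)
class GeneratingParameters:
    """Full parameter set of the forward structural model.

    ``loadings`` are in BP_ND units per latent unit with the thalamus
    loading fixed at 1; ``latent_coeffs`` are on the thalamus BP_ND scale
    (age per decade); ``direct_effects`` map (covariate, region) to BP_ND
    units; ``latent_resid_var`` and ``resid_vars`` are squared BP_ND units.
    """

    regions: tuple[str, ...] = REGIONS
    loadings: dict[str, float] = field(default_factory=_default_loadings)
    intercepts: dict[str, float] = field(default_factory=_default_intercepts)
    latent_coeffs: dict[str, float] = field(default_factory=_default_latent_coeffs)
    direct_effects: dict[tuple[str, str], float] = field(default_factory=_default_direct_effects)
    latent_resid_var: float = 0.06
    resid_vars: dict[str, float] = field(default_factory=_default_resid_vars)
    resid_covs: dict[tuple[str, str], float] = field(default_factory=_default_resid_covs)

    def __post_init__(self) -> None:
        if tuple(self.regions) != REGIONS:
            raise CohortError(f"regions must be {REGIONS}")
        if self.loadings.get("thalamus") != 1.0:
            raise CohortError("the thalamus loading is the reference and must equal 1")
        if self.latent_resid_var <= 0:
            raise CohortError("latent residual variance must be positive")
        for region in REGIONS:
            if self.resid_vars.get(region, 0.0) <= 0:
                raise CohortError(f"residual variance for {region} must be positive")
        for (a, b), cov in self.resid_covs.items():
            bound = np.sqrt(self.resid_vars[a] * self.resid_vars[b])
            if abs(cov) >= bound:
                raise CohortError(
                    f"residual covariance for ({a}, {b}) makes the 2x2 block non-positive-definite"
                )

    def residual_covariance(self) -> np.ndarray:
        """The 7x7 residual covariance Theta (diagonal plus pair terms)."""
        theta = np.diag([self.resid_vars[r] for r in REGIONS])
        idx = {r: i for i, r in enumerate(REGIONS)}
        for (a, b), cov in self.resid_covs.items():
            theta[idx[a], idx[b]] = theta[idx[b], idx[a]] = cov
        return theta

    def loading_vector(self) -> np.ndarray:
        return np.array([self.loadings[r] for r in REGIONS])

    def implied_covariance(self) -> np.ndarray:
        """Covariance of y given covariates: lambda psi lambda' + Theta."""
        lam = self.loading_vector()
        return self.latent_resid_var * np.outer(lam, lam) + self.residual_covariance()


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Per-stage substreams from one master seed (stage-level reproducibility)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genotypes(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw BDNF val66met genotypes from Hardy-Weinberg proportions and
    5-HTTLPR carrier groups as independent Bernoulli variables.

    With met-allele frequency p, genotype probabilities are
    (val/val, val/met, met/met) = ((1-p)^2, 2p(1-p), p^2).  The 5-HTTLPR
    group is 1 for S'-carriers (probability 1 - P(L_A L_A)), independent
    of BDNF, matching the observed lack of genotype association.
    """
    if rng is None:
        rng = _spawn(config.seed, 3)[0]
    p = config.met_allele_freq
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    genotypes = rng.choice(["val/val", "val/met", "met/met"], size=config.n_subjects, p=probs)
    shttlpr = (rng.random(config.n_subjects) < (1 - config.shttlpr_LALA_freq)).astype(int)
    return pd.DataFrame(
        {
            "bdnf_genotype": genotypes,
            "bdnf_group": (genotypes != "val/val").astype(int),
            "shttlpr_group": shttlpr,
        }
    )


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a truncated normal on [lo, hi] whose *truncated* mean and sd
    equal the requested values.

    The requested moments describe the observed (range-restricted)
    distribution, so the parent normal's location and scale are solved
    numerically such that the truncated distribution reproduces them.
    """
    from scipy import optimize as _opt
    from scipy import stats as _st

    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))

    key = (mean, sd, lo, hi)
    if key in _TRUNCNORM_CACHE:
        mu, s = _TRUNCNORM_CACHE[key]
        a, b = (lo - mu) / s, (hi - mu) / s
        return _st.truncnorm(a, b, loc=mu, scale=s).rvs(size=n, random_state=rng)

    def moments(params):
        mu, log_s = params
        s = np.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        dist = _st.truncnorm(a, b, loc=mu, scale=s)
        return [dist.mean() - mean, dist.std() - sd]

    sol = _opt.fsolve(moments, [mean, np.log(sd)], full_output=True)
    (mu, log_s), _, ok, _ = sol
    if ok != 1 or not np.all(np.isfinite([mu, log_s])):
        raise CohortError(
            f"no truncated normal on [{lo}, {hi}] has mean {mean} and sd {sd}"
        )
    s = float(np.exp(log_s))
    _TRUNCNORM_CACHE[key] = (float(mu), s)
    a, b = (lo - mu) / s, (hi - mu) / s
    return _st.truncnorm(a, b, loc=mu, scale=s).rvs(size=n, random_state=rng)


_TRUNCNORM_CACHE: dict[tuple, tuple[float, float]] = {}


def generate_covariates(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw age (truncated normal), sex/scanner indicators (Bernoulli) and
    BMI, daylight minutes and injected mass (normal; mass truncated at 0)."""
    if rng is None:
        rng = _spawn(config.seed, 3)[1]
    n = config.n_subjects
    age = _truncated_normal(
        config.age_mean, config.age_sd, config.age_min, config.age_max, n, rng
    )
    mass = rng.normal(config.injected_mass_mean, config.injected_mass_sd, size=n)
    mass = np.abs(mass) + 1e-6  # physical quantity; reflect at zero
    return pd.DataFrame(
        {
            "age": age,
            "sex": (rng.random(n) < config.sex_male_prob).astype(int),
            "pet_scanner": (rng.random(n) < config.pet_hrrt_prob).astype(int),
            "mri_scanner": (rng.random(n) < config.mri_verio_prob).astype(int),
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, size=n),
            "daylight": rng.normal(config.daylight_mean, config.daylight_sd, size=n),
            "injected_mass": mass,
        }
    )


def _centred_design(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Covariates as the forward model consumes them: continuous columns
    centred at configured population means (age in decades), dummies raw."""
    x = pd.DataFrame(index=subjects.index)
    x["bdnf_group"] = subjects["bdnf_group"].astype(float)
    x["shttlpr_group"] = subjects["shttlpr_group"].astype(float)
    x["age"] = (subjects["age"] - config.age_mean) / 10.0
    x["sex"] = subjects["sex"].astype(float)
    x["pet_scanner"] = subjects["pet_scanner"].astype(float)
    x["mri_scanner"] = subjects["mri_scanner"].astype(float)
    x["bmi"] = subjects["bmi"] - config.bmi_mean
    x["daylight"] = subjects["daylight"] - config.daylight_mean
    x["injected_mass"] = subjects["injected_mass"] - config.injected_mass_mean
    return x


def generate_bpnd(
    subjects: pd.DataFrame,
    params: GeneratingParameters,
    seed: int | np.random.Generator = 0,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Draw the seven regional BP_ND values for each subject from the
    latent-factor forward model and return the completed cohort table.

    ``subjects`` must carry genotype and covariate columns.  The returned
    frame is ``subjects`` plus ``bpnd_<region>`` columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config is None:
        config = CohortConfig(n_subjects=max(len(subjects), 10))
    missing = [c for c in COVARIATE_COLUMNS if c not in subjects.columns]
    if missing:
        raise CohortError(f"subject table lacks covariate columns: {missing}")

    x = _centred_design(subjects, config)
    n = len(subjects)
    lam = params.loading_vector()
    nu = np.array([params.intercepts[r] for r in REGIONS])

    beta_x = np.zeros(n)
    for cov, b in params.latent_coeffs.items():
        if ":" in cov:  # interaction term, e.g. "bdnf_group:shttlpr_group"
            a, c = cov.split(":", 1)
            beta_x += b * x[a].to_numpy() * x[c].to_numpy()
        else:
            beta_x += b * x[cov].to_numpy()
    eta = beta_x + rng.normal(0.0, np.sqrt(params.latent_resid_var), size=n)

    delta = np.zeros((n, len(REGIONS)))
    idx = {r: i for i, r in enumerate(REGIONS)}
    for (cov, region), d in params.direct_effects.items():
        delta[:, idx[region]] += d * x[cov].to_numpy()

    theta = params.residual_covariance()
    try:
        chol = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in __post_init__
        raise CohortError("residual covariance is not positive definite") from exc
    eps = rng.standard_normal((n, len(REGIONS))) @ chol.T

    y = nu[None, :] + np.outer(eta, lam) + delta + eps
    out = subjects.copy()
    for j, region in enumerate(REGIONS):
        out[f"bpnd_{region}"] = y[:, j]
    return out


def simulate_cohort(
    config: CohortConfig | None = None,
    params: GeneratingParameters | None = None,
) -> pd.DataFrame:
    """One-call cohort simulation: genotypes, covariates, then BP_ND.

    Fixing ``config.seed`` fixes every byte of the output; each stage uses
    its own substream of the master seed.
    """
    config = config or CohortConfig()
    params = params or GeneratingParameters()
    rng_geno, rng_cov, rng_bpnd = _spawn(config.seed, 3)
    geno = generate_genotypes(config, rng_geno)
    cov = generate_covariates(config, rng_cov)
    subjects = pd.concat([geno, cov], axis=1)
    subjects.insert(0, "subject_id", [f"s{i + 1:04d}" for i in range(config.n_subjects)])
    return generate_bpnd(subjects, params, rng_bpnd, config=config)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV with a fixed column order."""
    missing = [c for c in CSV_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortError(f"cohort table lacks columns: {missing}")
    bpnd = cohort[[f"bpnd_{r}" for r in REGIONS]]
    if bpnd.isna().any().any():
        bad = bpnd.isna().any()
        col = bad.index[bad.argmax()]
        row = int(bpnd[col].isna().idxmax())
        raise CohortError(f"NaN BP_ND in column {col}, row {row}")
    cohort.loc[:, list(CSV_COLUMNS)].to_csv(path, index=False, float_format="%.10g")


def read_cohort(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a cohort CSV (tolerant of leading '#' comment lines),
    validating presence of every required column."""
    table = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"cohort file lacks columns: {missing}")
    bpnd = table[[f"bpnd_{r}" for r in REGIONS]]
    if bpnd.isna().any().any():
        bad = bpnd.isna().any()
        col = bad.index[bad.argmax()]
        row = int(bpnd[col].isna().idxmax())
        raise CohortError(f"NaN BP_ND in column {col}, row {row}")
    return table[list(CSV_COLUMNS)]


def null_parameters(**overrides) -> GeneratingParameters:
    """Generating parameters with every covariate path zeroed (null model),
    optionally overriding selected fields afterwards."""
    base = GeneratingParameters(
        latent_coeffs={"bdnf_group": 0.0, "shttlpr_group": 0.0, "age": 0.0},
        direct_effects={},
    )
    return dataclasses.replace(base, **overrides) if overrides else base
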