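"""Single-latent-variable structural model for regional PET binding.

The seven regional BP_ND outcomes y_i of subject i load on one latent
serotonin-transporter variable (5-HTT_LV) regressed on covariates x_i:

    eta_i = beta . x_i + zeta_i,   zeta_i ~ N(0, psi)
    y_ij  = nu_j + lambda_j eta_i + delta_j . x_i + eps_ij,
    eps_i ~ N(0, Theta),

Theta diagonal apart from explicitly modelled residual-covariance pairs.
The thalamus loading is fixed at 1 (latent intercept 0), so latent-path
coefficients read as effects on thalamus BP_ND.  Marginally

    y_i ~ N( nu + (lambda beta' + Delta) x_i ,  psi lambda lambda' + Theta )

and the model is fitted by maximising the Gaussian likelihood over all
free parameters simultaneously, with standard errors from the inverse
observed information.  Scanner (PET/MRI) effects enter as direct paths on
each region; with both scanners on all seven regions the default final
specification has 43 free parameters against a saturated model with 77,
i.e. a 34-df likelihood-ratio comparison.

Follows the statsmodels idiom: :class:`LatentFactorModel` is built from a
cohort table, ``fit()`` returns a :class:`LatentFactorResults` carrying
estimates, their covariance, Wald tests, fit indices and effect
decompositions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import REGIONS, RESIDUAL_PAIRS

__all__ = [
    "ModelSpec",
    "ModelError",
    "prepare_design",
    "implied_moments",
    "LatentFactorModel",
    "LatentFactorResults",
    "FitIndices",
    "EffectDecomposition",
    "WaldTest",
    "rmsea",
    "lrt_pvalue",
    "add_interaction",
]

Z_95 = 1.959964  # normal quantile for 95% Wald intervals

#: Dichotomous covariates with their 0-coded reference levels.
DICHOTOMOUS = {
    "bdnf_group": "val/val",
    "shttlpr_group": "L_A L_A",
    "sex": "female",
    "pet_scanner": "Advance",
    "mri_scanner": "Trio",
}
CONTINUOUS = ("age", "bmi", "daylight", "injected_mass")


class ModelError(ValueError):
    """Invalid model specification, data or estimation failure."""


def _norm_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of the latent-variable model.

    ``latent_predictors`` regress the latent variable; ``direct_paths``
    are extra (covariate, region) effects; ``resid_cov_pairs`` free the
    named off-diagonal residual covariances; scanner covariates act as
    direct paths on the listed regions.  Interaction predictors are named
    ``"a:b"`` and expand to the product column.
    """

    outcomes: tuple[str, ...] = REGIONS
    latent_name: str = "5-HTT_LV"
    reference_outcome: str = "thalamus"
    latent: bool = True
    latent_predictors: tuple[str, ...] = ()
    direct_paths: tuple[tuple[str, str], ...] = ()
    resid_cov_pairs: tuple[tuple[str, str], ...] = ()
    pet_scanner_regions: tuple[str, ...] = REGIONS
    mri_scanner_regions: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "latent_predictors", tuple(self.latent_predictors))
        object.__setattr__(self, "direct_paths", tuple(tuple(p) for p in self.direct_paths))
        object.__setattr__(
            self, "resid_cov_pairs", tuple(_norm_pair(tuple(p)) for p in self.resid_cov_pairs)
        )
        object.__setattr__(self, "pet_scanner_regions", tuple(self.pet_scanner_regions))
        object.__setattr__(self, "mri_scanner_regions", tuple(self.mri_scanner_regions))
        if self.latent and self.reference_outcome not in self.outcomes:
            raise ModelError(f"reference outcome {self.reference_outcome!r} not among outcomes")
        paths = self.all_direct_paths
        if len(set(paths)) != len(paths):
            raise ModelError("duplicate direct paths in specification")
        for cov, region in paths:
            if region not in self.outcomes:
                raise ModelError(f"direct path targets unknown region {region!r}")
        if len(set(self.resid_cov_pairs)) != len(self.resid_cov_pairs):
            raise ModelError("duplicate residual-covariance pairs")
        for a, b in self.resid_cov_pairs:
            if a == b or a not in self.outcomes or b not in self.outcomes:
                raise ModelError(f"invalid residual-covariance pair ({a}, {b})")
        if len(set(self.latent_predictors)) != len(self.latent_predictors):
            raise ModelError("duplicate latent predictors")

    @property
    def all_direct_paths(self) -> tuple[tuple[str, str], ...]:
        scanner = tuple(("pet_scanner", r) for r in self.pet_scanner_regions) + tuple(
            ("mri_scanner", r) for r in self.mri_scanner_regions
        )
        return scanner + self.direct_paths

    @property
    def covariates(self) -> tuple[str, ...]:
        """Union of covariates appearing anywhere in the model, in stable order."""
        seen: dict[str, None] = {}
        for cov in self.latent_predictors:
            seen.setdefault(cov, None)
        for cov, _ in self.all_direct_paths:
            seen.setdefault(cov, None)
        return tuple(seen)

    @classmethod
    def base(cls) -> "ModelSpec":
        """Starting model: all candidate covariates regress the latent
        variable; scanners act region-wise; no residual covariances."""
        return cls(
            latent_predictors=(
                "bdnf_group",
                "shttlpr_group",
                "age",
                "sex",
                "bmi",
                "daylight",
                "injected_mass",
            ),
        )

    @classmethod
    def final(cls) -> "ModelSpec":
        """The data-driven final model: genotypes and age on the latent
        variable; direct genotype effect on neocortex and sex effect on
        caudate; three residually correlated region pairs; both scanners
        on every region (43 free parameters)."""
        return cls(
            latent_predictors=("bdnf_group", "shttlpr_group", "age"),
            direct_paths=(("bdnf_group", "neocortex"), ("sex", "caudate")),
            resid_cov_pairs=RESIDUAL_PAIRS,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "outcomes": list(self.outcomes),
            "latent_name": self.latent_name,
            "reference_outcome": self.reference_outcome,
            "latent": self.latent,
            "latent_predictors": list(self.latent_predictors),
            "direct_paths": [list(p) for p in self.direct_paths],
            "resid_cov_pairs": [list(p) for p in self.resid_cov_pairs],
            "pet_scanner_regions": list(self.pet_scanner_regions),
            "mri_scanner_regions": list(self.mri_scanner_regions),
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
        payload["direct_paths"] = [tuple(p) for p in payload.get("direct_paths", [])]
        payload["resid_cov_pairs"] = [tuple(p) for p in payload.get("resid_cov_pairs", [])]
        return cls(**payload)


def prepare_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Centre continuous covariates and validate dummy coding.

    Age is centred at the sample mean and divided by 10, so latent age
    coefficients are per decade; BMI, daylight and injected mass are
    mean-centred; dichotomous covariates must already be 0/1 (references:
    val/val, L_A L_A, female, Advance, Trio).  Returns a copy with the
    transformed covariates and untouched ``bpnd_*`` columns.
    """
    out = cohort.copy()
    for cov in DICHOTOMOUS:
        if cov not in out.columns:
            raise ModelError(f"cohort lacks covariate column {cov!r}")
        values = set(pd.unique(out[cov]))
        if not values <= {0, 1}:
            raise ModelError(f"covariate {cov!r} is not 0/1 dummy coded; saw values {sorted(values)}")
        out[cov] = out[cov].astype(float)
    for cov in CONTINUOUS:
        if cov not in out.columns:
            raise ModelError(f"cohort lacks covariate column {cov!r}")
        out[cov] = out[cov].astype(float) - out[cov].mean()
    out["age"] = out["age"] / 10.0
    return out


# ---------------------------------------------------------------------------
# Parameterisation


class _Parameterisation:
    """Maps a ModelSpec to a flat free-parameter vector (natural scale)
    plus the transformed scale used by the optimiser (log variances,
    atanh residual correlations)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.outcomes = spec.outcomes
        self.p = len(spec.outcomes)
        self.ridx = {r: j for j, r in enumerate(spec.outcomes)}
        self.covs = spec.covariates
        self.cidx = {c: k for k, c in enumerate(self.covs)}
        self.free_loadings = (
            tuple(r for r in spec.outcomes if r != spec.reference_outcome) if spec.latent else ()
        )
        names: list[str] = [f"nu_{r}" for r in spec.outcomes]
        names += [f"lambda_{r}" for r in self.free_loadings]
        names += [f"beta_{c}" for c in spec.latent_predictors]
        names += [f"delta_{c}__{r}" for c, r in spec.all_direct_paths]
        if spec.latent:
            names.append("psi")
        names += [f"theta_{r}" for r in spec.outcomes]
        names += [f"thetacov_{a}__{b}" for a, b in spec.resid_cov_pairs]
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_free = len(names)
        # slices
        i = 0
        self.sl_nu = slice(i, i + self.p); i += self.p
        self.sl_lam = slice(i, i + len(self.free_loadings)); i += len(self.free_loadings)
        self.sl_beta = slice(i, i + len(spec.latent_predictors)); i += len(spec.latent_predictors)
        self.sl_delta = slice(i, i + len(spec.all_direct_paths)); i += len(spec.all_direct_paths)
        if spec.latent:
            self.i_psi = i; i += 1
        else:
            self.i_psi = None
        self.sl_theta = slice(i, i + self.p); i += self.p
        self.sl_cov = slice(i, i + len(spec.resid_cov_pairs)); i += len(spec.resid_cov_pairs)
        assert i == self.n_free
        self.pair_idx = [
            (self.ridx[a], self.ridx[b]) for a, b in spec.resid_cov_pairs
        ]

    # -- structure assembly -------------------------------------------------
    def unpack(self, x: np.ndarray):
        spec = self.spec
        nu = x[self.sl_nu]
        lam = np.zeros(self.p)
        if spec.latent:
            lam[self.ridx[spec.reference_outcome]] = 1.0
            for r, v in zip(self.free_loadings, x[self.sl_lam]):
                lam[self.ridx[r]] = v
        beta = x[self.sl_beta]
        delta = x[self.sl_delta]
        psi = x[self.i_psi] if self.i_psi is not None else 0.0
        theta = x[self.sl_theta]
        covs = x[self.sl_cov]
        return nu, lam, beta, delta, psi, theta, covs

    def mean_matrix(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(nu, B) with mu_i = nu + B x_i over the spec's covariate order."""
        nu, lam, beta, delta, psi, theta, covs = self.unpack(x)
        B = np.zeros((self.p, len(self.covs)))
        for c, b in zip(self.spec.latent_predictors, beta):
            B[:, self.cidx[c]] += lam * b
        for (c, r), d in zip(self.spec.all_direct_paths, delta):
            B[self.ridx[r], self.cidx[c]] += d
        return nu, B

    def sigma(self, x: np.ndarray) -> np.ndarray:
        nu, lam, beta, delta, psi, theta, covs = self.unpack(x)
        sig = np.diag(theta).astype(float)
        if self.spec.latent:
            sig += psi * np.outer(lam, lam)
        for (ja, jb), v in zip(self.pair_idx, covs):
            sig[ja, jb] += v
            sig[jb, ja] += v
        return sig

    # -- transforms ---------------------------------------------------------
    def to_transformed(self, x: np.ndarray) -> np.ndarray:
        t = np.array(x, dtype=float)
        theta = x[self.sl_theta]
        if self.i_psi is not None:
            t[self.i_psi] = np.log(x[self.i_psi])
        t[self.sl_theta] = np.log(theta)
        for m, (ja, jb) in enumerate(self.pair_idx):
            rho = x[self.sl_cov][m] / np.sqrt(theta[ja] * theta[jb])
            t[self.sl_cov.start + m] = np.arctanh(np.clip(rho, -0.999, 0.999))
        return t

    def to_natural(self, t: np.ndarray) -> np.ndarray:
        x = np.array(t, dtype=float)
        if self.i_psi is not None:
            x[self.i_psi] = np.exp(t[self.i_psi])
        theta = np.exp(t[self.sl_theta])
        x[self.sl_theta] = theta
        for m, (ja, jb) in enumerate(self.pair_idx):
            rho = np.tanh(t[self.sl_cov][m])
            x[self.sl_cov.start + m] = rho * np.sqrt(theta[ja] * theta[jb])
        return x

    def chain_gradient(self, t: np.ndarray, g_nat: np.ndarray) -> np.ndarray:
        """Gradient wrt transformed params from the natural-scale gradient."""
        g = np.array(g_nat, dtype=float)
        x = self.to_natural(t)
        theta = x[self.sl_theta]
        if self.i_psi is not None:
            g[self.i_psi] = g_nat[self.i_psi] * x[self.i_psi]
        g[self.sl_theta] = g_nat[self.sl_theta] * theta
        for m, (ja, jb) in enumerate(self.pair_idx):
            i_cov = self.sl_cov.start + m
            cov = x[i_cov]
            rho = np.tanh(t[i_cov])
            # theta_ab = rho * exp((t_a + t_b)/2): variance transforms pick
            # up half the covariance gradient each
            g[self.sl_theta.start + ja] += g_nat[i_cov] * cov / 2.0
            g[self.sl_theta.start + jb] += g_nat[i_cov] * cov / 2.0
            g[i_cov] = g_nat[i_cov] * np.sqrt(theta[ja] * theta[jb]) * (1.0 - rho**2)
        return g


def implied_moments(
    spec: ModelSpec, params: dict[str, float] | pd.Series, covariate_row: dict[str, float] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix at one covariate row.

    mean_j = nu_j + lambda_j (beta . x) + delta_j . x ;
    Cov = psi lambda lambda' + Theta.
    """
    par = _Parameterisation(spec)
    x = np.empty(par.n_free)
    for name, i in par.index.items():
        if name not in dict(params):
            raise ModelError(f"parameter {name!r} missing from params")
        x[i] = dict(params)[name]
    row = dict(covariate_row)
    missing = [c for c in par.covs if c not in row]
    if missing:
        raise ModelError(f"covariate row lacks {missing}")
    xv = np.array([row[c] for c in par.covs], dtype=float)
    nu, B = par.mean_matrix(x)
    return nu + B @ xv, par.sigma(x)


# ---------------------------------------------------------------------------
# Model / Results


class LatentFactorModel:
    """Maximum-likelihood latent-factor model of regional BP_ND.

    Parameters
    ----------
    data : prepared cohort frame (see :func:`prepare_design`) with
        ``bpnd_<region>`` outcome columns and the spec's covariates.
    spec : model structure.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.par = _Parameterisation(spec)
        missing = [r for r in spec.outcomes if f"bpnd_{r}" not in data.columns]
        if missing:
            raise ModelError(f"data lacks outcome columns for regions: {missing}")
        self.endog = data[[f"bpnd_{r}" for r in spec.outcomes]].to_numpy(float)
        cols = []
        for cov in self.par.covs:
            if ":" in cov:
                a, b = cov.split(":", 1)
                cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
            else:
                if cov not in data.columns:
                    raise ModelError(f"data lacks covariate column {cov!r}")
                cols.append(data[cov].to_numpy(float))
        self.exog = np.column_stack(cols) if cols else np.empty((len(data), 0))
        self.nobs = self.endog.shape[0]
        if self.nobs <= self.par.n_free:
            raise ModelError(
                f"n_subjects ({self.nobs}) must exceed the number of free parameters ({self.par.n_free})"
            )

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, spec: ModelSpec | None = None) -> "LatentFactorModel":
        """Build from a raw cohort table, applying :func:`prepare_design`."""
        return cls(prepare_design(cohort), spec or ModelSpec.final())

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        """Gaussian log-likelihood at a natural-scale parameter vector."""
        return self._loglike_score(np.asarray(params, float))[0]

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood (natural scale)."""
        return self._loglike_score(np.asarray(params, float))[1]

    def _loglike_score(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        par = self.par
        n, p = self.nobs, par.p
        nu, B = par.mean_matrix(x)
        sigma = par.sigma(x)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(par.n_free)
        resid = self.endog - nu[None, :] - self.exog @ B.T
        A = np.linalg.inv(sigma)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        S = resid.T @ resid
        ll = -0.5 * (n * (p * np.log(2 * np.pi) + logdet) + np.sum(A * S))

        _, lam, beta, _, psi, _, _ = par.unpack(x)
        G = 0.5 * (A @ S @ A - n * A)
        ARt = A @ resid.T  # p x n
        M = ARt @ self.exog  # p x K
        g = np.zeros(par.n_free)
        g[par.sl_nu] = ARt.sum(axis=1)
        if self.spec.latent:
            lp_cols = [par.cidx[c] for c in self.spec.latent_predictors]
            u = self.exog[:, lp_cols] @ beta if beta.size else np.zeros(n)
            g_lam_full = ARt @ u + 2.0 * psi * (G @ lam)
            g[par.sl_lam] = [g_lam_full[par.ridx[r]] for r in par.free_loadings]
            g[par.sl_beta] = [float(lam @ M[:, par.cidx[c]]) for c in self.spec.latent_predictors]
            g[par.i_psi] = float(lam @ G @ lam)
        g[par.sl_delta] = [M[par.ridx[r], par.cidx[c]] for c, r in self.spec.all_direct_paths]
        g[par.sl_theta] = np.diag(G)
        g[par.sl_cov] = [2.0 * G[ja, jb] for ja, jb in par.pair_idx]
        return float(ll), g

    # -- starting values ----------------------------------------------------
    def start_params(self) -> np.ndarray:
        par, spec = self.par, self.spec
        x = np.zeros(par.n_free)
        ybar = self.endog.mean(axis=0)
        S = np.cov(self.endog, rowvar=False)
        x[par.sl_nu] = ybar
        if spec.latent:
            jref = par.ridx[spec.reference_outcome]
            s_ref = max(S[jref, jref], 1e-4)
            lam0 = S[:, jref] / s_ref
            x[par.sl_lam] = [np.clip(lam0[par.ridx[r]], -5, 5) for r in par.free_loadings]
            psi0 = 0.5 * s_ref
            x[par.i_psi] = psi0
            theta0 = np.maximum(np.diag(S) - psi0 * lam0**2, 0.1 * np.diag(S))
        else:
            theta0 = np.maximum(np.diag(np.atleast_2d(S)), 1e-6)
        x[par.sl_theta] = np.maximum(theta0, 1e-6)
        # beta, delta, resid covs start at zero
        return x

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 2000,
        multistart: int = 5,
        gtol: float = 1e-8,
    ) -> "LatentFactorResults":
        """Maximise the likelihood (quasi-Newton on the transformed scale:
        log variances, atanh residual correlations), with jittered restarts
        on non-convergence; honest ``converged`` flag."""
        par = self.par
        x0 = np.asarray(start_params, float) if start_params is not None else self.start_params()

        def objective(t: np.ndarray):
            x = par.to_natural(t)
            ll, g = self._loglike_score(x)
            if not np.isfinite(ll):
                return 1e12, np.zeros(par.n_free)
            return -ll, -par.chain_gradient(t, g)

        rng = np.random.default_rng(12345)
        t0 = par.to_transformed(x0)
        best_x, best_ll, best_res, converged = None, -np.inf, None, False
        for attempt in range(max(1, multistart)):
            tstart = t0 if attempt == 0 else t0 + rng.normal(0.0, 0.1 * attempt, size=t0.size)
            res = optimize.minimize(
                objective,
                tstart,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-5},
            )
            xhat = self._newton_polish(par.to_natural(res.x))
            ll, grad = self._loglike_score(xhat)
            if ll > best_ll:
                best_x, best_ll, best_res = xhat, ll, res
            # relative gradient criterion after polishing
            if np.max(np.abs(grad)) < gtol * max(1.0, abs(ll)) * 1e4:
                best_x, best_ll, best_res, converged = xhat, ll, res, True
                break
        vcov, vcov_flag = self._vcov(best_x)
        return LatentFactorResults(self, best_x, best_ll, vcov, converged, vcov_flag, best_res)

    def _newton_polish(self, x: np.ndarray, max_steps: int = 20) -> np.ndarray:
        """Newton refinement on the natural scale so estimates reach
        near-machine precision (the quasi-Newton stage stops at a loose
        gradient tolerance)."""
        from scipy.linalg import cho_factor, cho_solve

        ll, grad = self._loglike_score(x)
        factor = None
        for k in range(max_steps):
            if factor is None or k % 6 == 5:  # reuse the factorisation near the optimum
                info = self._information(x)
                try:
                    factor = cho_factor(info)
                except (np.linalg.LinAlgError, ValueError):
                    return x
            direction = cho_solve(factor, grad)
            if not np.all(np.isfinite(direction)):
                return x
            step = 1.0
            for _ in range(8):
                ll_new, grad_new = self._loglike_score(x + step * direction)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                    break
                step /= 2.0
            else:
                return x
            x = x + step * direction
            ll, grad = ll_new, grad_new
            if np.max(np.abs(step * direction)) < 1e-11:
                break
        return x

    def _information(self, x: np.ndarray) -> np.ndarray:
        """Observed information: negative Hessian of the log-likelihood,
        by central differences of the analytic score (natural scale)."""
        k = self.par.n_free
        H = np.zeros((k, k))
        h = 1e-5 * (np.abs(x) + 1e-3)
        for i in range(k):
            xp = x.copy(); xp[i] += h[i]
            xm = x.copy(); xm[i] -= h[i]
            H[i] = (self.score(xp) - self.score(xm)) / (2 * h[i])
        return -0.5 * (H + H.T)

    def _vcov(self, xhat: np.ndarray) -> tuple[np.ndarray, str]:
        """Inverse observed information."""
        info = self._information(xhat)
        try:
            vcov = np.linalg.inv(info)
            if np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError
            return vcov, "observed"
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information not positive definite; standard errors use a pseudo-inverse",
                stacklevel=2,
            )
            vcov = np.linalg.pinv(info)
            return vcov, "pseudo-inverse"

    # -- saturated reference ------------------------------------------------
    def saturated_loglike(self) -> tuple[float, int]:
        """Closed-form ML of the saturated model: unrestricted linear mean
        of each region on the union of modelled covariates plus an
        unstructured covariance.  Returns (loglik, n_params)."""
        n, p = self.nobs, self.par.p
        X = np.column_stack([np.ones(n), self.exog])
        coef, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ coef
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise ModelError("saturated covariance is singular")
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
        n_params = p * X.shape[1] + p * (p + 1) // 2
        return float(ll), n_params


@dataclass(frozen=True)
class WaldTest:
    estimate: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class FitIndices:
    """Likelihood-ratio comparison against the saturated model plus RMSEA."""

    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    rmsea_n_convention: float = np.nan  # point estimate with n (not n-1) denominator


@dataclass(frozen=True)
class EffectDecomposition:
    """Direct, indirect (beta * lambda) and total covariate effect on one
    region, with a delta-method 95% CI for the total."""

    covariate: str
    region: str
    direct: float
    indirect: float
    total: float
    se_total: float
    ci95: tuple[float, float]


def lrt_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability of a likelihood-ratio statistic."""
    if df <= 0:
        raise ModelError("LRT p-value undefined for df <= 0")
    return float(stats.chi2.sf(chi2, df))


def rmsea(
    chi2: float, df: int, n: int, denominator: str = "n-1"
) -> tuple[float, tuple[float, float]]:
    """Root mean square error of approximation with a 90% CI.

    point = sqrt(max(chi2 - df, 0) / (df * d)), d = n-1 (default) or n;
    the CI inverts the noncentral chi-square in its noncentrality.
    """
    if df <= 0:
        raise ModelError("RMSEA undefined for df <= 0")
    if n <= 1:
        raise ModelError("RMSEA requires n > 1")
    d = float(n - 1 if denominator == "n-1" else n)
    point = np.sqrt(max(chi2 - df, 0.0) / (df * d))

    def _ncp(prob: float) -> float:
        # smallest ncp with P(X2_{df,ncp} <= chi2) = prob; 0 if unreachable
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - prob
        if f(1e-10) < 0:
            return 0.0
        hi = max(chi2 - df, 1.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e7:  # pragma: no cover
                break
        return float(optimize.brentq(f, 1e-10, hi))

    lo = np.sqrt(_ncp(0.95) / (df * d))
    hi = np.sqrt(_ncp(0.05) / (df * d))
    return float(point), (float(lo), float(hi))


def add_interaction(spec: ModelSpec, cov_a: str, cov_b: str) -> ModelSpec:
    """Append the product term ``cov_a:cov_b`` as a latent predictor."""
    for cov in (cov_a, cov_b):
        if cov not in spec.latent_predictors:
            raise ModelError(f"{cov!r} is not a latent predictor")
    name = f"{cov_a}:{cov_b}"
    alt = f"{cov_b}:{cov_a}"
    if name in spec.latent_predictors or alt in spec.latent_predictors:
        raise ModelError(f"interaction {name!r} already present")
    return replace(spec, latent_predictors=spec.latent_predictors + (name,))


class LatentFactorResults:
    """Fitted latent-factor model: estimates, uncertainty, diagnostics."""

    def __init__(self, model, params, loglik, vcov, converged, vcov_flag, opt_result=None):
        self.model = model
        self.spec = model.spec
        names = model.par.names
        self.params = pd.Series(np.asarray(params, float), index=names, name="estimate")
        self.loglik = float(loglik)
        self.vcov = pd.DataFrame(vcov, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.maximum(np.diag(vcov), 0.0)), index=names, name="se")
        self.converged = converged
        self.vcov_flag = vcov_flag
        self.opt_result = opt_result
        self.nobs = model.nobs
        self.n_params = model.par.n_free

    # -- inference ----------------------------------------------------------
    def wald_test(self, param_name: str) -> WaldTest:
        """Wald z-test for one free parameter (error for fixed ones, e.g.
        the reference loading)."""
        ref = self.spec.reference_outcome
        if param_name == f"lambda_{ref}":
            raise ModelError(f"loading of {ref!r} is fixed at 1 and carries no standard error")
        if param_name not in self.params.index:
            raise ModelError(f"unknown or fixed parameter {param_name!r}")
        est = float(self.params[param_name])
        se = float(self.bse[param_name])
        if se == 0 or not np.isfinite(se):
            raise ModelError(f"no usable standard error for {param_name!r}")
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        return WaldTest(est, se, float(z), float(p), (est - Z_95 * se, est + Z_95 * se))

    def fit_indices(self) -> FitIndices:
        """LRT against the saturated model and RMSEA (both conventions)."""
        ll_sat, k_sat = self.model.saturated_loglike()
        df = k_sat - self.n_params
        if df < 0:
            raise ModelError("model is not nested in the saturated model (more parameters)")
        chi2 = max(2.0 * (ll_sat - self.loglik), 0.0)
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        point, ci = rmsea(chi2, df, self.nobs) if df > 0 else (0.0, (0.0, 0.0))
        point_n = rmsea(chi2, df, self.nobs, denominator="n")[0] if df > 0 else 0.0
        return FitIndices(float(chi2), int(df), p, point, ci, point_n)

    def total_effect(self, covariate: str, region: str) -> EffectDecomposition:
        """Total = direct (delta) + indirect (beta * lambda) effect of a
        latent predictor on one region, delta-method CI for the total."""
        if region not in self.spec.outcomes:
            raise ModelError(f"unknown region {region!r}")
        if covariate not in self.spec.latent_predictors:
            raise ModelError(f"{covariate!r} does not predict the latent variable")
        b_name = f"beta_{covariate}"
        lam_name = f"lambda_{region}"
        d_name = f"delta_{covariate}__{region}"
        beta = float(self.params[b_name])
        lam = 1.0 if region == self.spec.reference_outcome else float(self.params[lam_name])
        direct = float(self.params[d_name]) if d_name in self.params.index else 0.0
        indirect = beta * lam
        total = direct + indirect
        # delta method: grad over the free params involved
        involved, grad = [b_name], [lam]
        if region != self.spec.reference_outcome:
            involved.append(lam_name); grad.append(beta)
        if d_name in self.params.index:
            involved.append(d_name); grad.append(1.0)
        g = np.array(grad)
        sub = self.vcov.loc[involved, involved].to_numpy()
        var = float(g @ sub @ g)
        se = float(np.sqrt(max(var, 0.0)))
        return EffectDecomposition(
            covariate, region, direct, indirect, total, se, (total - Z_95 * se, total + Z_95 * se)
        )

    # -- reporting ----------------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"estimate": self.params, "se": self.bse})
        frame["z"] = frame["estimate"] / frame["se"]
        frame["p"] = 2.0 * stats.norm.sf(np.abs(frame["z"]))
        frame["ci_low"] = frame["estimate"] - Z_95 * frame["se"]
        frame["ci_high"] = frame["estimate"] + Z_95 * frame["se"]
        return frame

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        lines = [
            f"Latent factor model of {len(self.spec.outcomes)} regional BP_ND outcomes",
            f"  latent: {self.spec.latent_name} (reference {self.spec.reference_outcome}, loading fixed at 1)",
            f"  n = {self.nobs}, free parameters = {self.n_params}, "
            f"log-likelihood = {self.loglik:.3f}, converged = {self.converged}",
            "",
            self.params_frame().to_string(float_format=lambda v: f"{v:10.4f}"),
        ]
        try:
            fi = self.fit_indices()
            lines += [
                "",
                f"  LRT vs saturated: chi2 = {fi.chi2:.1f}, df = {fi.df}, p = {fi.p_value:.3f}",
                f"  RMSEA = {fi.rmsea:.3f} (90% CI {fi.rmsea_ci90[0]:.3f}, {fi.rmsea_ci90[1]:.3f}) "
                f"[n-1 denominator; n convention: {fi.rmsea_n_convention:.3f}]",
            ]
        except ModelError:
            pass
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "estimates": {k: float(v) for k, v in self.params.items()},
            "ses": {k: float(v) for k, v in self.bse.items()},
            "vcov": self.vcov.to_numpy().tolist(),
            "param_names": list(self.params.index),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_subjects": self.nobs,
            "converged": self.converged,
            "vcov_flag": self.vcov_flag,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def params_csv(self, path: str | Path) -> None:
        self.params_frame().rename_axis("parameter").to_csv(path, float_format="%.10g")
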