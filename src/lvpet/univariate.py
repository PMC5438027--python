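"""Companion univariate analyses: per-region regressions, percent
differences, Holm family-wise correction, Hardy–Weinberg testing and
genotype balance checks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import REGIONS
from .sem import prepare_design

__all__ = [
    "RegionResult",
    "GenotypeCounts",
    "fit_region_ols",
    "percent_difference",
    "holm_adjust",
    "hwe_test",
    "balance_table",
    "univariate_table",
]

#: Covariates of every univariate regional regression; sex joins for caudate.
UNIVARIATE_COVARIATES = ("age", "pet_scanner", "mri_scanner")


@dataclass(frozen=True)
class RegionResult:
    """Genotype effect on one region from a univariate linear model."""

    region: str
    genotype: str
    estimate: float
    ci95: tuple[float, float]
    p: float
    intercept: float
    percent_diff: float
    p_fwe: float = np.nan


@dataclass(frozen=True)
class GenotypeCounts:
    """Biallelic genotype counts (major homozygote, heterozygote, minor)."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_AA + self.n_Aa + self.n_aa < 1:
            raise ValueError("need at least one genotyped subject")


def fit_region_ols(cohort: pd.DataFrame, region: str, genotype: str = "bdnf_group") -> RegionResult:
    """OLS of one region's BP_ND on a genotype dummy plus age, PET scanner
    and MRI scanner (and sex, for caudate only); t-based inference.

    ``cohort`` may be raw (design preparation is applied) and the genotype
    effect is reported with a 95% CI and the percent difference relative
    to the model intercept.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if genotype not in ("bdnf_group", "shttlpr_group"):
        raise ValueError("genotype must be 'bdnf_group' or 'shttlpr_group'")
    data = prepare_design(cohort)
    covs = list(UNIVARIATE_COVARIATES) + (["sex"] if region == "caudate" else [])
    X = sm.add_constant(data[[genotype] + covs])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        collinear = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear or list(X.columns)}")
    fit = sm.OLS(data[f"bpnd_{region}"], X).fit()
    est = float(fit.params[genotype])
    ci = fit.conf_int().loc[genotype]
    intercept = float(fit.params["const"])
    return RegionResult(
        region=region,
        genotype="BDNF" if genotype == "bdnf_group" else "5-HTTLPR",
        estimate=est,
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[genotype]),
        intercept=intercept,
        percent_diff=percent_difference(est, intercept),
    )


def percent_difference(estimate: float, intercept: float) -> float:
    """Effect as a percentage of the regression intercept (group mean of
    the reference level at covariate means): 100 * estimate / intercept."""
    if intercept == 0:
        raise ZeroDivisionError("percent difference undefined for zero intercept")
    return 100.0 * estimate / intercept


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down family-wise adjusted p-values.

    p_fwe_(i) = max_{j <= i} ( (m - j + 1) * p_(j) ), capped at 1,
    returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    idx = np.argsort(p, kind="stable")
    raw = p[idx] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(raw), 1.0)
    out = np.empty(m)
    out[idx] = adj
    return out


def hwe_test(counts: GenotypeCounts) -> tuple[float, int, float]:
    """Pearson chi-square test of Hardy–Weinberg proportions (df = 1,
    no continuity correction).

    The minor-allele frequency p is estimated from the counts and the
    observed genotype counts are compared with n*(q^2, 2pq, p^2).
    """
    n = counts.n_AA + counts.n_Aa + counts.n_aa
    p = (2 * counts.n_aa + counts.n_Aa) / (2 * n)
    q = 1.0 - p
    if p in (0.0, 1.0):
        warnings.warn("monomorphic sample: HWE chi-square defined as 0", stacklevel=2)
        return 0.0, 1, 1.0
    expected = n * np.array([q * q, 2 * p * q, p * p])
    observed = np.array([counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


#: Measures summarised in the demographic balance table.
BALANCE_CONTINUOUS = ("age", "bmi", "daylight", "injected_mass")
BALANCE_CATEGORICAL = ("sex", "pet_scanner", "mri_scanner")


def balance_table(cohort: pd.DataFrame, grouping: str = "bdnf_group") -> pd.DataFrame:
    """Group comparability check: Welch t-tests for continuous measures and
    chi-square tests for categorical ones, across genotype groups."""
    if grouping not in ("bdnf_group", "shttlpr_group"):
        raise ValueError("grouping must be 'bdnf_group' or 'shttlpr_group'")
    g0 = cohort[cohort[grouping] == 0]
    g1 = cohort[cohort[grouping] == 1]
    rows = []
    for measure in BALANCE_CONTINUOUS:
        if len(g0) < 2 or len(g1) < 2:
            rows.append({"measure": measure, "test": "t", "p": np.nan, "note": "group n < 2, skipped"})
            continue
        a, b = g0[measure].to_numpy(float), g1[measure].to_numpy(float)
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "measure": measure,
                "test": "t",
                "group0": f"{a.mean():.3g}±{a.std(ddof=1):.3g}",
                "group1": f"{b.mean():.3g}±{b.std(ddof=1):.3g}",
                "p": p,
            }
        )
    for measure in BALANCE_CATEGORICAL:
        table = pd.crosstab(cohort[grouping], cohort[measure])
        if table.shape != (2, 2) or (table.to_numpy() == 0).any():
            rows.append({"measure": measure, "test": "chi2", "p": np.nan, "note": "degenerate table, skipped"})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "measure": measure,
                "test": "chi2",
                "group0": f"{int(table.loc[0, 0])}/{int(table.loc[0, 1])}",
                "group1": f"{int(table.loc[1, 0])}/{int(table.loc[1, 1])}",
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def univariate_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-region genotype effects for both polymorphisms with Holm
    correction across the seven regions (one family per genotype)."""
    rows = []
    for genotype in ("bdnf_group", "shttlpr_group"):
        results = [fit_region_ols(cohort, region, genotype) for region in REGIONS]
        p_fwe = holm_adjust([r.p for r in results])
        for r, adj in zip(results, p_fwe):
            rows.append(
                {
                    "region": r.region,
                    "genotype": r.genotype,
                    "estimate": r.estimate,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "p": r.p,
                    "p_fwe": adj,
                    "percent_diff": r.percent_diff,
                    "subcortical": r.region != "neocortex",
                }
            )
    return pd.DataFrame(rows)
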