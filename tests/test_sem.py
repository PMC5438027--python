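import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from lvpet.cohort import (
    REGIONS,
    CohortConfig,
    GeneratingParameters,
    generate_bpnd,
    simulate_cohort,
)
from lvpet.sem import (
    LatentFactorModel,
    ModelError,
    ModelSpec,
    add_interaction,
    implied_moments,
    lrt_pvalue,
    prepare_design,
    rmsea,
)

from conftest import null_generating_parameters


class TestPrepareDesign:
    def test_age_centred_in_decades(self, cohort144):
        toy = cohort144.head(3).copy()
        toy["age"] = [20.0, 30.0, 40.0]
        out = prepare_design(toy)
        assert np.allclose(out["age"], [-1.0, 0.0, 1.0])

    def test_constant_age_centres_to_zero(self, cohort144):
        toy = cohort144.head(5).copy()
        toy["age"] = 33.0
        assert np.allclose(prepare_design(toy)["age"], 0.0)

    def test_dummy_mean_reflects_group_sizes(self, cohort144):
        """With the study's 92/52 split the BDNF dummy mean is 52/144."""
        toy = pd.concat([cohort144] * 2).head(144).copy().reset_index(drop=True)
        toy["bdnf_group"] = np.r_[np.zeros(92), np.ones(52)].astype(int)
        assert prepare_design(toy)["bdnf_group"].mean() == pytest.approx(52 / 144)

    def test_non_binary_dummy_rejected_with_values(self, cohort144):
        toy = cohort144.head(4).copy()
        toy["sex"] = [0, 1, 2, 0]
        with pytest.raises(ModelError, match="2"):
            prepare_design(toy)


class TestImpliedMoments:
    def test_forced_two_outcome_example(self):
        """lambda=(1, 0.5), psi=1, theta=diag(0.1, 0.2) imply
        Cov = [[1.1, 0.5], [0.5, 0.45]]."""
        spec = ModelSpec(
            outcomes=("thalamus", "caudate"),
            reference_outcome="thalamus",
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        params = {
            "nu_thalamus": 2.0,
            "nu_caudate": 1.5,
            "lambda_caudate": 0.5,
            "psi": 1.0,
            "theta_thalamus": 0.1,
            "theta_caudate": 0.2,
        }
        mean, cov = implied_moments(spec, params, {})
        assert np.allclose(mean, [2.0, 1.5])
        assert np.allclose(cov, [[1.1, 0.5], [0.5, 0.45]])

    def test_zero_psi_gives_theta(self):
        spec = ModelSpec(
            outcomes=("thalamus", "caudate"),
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        params = {
            "nu_thalamus": 0.0,
            "nu_caudate": 0.0,
            "lambda_caudate": 0.7,
            "psi": 0.0,
            "theta_thalamus": 0.3,
            "theta_caudate": 0.4,
        }
        _, cov = implied_moments(spec, params, {})
        assert np.allclose(cov, np.diag([0.3, 0.4]))

    def test_agrees_with_forward_simulator(self):
        """Implied moments match brute-force Monte-Carlo moments of the
        generator at a fixed covariate row."""
        gen = GeneratingParameters()
        spec = ModelSpec(
            latent_predictors=("bdnf_group", "shttlpr_group", "age"),
            direct_paths=(("bdnf_group", "neocortex"), ("sex", "caudate")),
            resid_cov_pairs=(("caudate", "putamen"), ("midbrain", "thalamus"), ("amygdala", "hippocampus")),
            mri_scanner_regions=("midbrain",),
        )
        params = {f"nu_{r}": gen.intercepts[r] for r in REGIONS}
        params |= {f"lambda_{r}": gen.loadings[r] for r in REGIONS if r != "thalamus"}
        params |= {f"beta_{c}": v for c, v in gen.latent_coeffs.items()}
        params |= {f"delta_{c}__{r}": v for (c, r), v in gen.direct_effects.items()}
        params |= {"psi": gen.latent_resid_var}
        params |= {f"theta_{r}": gen.resid_vars[r] for r in REGIONS}
        params |= {f"thetacov_{a}__{b}": v for (a, b), v in gen.resid_covs.items()}
        row = {c: 0.0 for c in spec.covariates}
        mean, cov = implied_moments(spec, params, row)
        assert np.allclose(cov, gen.implied_covariance())

        n = 40_000
        cfg = CohortConfig(n_subjects=n)
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "bdnf_genotype": "val/val",
                "bdnf_group": 0,
                "shttlpr_group": 0,
                "age": cfg.age_mean,
                "sex": 0,
                "pet_scanner": 0,
                "mri_scanner": 0,
                "bmi": cfg.bmi_mean,
                "daylight": cfg.daylight_mean,
                "injected_mass": cfg.injected_mass_mean,
            }
        )
        sim = generate_bpnd(subjects, gen, seed=17, config=cfg)
        y = sim[[f"bpnd_{r}" for r in REGIONS]].to_numpy()
        mc_mean, mc_cov = y.mean(axis=0), np.cov(y, rowvar=False)
        assert np.allclose(mc_mean, mean, atol=3.5 * np.sqrt(np.diag(cov) / n))
        se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n)
        assert np.all(np.abs(mc_cov - cov) < 3.5 * se)

    def test_missing_parameter_rejected(self):
        spec = ModelSpec(
            outcomes=("thalamus", "caudate"), pet_scanner_regions=(), mri_scanner_regions=()
        )
        with pytest.raises(ModelError, match="missing"):
            implied_moments(spec, {"nu_thalamus": 0.0}, {})


class TestLikelihood:
    def test_analytic_score_matches_numeric_gradient(self, prepared144):
        model = LatentFactorModel(prepared144, ModelSpec.final())
        x = model.start_params()
        # nudge away from the zero-initialised coefficients
        rng = np.random.default_rng(0)
        x = x + rng.normal(0.0, 0.01, size=x.size) * (np.abs(x) + 0.1)
        x[model.par.sl_theta] = np.abs(x[model.par.sl_theta])
        ll, g = model._loglike_score(x)
        num = np.empty_like(g)
        for i in range(x.size):
            h = 1e-6 * (abs(x[i]) + 1e-4)
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (model.loglike(xp) - model.loglike(xm)) / (2 * h)
        assert np.max(np.abs(g - num) / (1.0 + np.abs(num))) < 1e-3

    def test_adding_a_path_never_decreases_loglik(self, prepared144, final_fit):
        spec_plus = dataclasses.replace(
            ModelSpec.final(),
            direct_paths=ModelSpec.final().direct_paths + (("age", "caudate"),),
        )
        fit_plus = LatentFactorModel(prepared144, spec_plus).fit()
        assert fit_plus.loglik >= final_fit.loglik - 1e-6


class TestFitML:
    def test_single_outcome_reduces_to_ols(self, prepared144):
        """With one outcome and no latent variable the ML fit equals the
        closed-form least-squares solution to 1e-8."""
        spec = ModelSpec(
            outcomes=("thalamus",),
            latent=False,
            direct_paths=(("age", "thalamus"), ("sex", "thalamus"), ("bdnf_group", "thalamus")),
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        fit = LatentFactorModel(prepared144, spec).fit()
        X = sm.add_constant(prepared144[["age", "sex", "bdnf_group"]])
        ols = sm.OLS(prepared144["bpnd_thalamus"], X).fit()
        assert fit.params["nu_thalamus"] == pytest.approx(ols.params["const"], abs=1e-8)
        assert fit.params["delta_age__thalamus"] == pytest.approx(ols.params["age"], abs=1e-8)
        assert fit.params["delta_sex__thalamus"] == pytest.approx(ols.params["sex"], abs=1e-8)
        assert fit.params["delta_bdnf_group__thalamus"] == pytest.approx(
            ols.params["bdnf_group"], abs=1e-8
        )
        # ML residual variance uses n, not n - k
        assert fit.params["theta_thalamus"] == pytest.approx(
            ols.ssr / len(prepared144), abs=1e-8
        )

    def test_recovers_generating_parameters_at_large_n(self, big_cohort):
        """Every free parameter of the (correctly specified) final model is
        recovered within sampling error at n = 100,000."""
        gen = GeneratingParameters()
        fit = LatentFactorModel.from_cohort(big_cohort, ModelSpec.final())
        res = fit.fit()
        assert res.converged
        truth = {f"lambda_{r}": gen.loadings[r] for r in REGIONS if r != "thalamus"}
        truth |= {f"beta_{c}": v for c, v in gen.latent_coeffs.items()}
        truth |= {f"delta_{c}__{r}": v for (c, r), v in gen.direct_effects.items()}
        truth |= {"psi": gen.latent_resid_var}
        truth |= {f"theta_{r}": gen.resid_vars[r] for r in REGIONS}
        truth |= {f"thetacov_{a}__{b}": v for (a, b), v in gen.resid_covs.items()}
        # MRI scanner deltas outside midbrain are genuinely zero
        truth |= {
            f"delta_mri_scanner__{r}": 0.0 for r in REGIONS if ("mri_scanner", r) not in gen.direct_effects
        }
        for name, value in truth.items():
            est, se = res.params[name], res.bse[name]
            assert abs(est - value) < 3.5 * se, f"{name}: {est} vs {value} (se {se})"

    def test_too_few_subjects_rejected(self, prepared144):
        with pytest.raises(ModelError, match="exceed"):
            LatentFactorModel(prepared144.head(40), ModelSpec.final())

    def test_converged_flag_and_summary(self, final_fit):
        assert final_fit.converged
        text = final_fit.summary()
        assert "beta_bdnf_group" in text
        assert "RMSEA" in text


class TestWald:
    def test_consistent_with_normal_tail(self, final_fit):
        w = final_fit.wald_test("beta_bdnf_group")
        assert w.z == pytest.approx(w.estimate / w.se)
        assert w.p == pytest.approx(2 * stats.norm.sf(abs(w.z)))
        assert w.ci95[0] == pytest.approx(w.estimate - 1.959964 * w.se)
        assert w.ci95[1] == pytest.approx(w.estimate + 1.959964 * w.se)

    def test_fixed_reference_loading_rejected(self, final_fit):
        with pytest.raises(ModelError, match="fixed"):
            final_fit.wald_test("lambda_thalamus")

    def test_unknown_parameter_rejected(self, final_fit):
        with pytest.raises(ModelError):
            final_fit.wald_test("beta_nonexistent")


class TestLRT:
    def test_saturated_equivalent_model_gives_zero_chi2(self, prepared144):
        """A two-outcome model with free covariance is exactly as flexible
        as the saturated model."""
        spec = ModelSpec(
            outcomes=("caudate", "putamen"),
            latent=False,
            resid_cov_pairs=(("caudate", "putamen"),),
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        fit = LatentFactorModel(prepared144, spec).fit()
        fi = fit.fit_indices()
        assert fi.df == 0
        assert abs(fi.chi2) < 1e-6
        assert fi.p_value == 1.0

    def test_printed_statistic_tail_probability(self):
        assert lrt_pvalue(50.9, 34) == pytest.approx(0.0313, abs=5e-4)

    def test_two_outcome_chi2_matches_refit_oracle(self, prepared144):
        """Independence-model chi2 equals twice the gap between separately
        maximised log-likelihoods (closed-form normal MLEs)."""
        spec = ModelSpec(
            outcomes=("caudate", "putamen"),
            latent=False,
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        fit = LatentFactorModel(prepared144, spec).fit()
        fi = fit.fit_indices()
        y = prepared144[["bpnd_caudate", "bpnd_putamen"]].to_numpy()
        n = len(y)
        # brute force: independent normal MLE per outcome; saturated = bivariate MLE
        ll_indep = sum(
            -0.5 * n * (np.log(2 * np.pi) + np.log(np.var(col)) + 1) for col in y.T
        )
        s = np.cov(y, rowvar=False, ddof=0)
        ll_sat = -0.5 * n * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(s)) + 2)
        assert fi.chi2 == pytest.approx(2 * (ll_sat - ll_indep), abs=1e-5)
        assert fi.df == 1


class TestRmsea:
    def test_truncates_to_zero(self):
        point, _ = rmsea(10.0, 34, 144)
        assert point == 0.0

    def test_printed_fit_under_both_conventions(self):
        """Recomputation from (50.9, 34, 144) gives 0.059 with either the
        n-1 or the n denominator."""
        p1, ci = rmsea(50.9, 34, 144, denominator="n-1")
        p2, _ = rmsea(50.9, 34, 144, denominator="n")
        assert round(p1, 3) == 0.059
        assert round(p2, 3) == 0.059
        assert ci[0] < p1 < ci[1]

    def test_ci_brackets_point_when_chi2_exceeds_df(self):
        point, (lo, hi) = rmsea(60.0, 30, 200)
        assert lo <= point <= hi

    def test_zero_df_rejected(self):
        with pytest.raises(ModelError):
            rmsea(5.0, 0, 100)


class TestTotalEffect:
    def test_decomposition_identity(self, final_fit):
        eff = final_fit.total_effect("bdnf_group", "neocortex")
        assert eff.total == eff.direct + eff.indirect
        assert eff.indirect == pytest.approx(
            final_fit.params["beta_bdnf_group"] * final_fit.params["lambda_neocortex"]
        )
        assert eff.direct == pytest.approx(final_fit.params["delta_bdnf_group__neocortex"])

    def test_no_direct_path_contributes_zero_direct(self, final_fit):
        eff = final_fit.total_effect("bdnf_group", "caudate")
        assert eff.direct == 0.0
        assert eff.total == eff.indirect

    def test_reference_region_effect_is_latent_coefficient(self, final_fit):
        eff = final_fit.total_effect("bdnf_group", "thalamus")
        assert eff.total == pytest.approx(final_fit.params["beta_bdnf_group"])

    def test_unknown_region_rejected(self, final_fit):
        with pytest.raises(ModelError):
            final_fit.total_effect("bdnf_group", "cerebellum")

    def test_delta_method_matches_parametric_bootstrap(self):
        """Delta-method variance of the total effect agrees with a
        parametric bootstrap from the fitted model."""
        spec = ModelSpec(
            outcomes=("thalamus", "caudate", "neocortex"),
            latent_predictors=("bdnf_group",),
            direct_paths=(("bdnf_group", "neocortex"),),
            pet_scanner_regions=(),
            mri_scanner_regions=(),
        )
        cohort = simulate_cohort(CohortConfig(n_subjects=400, seed=21))
        data = prepare_design(cohort)
        fit = LatentFactorModel(data, spec).fit()
        eff = fit.total_effect("bdnf_group", "neocortex")

        par = fit.model.par
        xhat = fit.params.to_numpy()
        nu, B = par.mean_matrix(xhat)
        sigma = par.sigma(xhat)
        X = fit.model.exog
        mu = nu[None, :] + X @ B.T
        chol = np.linalg.cholesky(sigma)
        rng = np.random.default_rng(5)
        totals = []
        for _ in range(300):
            yb = mu + rng.standard_normal(mu.shape) @ chol.T
            boot = data.copy()
            for j, region in enumerate(spec.outcomes):
                boot[f"bpnd_{region}"] = yb[:, j]
            bfit = LatentFactorModel(boot, spec).fit(start_params=xhat, multistart=1)
            totals.append(bfit.total_effect("bdnf_group", "neocortex").total)
        boot_var = np.var(totals, ddof=1)
        assert abs(boot_var / eff.se_total**2 - 1.0) < 0.30


class TestInteraction:
    def test_product_term_appended(self):
        spec = add_interaction(ModelSpec.final(), "bdnf_group", "shttlpr_group")
        assert "bdnf_group:shttlpr_group" in spec.latent_predictors

    def test_duplicate_rejected(self):
        spec = add_interaction(ModelSpec.final(), "bdnf_group", "shttlpr_group")
        with pytest.raises(ModelError, match="already"):
            add_interaction(spec, "shttlpr_group", "bdnf_group")

    def test_non_latent_predictor_rejected(self):
        with pytest.raises(ModelError):
            add_interaction(ModelSpec.final(), "bdnf_group", "bmi")

    def test_fit_and_wald_work_downstream(self, prepared144):
        spec = add_interaction(ModelSpec.final(), "bdnf_group", "shttlpr_group")
        fit = LatentFactorModel(prepared144, spec).fit()
        w = fit.wald_test("beta_bdnf_group:shttlpr_group")
        assert 0.0 <= w.p <= 1.0

    def test_power_exceeds_type_i_rate(self):
        """With a true genotype-by-genotype interaction of 0.15 the Wald
        rejection rate at n=144 exceeds the rate under the null."""
        spec = add_interaction(ModelSpec.final(), "bdnf_group", "shttlpr_group")
        name = "beta_bdnf_group:shttlpr_group"

        def rejection_rate(gen, seed0, nsim=50):
            hits = 0
            for s in range(nsim):
                cohort = simulate_cohort(CohortConfig(seed=seed0 + s), gen)
                fit = LatentFactorModel.from_cohort(cohort, spec).fit()
                hits += fit.wald_test(name).p < 0.05
            return hits / nsim

        base = GeneratingParameters()
        with_int = dataclasses.replace(
            base,
            latent_coeffs={**base.latent_coeffs, "bdnf_group:shttlpr_group": 0.15},
        )
        assert rejection_rate(with_int, 3000) > rejection_rate(base, 4000)
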