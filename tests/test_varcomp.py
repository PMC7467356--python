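"""Random-intercept REML fit and the variance decomposition."""

import numpy as np
import pandas as pd
import pytest

import igglycome as ig
from igglycome.simulate import simulate_variance_benchmark
from igglycome.varcomp import (TraitVarianceModel, decompose_variance,
                               fit_lmm_reml)


@pytest.fixture(scope="module")
def benchmark_fit():
    df, truth = simulate_variance_benchmark(seed=42)
    res = TraitVarianceModel.from_dataframe(df, "y").fit()
    return df, truth, res


class TestRemlFit:
    def test_boundary_fit_equals_ols(self):
        df, _ = simulate_variance_benchmark(seed=1, country_share=0.0,
                                            n_countries=5, n_per_country=50)
        model = TraitVarianceModel.from_dataframe(df, "y")
        beta_gls, _, _ = model._gls(0.0)
        beta_ols, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
        assert np.max(np.abs(beta_gls - beta_ols)) < 1e-10

    def test_zero_country_variance_estimated_near_zero(self):
        lams = []
        for seed in range(5):
            df, _ = simulate_variance_benchmark(seed=seed, country_share=0.0,
                                                n_countries=8, n_per_country=60)
            res = TraitVarianceModel.from_dataframe(df, "y").fit()
            lams.append(res.lam)
        assert np.median(lams) < 0.01

    def test_balanced_anova_closed_form(self, rng):
        """Textbook one-way ANOVA variance components, balanced design."""
        J, m = 6, 30
        u = rng.normal(0, 2.0, J)
        y = np.repeat(u, m) + rng.normal(0, 1.0, J * m)
        country = np.repeat([f"c{j}" for j in range(J)], m)
        res = TraitVarianceModel(y, None, None, country).fit()
        ybar = y.reshape(J, m).mean(axis=1)
        msb = m * np.sum((ybar - y.mean()) ** 2) / (J - 1)
        msw = np.sum((y.reshape(J, m) - ybar[:, None]) ** 2) / (J * (m - 1))
        assert res.sigma2_resid == pytest.approx(msw, rel=1e-6)
        assert res.sigma2_country == pytest.approx((msb - msw) / m, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self, benchmark_fit):
        smf = pytest.importorskip("statsmodels.formula.api")
        df, _, res = benchmark_fit
        sm_fit = smf.mixedlm("y ~ age + C(sex)", df,
                             groups=df["country"]).fit(reml=True)
        assert res.sigma2_country == pytest.approx(sm_fit.cov_re.iloc[0, 0],
                                                   rel=1e-2)
        assert res.sigma2_resid == pytest.approx(sm_fit.scale, rel=1e-3)
        assert res.fe_params["age"] == pytest.approx(
            sm_fit.fe_params["age"], abs=1e-5)

    def test_recovers_realized_truth(self, benchmark_fit):
        _, truth, res = benchmark_fit
        real = truth["realized"]
        assert res.sigma2_country == pytest.approx(real["sigma2_country"],
                                                   rel=0.15)
        assert res.sigma2_resid == pytest.approx(real["sigma2_resid"], rel=0.05)

    def test_collinear_design_rejected(self, rng):
        y = rng.normal(0, 1, 40)
        age = np.full(40, 50.0)  # constant age column is collinear with intercept
        country = np.repeat(["a", "b"], 20)
        with pytest.raises(ValueError, match="collinear"):
            TraitVarianceModel(y, age, None, country)

    def test_single_country_rejected(self, rng):
        with pytest.raises(ValueError, match="countries"):
            TraitVarianceModel(rng.normal(0, 1, 20), None, None, ["x"] * 20)


class TestVarianceExplained:
    def test_null_model_all_shares_near_zero(self, rng):
        n = 2000
        df = pd.DataFrame({
            "y": rng.normal(0, 1, n),
            "age": rng.uniform(18, 70, n),
            "sex": rng.choice(["F", "M"], n),
            "country": rng.choice([f"c{j}" for j in range(10)], n),
        })
        ve = TraitVarianceModel.from_dataframe(df, "y").fit().variance_explained()
        assert ve["age"] < 0.5
        assert ve["sex"] < 0.5
        assert ve["country"] < 1.5

    def test_age_dominated_signal_recovered(self):
        """Roughly a third of variance from age alone."""
        df, truth = simulate_variance_benchmark(
            seed=3, country_share=0.02, age_share=0.31, sex_share=0.0)
        ve = TraitVarianceModel.from_dataframe(df, "y").fit().variance_explained()
        # one seed: the fitted age slope carries sampling noise of a few
        # percent, which enters the share quadratically
        assert ve["age"] == pytest.approx(truth["realized"]["age_share_pct"],
                                          abs=3.0)

    def test_accounting_identity(self, benchmark_fit):
        _, _, res = benchmark_fit
        ve = res.variance_explained()
        total = ve["fixed_total"] + ve["country"] + ve["residual"]
        assert total == pytest.approx(100.0, abs=1e-9)
        parts = ve["age"] + ve["sex"] + ve["fixed_covariance"]
        assert parts == pytest.approx(ve["fixed_total"], abs=1e-9)

    def test_invariance_to_sex_coding_and_age_centering(self, benchmark_fit):
        df, _, res = benchmark_fit
        ve = res.variance_explained()
        recoded = df.copy()
        recoded["sex"] = recoded["sex"].map({"F": "zF", "M": "aM"})  # flip order
        recoded["age"] = recoded["age"] - recoded["age"].mean()
        ve2 = TraitVarianceModel.from_dataframe(
            recoded, "y").fit().variance_explained()
        for key in ("age", "sex", "country", "residual"):
            # exact in theory; the profiled lambda re-optimizes to within
            # its numerical tolerance under the reparametrization
            assert ve2[key] == pytest.approx(ve[key], abs=1e-3)

    def test_mean_bias_under_one_point_over_seed_grid(self):
        biases = []
        for seed in range(60):
            df, truth = simulate_variance_benchmark(seed=seed)
            res = TraitVarianceModel.from_dataframe(df, "y").fit()
            est = res.variance_explained()["country"]
            biases.append(est - truth["realized"]["country_share_pct"])
        assert abs(np.mean(biases)) < 1.0


class TestLrt:
    def test_huge_country_effect_detected(self):
        df, _ = simulate_variance_benchmark(seed=5, country_share=0.5)
        res = TraitVarianceModel.from_dataframe(df, "y").fit()
        assert res.lrt_random_effect()["pvalue"] < 1e-10

    def test_null_calibration_uniform_or_conservative(self):
        pvals = []
        for seed in range(300):
            df, _ = simulate_variance_benchmark(
                seed=10_000 + seed, country_share=0.0,
                n_countries=6, n_per_country=25)
            res = TraitVarianceModel.from_dataframe(df, "y").fit()
            pvals.append(res.lrt_random_effect()["pvalue"])
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert (pvals < alpha).mean() <= alpha + 0.03

    def test_boundary_mixture_halves_p(self):
        df, _ = simulate_variance_benchmark(seed=6, country_share=0.1,
                                            n_countries=8, n_per_country=40)
        res = TraitVarianceModel.from_dataframe(df, "y").fit()
        default = res.lrt_random_effect(boundary_mixture=False)
        mixture = res.lrt_random_effect(boundary_mixture=True)
        assert default["statistic"] > 0
        assert mixture["pvalue"] == pytest.approx(default["pvalue"] / 2.0)


class TestTableOutput:
    def test_decomposition_table_shape(self, medium_cohort):
        traits = ig.derive_fc_traits(
            pd.concat(medium_cohort.compositions, axis=1))
        table = decompose_variance(traits, medium_cohort.metadata)
        assert len(table) == 15  # 3 subclasses x 5 traits
        assert set(table["subclass"]) == {"IgG1", "IgG2", "IgG4"}
        assert ((table["country_pct"] >= 0) & (table["country_pct"] <= 100)).all()
        assert (table["lrt_pvalue"] <= 1).all()

    def test_summary_renders(self, benchmark_fit):
        _, _, res = benchmark_fit
        text = res.summary()
        assert "sigma2 country" in text
        assert "Variance explained" in text
        assert "LRT" in text

    def test_functional_wrapper(self):
        df, _ = simulate_variance_benchmark(seed=8, n_countries=5,
                                            n_per_country=40)
        res = fit_lmm_reml(df["y"], df["age"], df["sex"], df["country"])
        assert res.sigma2_resid > 0
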