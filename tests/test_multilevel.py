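import itertools

import numpy as np
import pandas as pd
import pytest

from agemeta import (
    ModelSpec,
    build_sampling_covariance,
    cochran_q,
    fit_reml,
    influence_analysis,
    rho_sensitivity,
    subgroup_fit,
)
from agemeta.model import SingularDesignError, _restricted_loglik, _study_indicator, design_matrix
from agemeta.simulate import SimConfig, generate

from conftest import make_frame
from agemeta import from_dataframe


class TestSamplingCovariance:
    def test_rho_zero_is_diagonal(self, small_dataset):
        V = build_sampling_covariance(small_dataset, 0.0)
        assert np.allclose(V, np.diag(small_dataset.v))

    def test_hand_computed_off_diagonal(self, dataset_factory):
        ds = dataset_factory([
            ("e1", "s1", 0.1, 0.04, 50, 2000),
            ("e2", "s1", 0.2, 0.01, 50, 2000),
        ])
        V = build_sampling_covariance(ds, 0.5)
        assert V[0, 1] == pytest.approx(0.5 * 0.2 * 0.1, abs=1e-15)
        assert V[0, 0] == pytest.approx(0.04)

    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    def test_positive_definite_for_random_datasets(self, rho):
        ds = generate(SimConfig(seed=3, s=8, estimates_per_study=4))
        V = build_sampling_covariance(ds, rho)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_rejects_rho_outside_range(self, small_dataset):
        for rho in (-0.1, 1.0):
            with pytest.raises(ValueError):
                build_sampling_covariance(small_dataset, rho)


class TestREML:
    def test_single_estimate_identity(self, dataset_factory):
        ds = dataset_factory([("e1", "s1", 0.37, 0.02, 40, 2001)])
        f = fit_reml(ds)
        assert f.pooled_r == pytest.approx(0.37)
        assert f.tau2_study == 0.0 and f.sigma2_estimate == 0.0
        assert f.Q == 0.0 and f.Q_df == 0

    @pytest.mark.parametrize(
        "r1, r2, v", [(0.5, -0.1, 0.02), (0.3, 0.31, 0.05), (0.8, -0.8, 0.001)]
    )
    def test_two_study_equal_variance_closed_form(self, dataset_factory, r1, r2, v):
        """Equal-variance two-study REML: pooled = mean, total heterogeneity
        = max(0, (r1-r2)^2/2 - v)."""
        ds = dataset_factory([
            ("e1", "s1", r1, v, 50, 2000),
            ("e2", "s2", r2, v, 50, 2005),
        ])
        f = fit_reml(ds, robust=False)
        assert f.pooled_r == pytest.approx((r1 + r2) / 2, abs=1e-10)
        expect_het = max(0.0, (r1 - r2) ** 2 / 2 - v)
        assert f.tau2_study + f.sigma2_estimate == pytest.approx(expect_het, abs=1e-10)

    def test_matches_independent_multilevel_oracle(self, small_dataset):
        """Frozen expected values computed with metafor::rma.mv (R), the
        reference multilevel meta-analysis implementation, on this fixture."""
        f = fit_reml(small_dataset, ModelSpec(rho=0.5))
        assert f.pooled_r == pytest.approx(0.047503582143, abs=1e-6)
        assert f.se_model[0] == pytest.approx(0.109872449360, abs=1e-6)
        assert f.tau2_study == pytest.approx(0.023018228910, abs=1e-6)
        assert f.sigma2_estimate == pytest.approx(0.010926026873, abs=1e-6)
        assert f.Q == pytest.approx(23.373857849636, abs=1e-6)
        assert f.Q_p == pytest.approx(0.001466905994, abs=1e-8)
        assert f.Q_df == 7

    def test_meta_regression_matches_oracle(self, small_dataset):
        """metafor::rma.mv with a continuous moderator; residual estimate-level
        variance collapses to the boundary on this fixture."""
        f = fit_reml(small_dataset, ModelSpec(rho=0.5, moderators=("age_span_decades",)))
        assert f.beta[0] == pytest.approx(-0.3083909, abs=1e-6)
        assert f.beta[1] == pytest.approx(0.08933315, abs=1e-6)
        assert f.se_model[0] == pytest.approx(0.134907, abs=1e-5)
        assert f.se_model[1] == pytest.approx(0.02625313, abs=1e-6)
        assert f.tau2_study == pytest.approx(0.01483242, abs=1e-6)
        assert f.sigma2_estimate == pytest.approx(0.0, abs=1e-7)
        assert f.Q == pytest.approx(7.61993, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimizer_matches_grid_search_oracle(self, seed):
        """For small k the REML optimum must match a dense grid +
        derivative-free polish of the same objective to 1e-6 in loglik."""
        ds = generate(SimConfig(seed=seed, s=4, estimates_per_study=3,
                                mu=0.1, tau2_study=0.03, sigma2_estimate=0.02))
        assert ds.k <= 12
        f = fit_reml(ds, robust=False)
        y, X = ds.y, np.ones((ds.k, 1))
        V = build_sampling_covariance(ds, 0.5)
        Z = _study_indicator(ds)
        ZZt = Z @ Z.T
        grid = np.linspace(0, 0.2, 81)
        best, best_theta = -np.inf, None
        for t2, s2 in itertools.product(grid, grid):
            ll, _, _ = _restricted_loglik((t2, s2), y, X, V, ZZt)
            if ll > best:
                best, best_theta = ll, (t2, s2)
        from scipy.optimize import minimize
        res = minimize(
            lambda th: -_restricted_loglik(np.maximum(th, 0), y, X, V, ZZt)[0],
            best_theta, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 5000},
        )
        assert f.reml_loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_rank_deficient_moderators_rejected(self, small_dataset):
        ds = small_dataset.subset(slice(None))
        ds.df["copy"] = ds.df["age_span_decades"]
        with pytest.raises(SingularDesignError):
            fit_reml(ds, ModelSpec(moderators=("age_span_decades", "copy")))


class TestRobustInference:
    def test_two_study_worked_example_wide_interval(self, dataset_factory):
        """Two wildly disagreeing single-estimate studies: CR2/Satterthwaite
        yields df = 1 and a t interval two orders wider than the estimate."""
        ds = dataset_factory([
            ("e1", "s1", -0.72, 0.22**2, 20, 1994),
            ("e2", "s2", 0.30, 0.07**2, 100, 2002),
        ])
        f = fit_reml(ds)
        assert f.robust_available
        assert f.df_robust[0] == pytest.approx(1.0, abs=1e-8)
        assert f.pooled_r == pytest.approx(-0.19, abs=0.005)
        assert f.ci95_robust[0][0] == pytest.approx(-6.66, abs=0.01)
        assert f.ci95_robust[0][1] == pytest.approx(6.28, abs=0.01)
        assert any("df < 4" in w for w in f.warnings)

    def test_robust_approaches_model_se_with_many_clusters(self):
        """Correctly specified homoscedastic clusters: sandwich and model SEs
        converge as the number of studies grows."""
        rng = np.random.default_rng(11)
        rows = []
        for j in range(200):
            r = float(np.clip(0.1 + rng.normal(0, np.sqrt(0.02 + 0.01)), -0.95, 0.95))
            rows.append((f"e{j}", f"s{j:03d}", r, 0.01, 100, 2000 + j % 20))
        ds = from_dataframe(make_frame(rows))
        f = fit_reml(ds)
        assert f.se_robust[0] / f.se_model[0] == pytest.approx(1.0, abs=0.1)

    def test_robust_covariance_symmetric_psd(self, small_dataset):
        f = fit_reml(small_dataset, ModelSpec(rho=0.5, moderators=("age_span_decades",)))
        V = f.vcov_robust
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-12

    def test_single_study_refused(self, dataset_factory):
        ds = dataset_factory([
            ("e1", "s1", 0.1, 0.01, 50, 2000),
            ("e2", "s1", 0.2, 0.02, 50, 2000),
        ])
        f = fit_reml(ds)
        assert not f.robust_available
        assert any("single study" in w for w in f.warnings)


class TestCochranQ:
    def test_identical_effects_give_zero_q(self, dataset_factory):
        ds = dataset_factory([
            ("e1", "s1", 0.2, 0.01, 50, 2000),
            ("e2", "s2", 0.2, 0.02, 50, 2001),
            ("e3", "s3", 0.2, 0.015, 50, 2002),
        ])
        Q, df, p = cochran_q(ds)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_null_distribution_mean(self):
        """Under homogeneity with independent errors, Q ~ chi2(k-1)."""
        rng = np.random.default_rng(7)
        k = 10
        qs = []
        for _ in range(800):
            v = rng.uniform(0.005, 0.05, k)
            y = rng.normal(0, np.sqrt(v))
            rows = [(f"e{i}", f"s{i}", float(np.clip(y[i], -0.99, 0.99)),
                     float(v[i]), 50, 2000 + i) for i in range(k)]
            ds = from_dataframe(make_frame(rows))
            qs.append(cochran_q(ds, ModelSpec(rho=0.0))[0])
        assert np.mean(qs) == pytest.approx(k - 1, rel=0.05)

    def test_fixed_effects_estimate_invariant_to_variance_scaling(self, small_dataset):
        """With variance components at zero, inflating every var_r by a common
        factor leaves the GLS point estimate unchanged."""
        X = np.ones((small_dataset.k, 1))
        y = small_dataset.y

        def gls_beta(scale):
            V = build_sampling_covariance(small_dataset, 0.5) * scale
            W = np.linalg.inv(V)
            return float(np.linalg.solve(X.T @ W @ X, X.T @ W @ y).item())

        assert gls_beta(1.0) == pytest.approx(gls_beta(7.3), abs=1e-12)


class TestInfluence:
    def test_planted_outlier_study_has_largest_delta(self):
        rng = np.random.default_rng(5)
        rows = [(f"e{j}", f"s{j:02d}", float(rng.normal(0, 0.03)), 0.01, 80, 2000 + j)
                for j in range(8)]
        rows.append(("out", "s_out", 0.8, 0.01, 80, 2010))
        ds = from_dataframe(make_frame(rows))
        table = influence_analysis(ds)
        assert len(table) == ds.s
        worst = table.loc[table["delta"].abs().idxmax(), "omitted_study_id"]
        assert worst == "s_out"

    def test_refused_below_three_studies(self, dataset_factory):
        ds = dataset_factory([
            ("e1", "s1", 0.1, 0.01, 50, 2000),
            ("e2", "s2", 0.2, 0.02, 50, 2001),
        ])
        with pytest.raises(ValueError, match="3 studies"):
            influence_analysis(ds)


class TestSubgroups:
    def test_equivalent_to_separate_fits_on_disjoint_studies(self):
        ds = generate(SimConfig(seed=9, s=8, estimates_per_study=2, mu=0.1))
        ds.df["grp"] = np.where(ds.df["study_id"] < "study_004", "a", "b")
        fits = subgroup_fit(ds, "grp")
        for level in ("a", "b"):
            direct = fit_reml(ds.subset(ds.df["grp"] == level))
            assert fits[level].pooled_r == pytest.approx(direct.pooled_r, abs=1e-10)
            assert fits[level].tau2_study == pytest.approx(direct.tau2_study, abs=1e-10)

    def test_singleton_level_skipped_with_warning(self, dataset_factory):
        ds = dataset_factory([
            ("e1", "s1", 0.1, 0.01, 50, 2000),
            ("e2", "s2", 0.2, 0.02, 50, 2001),
            ("e3", "s3", 0.0, 0.02, 50, 2002),
        ], domain=["gain", "gain", "loss"])
        with pytest.warns(UserWarning, match="loss"):
            fits = subgroup_fit(ds, "domain")
        assert set(fits) == {"gain"}

    def test_subgroups_differ_from_shared_heterogeneity_metaregression(self):
        """When true heterogeneity differs by level, per-level fits and a
        meta-regression with a shared residual variance disagree."""
        a = generate(SimConfig(seed=1, s=10, estimates_per_study=2, mu=0.0,
                               tau2_study=0.0, sigma2_estimate=0.0))
        b = generate(SimConfig(seed=2, s=10, estimates_per_study=2, mu=0.3,
                               tau2_study=0.08, sigma2_estimate=0.02))
        b.df["study_id"] = "x_" + b.df["study_id"]
        b.df["record_id"] = "x_" + b.df["record_id"]
        b.df["estimate_id"] = "x_" + b.df["estimate_id"]
        df = pd.concat([a.df, b.df], ignore_index=True)
        df["domain"] = np.where(df["study_id"].str.startswith("x_"), "loss", "gain")
        ds = from_dataframe(df)
        sub = subgroup_fit(ds, "domain")
        mr = fit_reml(ds, ModelSpec(moderators=("domain",)))
        pooled_loss_mr = mr.beta[0] + mr.beta[1]
        # point estimates may be close; the variance structure must differ
        assert sub["gain"].tau2_study + sub["gain"].sigma2_estimate < \
            sub["loss"].tau2_study + sub["loss"].sigma2_estimate
        assert abs(pooled_loss_mr - sub["loss"].pooled_r) > 1e-6


def test_rho_sensitivity_is_continuous(small_dataset):
    table = rho_sensitivity(small_dataset)
    assert len(table) == 9
    steps = np.abs(np.diff(table["pooled_r"].to_numpy()))
    assert steps.max() < 0.05  # no jumps across neighbouring rho values
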