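"""Censored-regression stage: MLE oracles, recovery, Wald and VIF checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from hospeff import (
    MODEL_SETS,
    Tobit,
    compare_models,
    load_fixture,
    transform_scores,
    vif,
)
from hospeff.simulate import SyntheticConfig, generate_tobit_panel
from hospeff.tobit import RankDeficientError


def _simulate_pooled(n, beta, sigma, rng, censor=True):
    X = np.column_stack([rng.normal(0, 1, (n, len(beta) - 1)), np.ones(n)])
    latent = X @ beta + rng.normal(0, sigma, n)
    y = np.maximum(latent, 0.0) if censor else latent
    return y, X


class TestTransform:
    def test_boundary_and_arithmetic(self):
        out = transform_scores([1.0, 0.5, 0.7252])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)
        # consistent with the reciprocal formulation: 1/0.7252 = 1.3789
        assert out[2] == pytest.approx(0.3789, abs=5e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transform_scores([0.0, 0.5])
        with pytest.raises(ValueError):
            transform_scores([1.2])
        # LP round-off just above 1 is censored, not an error
        assert transform_scores([1.0 + 1e-12])[0] == 0.0

    def test_censoring_monotone_in_threshold(self, rng):
        latent = rng.normal(0.3, 0.5, 500)
        counts = [(np.maximum(latent - c, 0) > 0).sum() for c in (0.0, 0.2, 0.4)]
        assert counts == sorted(counts, reverse=True)


class TestPooledTobit:
    def test_reduces_to_least_squares_without_censoring(self, rng):
        beta = np.array([0.5, -0.3, 1.0])
        y, X = _simulate_pooled(400, beta, 0.4, rng, censor=False)
        y = y - y.min() + 0.1  # strictly positive: no censored rows
        fit = Tobit(y, X, ["a", "b", "const"]).fit(random_effects=False)
        ols = sm.OLS(y, X).fit()
        assert np.abs(fit.params.to_numpy() - ols.params).max() < 1e-4
        sigma_mle = np.sqrt(np.mean(ols.resid**2))
        assert fit.sigma_e == pytest.approx(sigma_mle, abs=1e-4)

    def test_intercept_only_matches_grid_oracle(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.ones((4, 1))
        fit = Tobit(y, X, ["const"]).fit(random_effects=False)
        # brute-force the two-parameter likelihood on a fine grid
        mus = np.linspace(-1.0, 2.0, 601)
        sigmas = np.linspace(0.05, 3.0, 600)
        best, arg = -np.inf, None
        for mu, s in itertools.product(mus, sigmas):
            ll = 2 * stats.norm.logcdf(-mu / s) + np.sum(
                stats.norm.logpdf((np.array([1.0, 1.0]) - mu) / s) - np.log(s)
            )
            if ll > best:
                best, arg = ll, (mu, s)
        assert fit.params["const"] == pytest.approx(arg[0], abs=1e-2)
        assert fit.sigma_e == pytest.approx(arg[1], abs=1e-2)
        assert fit.llf >= best - 1e-3  # MLE at least as good as grid optimum

    def test_simulation_recovery_within_3_se(self, rng):
        beta = np.array([0.4, -0.25, 0.3])  # ~30% censoring at sigma 0.5
        y, X = _simulate_pooled(2000, beta, 0.5, rng)
        assert 0.2 < np.mean(y == 0) < 0.45
        fit = Tobit(y, X, ["a", "b", "const"]).fit(random_effects=False)
        err = np.abs(fit.params.to_numpy() - beta)
        assert (err < 3 * fit.bse.to_numpy()).all()

    def test_loglik_improves_on_start(self, rng):
        beta = np.array([0.3, 0.2])
        y, X = _simulate_pooled(300, beta, 0.4, rng)
        model = Tobit(y, X, ["a", "const"])
        start = model._start_params(False)
        fit = model.fit(random_effects=False)
        assert fit.llf >= model.loglike_pooled(start) - 1e-10

    def test_all_censored_is_degenerate(self):
        with pytest.raises(ValueError, match="censored"):
            Tobit(np.zeros(10), np.ones((10, 1)))

    def test_rank_deficiency_names_columns(self, rng):
        X = np.column_stack([np.ones(50), np.ones(50)])
        y = np.abs(rng.normal(1, 1, 50))
        with pytest.raises(RankDeficientError):
            Tobit(y, X, ["c1", "c2"])


class TestRandomEffectsTobit:
    def test_sigma_u_zero_limit_equals_pooled(self):
        cfg = SyntheticConfig(seed=3, sigma_u=0.0, n_dmus=25, n_years=4)
        df, _ = generate_tobit_panel(cfg)
        covs = ["Z1", "Z3", "Z5"]
        model = Tobit.from_dataframe(df, covariates=covs)
        pooled = model.fit(random_effects=False)
        # constrain sigma_u ~ 0 in the RE likelihood: coefficients must agree
        params_re = np.concatenate([pooled._params, [np.log(1e-8)]])
        ll_re = model.loglike_re(params_re)
        assert ll_re == pytest.approx(pooled.llf, abs=1e-4)

    def test_recovers_group_variance_at_200_groups(self):
        cfg = SyntheticConfig(seed=9, n_dmus=200, n_years=5)
        df, truth = generate_tobit_panel(cfg)
        covs = ["Z1", "Z3", "Z5", "Z6", "D1", "D2", "D3"]
        fit = Tobit.from_dataframe(df, covariates=covs).fit()
        assert abs(fit.sigma_u - truth["sigma_u"]) / truth["sigma_u"] < 0.30
        err = np.abs(
            fit.params[covs].to_numpy()
            - np.array([truth["beta"].get(c, 0.0) for c in covs])
        )
        assert (err < 3 * fit.bse[covs].to_numpy() + 1e-12).all()

    def test_study_shaped_panel_fits_and_finds_group_effect(self):
        cfg = SyntheticConfig(seed=5)  # 39 groups x 5 obs, as in the study
        df, truth = generate_tobit_panel(cfg)
        fit = Tobit.from_dataframe(df, covariates=["Z1", "Z3", "Z5", "Z6"]).fit()
        assert fit.n_obs == 195 and fit.n_groups == 39 and fit.obs_per_group == 5
        assert fit.sigma_u > 0.05  # group effect detected
        assert fit.llf >= fit.model.fit(random_effects=False).llf - 1e-6

    def test_quadrature_converged_at_default_nodes(self):
        cfg = SyntheticConfig(seed=4, n_dmus=20, n_years=4)
        df, _ = generate_tobit_panel(cfg)
        covs = ["Z1", "Z3", "Z5"]
        fit = Tobit.from_dataframe(df, covariates=covs).fit()  # default 32 nodes
        doubled = Tobit.from_dataframe(df, covariates=covs, n_quad=64)
        assert abs(doubled.loglike_re(fit._params) - fit.llf) < 1e-4

    def test_too_few_quadrature_nodes_rejected(self):
        cfg = SyntheticConfig(seed=4, n_dmus=6, n_years=2)
        df, _ = generate_tobit_panel(cfg)
        with pytest.raises(ValueError, match="nodes"):
            Tobit.from_dataframe(df, covariates=["Z1"], n_quad=2)


class TestWaldAndComparison:
    def test_single_coefficient_identity(self, rng):
        y, X = _simulate_pooled(400, np.array([0.3, 0.4]), 0.5, rng)
        fit = Tobit(y, X, ["a", "const"]).fit(random_effects=False)
        stat, df = fit.wald_test(["a"])
        assert df == 1
        assert stat == pytest.approx((fit.params["a"] / fit.bse["a"]) ** 2, abs=1e-9)
        assert fit.wald_test([]) == (0.0, 0)

    def test_null_statistic_distributed_as_chi2(self):
        # beta = 0 for all slopes: Wald stat should average ~ df
        stats_ = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            beta = np.array([0.0, 0.0, 0.0, 0.5])
            y, X = _simulate_pooled(300, beta, 0.5, rng)
            fit = Tobit(y, X, ["a", "b", "c", "const"]).fit(
                random_effects=False, n_starts=1
            )
            stats_.append(fit.wald_stat)
        mean = np.mean(stats_)
        # mean of chi2_3 is 3, MC sd of the mean ~ sqrt(6/40) = 0.39
        assert abs(mean - 3.0) < 1.2

    def test_compare_models_ranks_by_wald(self):
        cfg = SyntheticConfig(seed=6)
        df, _ = generate_tobit_panel(cfg)
        ranked = compare_models(
            df, {"full": ["Z1", "Z3", "Z5", "Z6"], "noise": ["Z4", "Z7"]},
            random_effects=False,
        )
        assert list(ranked["model"]) == ["full", "noise"]
        assert ranked["wald_chi2"].is_monotonic_decreasing

    def test_collinear_candidate_isolated(self):
        cfg = SyntheticConfig(seed=6, n_dmus=20, n_years=3)
        df, _ = generate_tobit_panel(cfg)
        df["D_dup"] = df["D1"]
        ranked = compare_models(
            df,
            {"ok": ["Z1", "Z3"], "bad": ["D1", "D_dup", "Z1"]},
            random_effects=False,
        )
        row_bad = ranked.set_index("model").loc["bad"]
        assert "collinear" in row_bad["error"] or "rank" in row_bad["error"]
        assert ranked.set_index("model").loc["ok", "error"] == ""

    def test_default_candidates_match_published_sets(self):
        tab = load_fixture("tobit_models")
        stats_terms = {"n_obs", "n_groups", "obs_per_group", "wald_chi2", "log_likelihood"}
        for name, covs in MODEL_SETS.items():
            printed = set(tab.loc[tab.model == name, "term"]) - stats_terms - {"const"}
            assert printed == set(covs)

    def test_sign_convention_on_synthetic_data(self):
        # a covariate built to reduce inefficiency gets a negative coefficient
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(seed=200 + seed)
            df, _ = generate_tobit_panel(cfg)
            fit = Tobit.from_dataframe(
                df, covariates=["Z1", "Z3", "Z5", "Z6"]
            ).fit(random_effects=False)
            hits += fit.params["Z5"] < 0  # true effect -0.01
        assert hits >= 19


class TestVIF:
    def test_orthogonal_covariates_have_unit_vif(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1.0, abs=1e-10)
        assert out["b"] == pytest.approx(1.0, abs=1e-10)

    def test_near_duplicate_explodes(self, rng):
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x, "x2": x + rng.normal(0, 0.01, 200), "z": rng.normal(0, 1, 200)})
        out = vif(df)
        assert out["x"] > 100 and out["x2"] > 100

    def test_matches_inverse_correlation_diagonal(self, rng):
        X = rng.normal(0, 1, (300, 4)) @ rng.uniform(0.5, 1.5, (4, 4))
        df = pd.DataFrame(X, columns=list("abcd"))
        out = vif(df)
        oracle = np.diag(np.linalg.inv(np.corrcoef(X, rowvar=False)))
        assert np.abs(out.to_numpy() - oracle).max() < 1e-8

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            vif(df)

    def test_published_factor_table_shows_no_collinearity(self):
        factors = load_fixture("factors_2019")
        out = vif(factors, list("Z1 Z2 Z3 Z4 Z5 Z6 Z7 D1 D2 D3".split()))
        assert (out >= 1.0 - 1e-12).all()
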