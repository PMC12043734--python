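"""Estimator battery: differencing, Keller expansion, cluster-robust OLS,
stratified/trend/GLM fits, and the confounding-removal properties."""

import numpy as np
import pandas as pd
import pytest

from twingxe.scenarios import clean_params
from twingxe.synthetic_registry import generate_registry
from twingxe.phenotype_transforms import standardize_pgi
from twingxe.gxe_estimators import (
    ModelSpec,
    build_design,
    fit_between,
    fit_glm,
    fit_linear_clustered,
    fit_stratified,
    fit_trend,
    fit_within,
    keller_expand,
    pair_difference,
)

LATENT = ModelSpec(outcome="edu_latent", exposure="pgi", covariates=(), keller=False)
LATENT_W = ModelSpec(outcome="edu_latent", exposure="pgi", design="within",
                     covariates=(), keller=False)


class TestPairDifference:
    def test_difference_arithmetic_and_sign_convention(self):
        df = pd.DataFrame({
            "twin_id": [0, 1], "pair_id": [0, 0], "zygosity": "DZ",
            "sex": ["F", "M"], "birth_year": 1950, "batch": "a",
            "pgi": [1.3, 0.3], "edu_decile": [9.0, 6.0],
        })
        pairs = pair_difference(df)
        assert pairs.loc[0, "d_pgi"] == pytest.approx(1.0)
        assert pairs.loc[0, "d_edu_decile"] == pytest.approx(3.0)
        assert pairs.loc[0, "sex_difference"] == "mixed"

    def test_mz_and_incomplete_pairs_excluded(self, full_registry):
        pairs = pair_difference(full_registry)
        dz_complete = (
            full_registry[full_registry["zygosity"] == "DZ"]
            .dropna(subset=["edu_decile", "pgi"])
            .groupby("pair_id").size()
        )
        assert len(pairs) == (dz_complete == 2).sum()

    def test_order_flip_flips_signs_but_not_slope(self, small_registry):
        df = small_registry
        pairs = pair_difference(df, outcome="edu_latent")
        flipped = df.copy()
        flipped["twin_id"] = -flipped["twin_id"]  # reverses within-pair order
        pairs_f = pair_difference(flipped, outcome="edu_latent")
        merged = pairs.merge(pairs_f, on="pair_id", suffixes=("", "_f"))
        np.testing.assert_allclose(merged["d_pgi"], -merged["d_pgi_f"])
        a = fit_within(pairs, LATENT_W).params["d_pgi"]
        b = fit_within(pairs_f, LATENT_W).params["d_pgi"]
        assert abs(a - b) < 1e-10

    def test_no_eligible_pairs_raises(self):
        df = pd.DataFrame({
            "twin_id": [0, 1], "pair_id": [0, 0], "zygosity": "MZ",
            "sex": "F", "birth_year": 1950, "batch": "a",
            "pgi": [1.0, 1.0], "edu_decile": [5.0, 5.0],
        })
        with pytest.raises(ValueError, match="no eligible"):
            pair_difference(df)


class TestKellerExpansion:
    def test_single_covariate_single_moderator_counts(self):
        terms = keller_expand("pgi", ["m"], ["sex"])
        assert terms == ["const", "pgi", "m", "pgi:m", "sex", "sex:pgi", "sex:m"]

    def test_bare_model(self):
        assert keller_expand("pgi", [], [], keller=True) == ["const", "pgi"]

    def test_full_covariate_block_count(self):
        covs = [f"pc{i}" for i in range(1, 21)] + ["sex", "b1", "b2"]
        terms = keller_expand("pgi", ["m"], covs)
        assert len(terms) == 4 + 23 + 2 * 23  # core + mains + interactions

    def test_duplicate_terms_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            keller_expand("pgi", ["pgi"], [])


class TestClusteredOLS:
    def test_singleton_clusters_equal_hc1(self, rng):
        import statsmodels.api as sm
        n = 300
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        y = 0.5 * X["x"] + rng.standard_normal(n)
        ours = fit_linear_clustered(X, y, groups=None)
        ref = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(ours.params["x"], ref.params["x"], atol=1e-10)
        np.testing.assert_allclose(ours.se["x"], ref.bse["x"], atol=1e-10)

    def test_matches_statsmodels_cluster_estimates(self, rng):
        # dual route: independent sandwich implementation vs statsmodels
        import statsmodels.api as sm
        n = 400
        g = np.repeat(np.arange(n // 2), 2)
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        y = 0.3 * X["x"] + np.repeat(rng.standard_normal(n // 2), 2) \
            + rng.standard_normal(n)
        ours = fit_linear_clustered(X, y, groups=g)
        ref = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": g})
        np.testing.assert_allclose(ours.params["x"], ref.params["x"], atol=1e-10)
        # statsmodels applies the same (G/(G-1))((N-1)/(N-K)) factor
        np.testing.assert_allclose(ours.se["x"], ref.bse["x"], rtol=1e-8)

    def test_duplicating_rows_within_cluster_keeps_estimates(self, rng):
        n = 200
        g = np.arange(n)
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        y = pd.Series(0.4 * X["x"] + rng.standard_normal(n))
        base = fit_linear_clustered(X, y, groups=g)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = pd.concat([y, y], ignore_index=True)
        dup = fit_linear_clustered(X2, y2, groups=np.concatenate([g, g]))
        np.testing.assert_allclose(base.params["x"], dup.params["x"], atol=1e-10)

    def test_collinear_column_dropped_with_log(self, rng, caplog):
        n = 100
        x = rng.standard_normal(n)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        res = fit_linear_clustered(X, x + rng.standard_normal(n), None)
        assert res.dropped == ["x2"]

    def test_too_few_clusters_raises(self):
        X = pd.DataFrame({"const": [1.0, 1.0]})
        with pytest.raises(ValueError, match="clusters"):
            fit_linear_clustered(X, np.zeros(2), groups=np.zeros(2))

    def test_size_under_null(self, rng):
        # rejection rate at nominal 5% stays in [3.5, 6.5]% (1000 reps)
        reps, n = 1000, 2000
        rejections = 0
        for _ in range(reps):
            g = np.repeat(np.arange(n // 2), 2)
            x = rng.standard_normal(n)
            y = np.repeat(rng.standard_normal(n // 2), 2) + rng.standard_normal(n)
            res = fit_linear_clustered(
                pd.DataFrame({"const": 1.0, "x": x}), y, groups=g)
            rejections += res.pvalues["x"] < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestBetweenWithin:
    def test_between_recovers_direct_effect(self):
        df = generate_registry(clean_params(n_pairs=25_000), seed=21)
        fit = fit_between(df, LATENT)
        assert abs(fit.params["pgi"] - 0.3) < 0.02

    def test_permuted_pgi_gives_null(self, rng):
        df = generate_registry(clean_params(n_pairs=10_000), seed=22)
        df = df.assign(pgi=rng.permutation(df["pgi"].to_numpy()))
        fit = fit_between(df, LATENT)
        assert abs(fit.params["pgi"]) < 2 * fit.se["pgi"]

    def test_within_removes_nurture(self):
        df = generate_registry(
            clean_params(n_pairs=25_000, delta_nurture=0.1, r_am=0.2), seed=23)
        pairs = pair_difference(df, outcome="edu_latent")
        fit = fit_within(pairs, LATENT_W)
        assert abs(fit.params["d_pgi"] - 0.3) < 0.03

    @pytest.mark.parametrize("n_pairs,seed", [(500, 1), (2_000, 2), (5_000, 3)])
    def test_difference_equals_pair_fixed_effects(self, n_pairs, seed):
        # property: FD (no const) == demeaned FE; FD (const) == FE + order dummy
        from twingxe.scenarios import fe_equivalence_gap
        assert fe_equivalence_gap(seed, n_pairs=n_pairs) < 1e-8

    def test_within_rejects_pair_varying_moderator(self, small_registry):
        pairs = pair_difference(small_registry, outcome="edu_latent")
        spec = ModelSpec(outcome="edu_latent", design="within",
                         moderators=("d_pgi",), covariates=(), keller=False)
        with pytest.raises(ValueError, match="pair-level"):
            fit_within(pairs, spec)

    def test_batch_shift_removed_by_standardization(self):
        # pure additive batch offsets leave estimates unchanged after the
        # within-stratum standardization
        base = clean_params(
            n_pairs=20_000, birth_year_range=(1950, 1951),
            batch_birthyear_map={1950: {"a": 0.5, "b": 0.5}},
            batch_shift={"a": 0.0, "b": 0.0})
        shifted = clean_params(
            n_pairs=20_000, birth_year_range=(1950, 1951),
            batch_birthyear_map={1950: {"a": 0.5, "b": 0.5}},
            batch_shift={"a": 0.0, "b": 1.5})
        df0 = generate_registry(base, seed=31)
        df1 = generate_registry(shifted, seed=31)
        df0 = standardize_pgi(df0)
        df1 = standardize_pgi(df1)
        f0 = fit_between(df0, LATENT)
        f1 = fit_between(df1, LATENT)
        assert abs(f0.params["pgi"] - f1.params["pgi"]) < 1e-9


class TestStratifiedAndTrend:
    def test_two_decade_recovery(self):
        params = clean_params(
            n_pairs=20_000, birth_year_range=(1950, 1969),
            reference_year=1955, beta0=0.2,
            gamma_schedule={1950: 0.0, 1960: 0.0})
        df = generate_registry(params, seed=41)
        # overwrite latent with an exact two-level effect for a sharp truth
        rng = np.random.default_rng(5)
        beta = np.where(df["birth_year"] < 1960, 0.2, 0.4)
        df["edu_latent"] = beta * df["g_true"] + rng.standard_normal(len(df))
        res = fit_stratified(df, LATENT, ("decade",), min_n=50)
        assert abs(res.fits[1950].params["pgi"] - 0.2) < 0.03
        assert abs(res.fits[1960].params["pgi"] - 0.4) < 0.03

    def test_constant_stratum_matches_unstratified(self, small_registry):
        df = small_registry.assign(decade=1950)
        strat = fit_stratified(df, LATENT, ("decade",), min_n=10)
        whole = fit_between(df, LATENT)
        assert strat.fits[1950].params["pgi"] == pytest.approx(
            whole.params["pgi"], abs=1e-12)

    def test_undersized_stratum_reported(self, small_registry):
        res = fit_stratified(small_registry, LATENT, ("decade",), min_n=10**6)
        assert res.fits == {}
        assert sum(res.skipped.values()) == len(small_registry)

    def test_trend_recovery_and_null(self):
        p = clean_params(n_pairs=30_000, birth_year_range=(1920, 1979),
                         reference_year=1920, beta0=0.15, beta_trend=0.004)
        df = generate_registry(p, seed=51)
        fit = fit_trend(df, LATENT)
        assert abs(fit.params["pgi:birth_year_c"] - 0.004) < 0.0015

        p0 = clean_params(n_pairs=20_000, birth_year_range=(1920, 1979),
                          reference_year=1920, beta0=0.2, beta_trend=0.0)
        df0 = generate_registry(p0, seed=52)
        f0 = fit_trend(df0, LATENT)
        term = "pgi:birth_year_c"
        assert abs(f0.params[term]) < 2 * f0.se[term]

    def test_degenerate_birth_year_variance_raises(self, rng):
        df = generate_registry(
            clean_params(n_pairs=200, birth_year_range=(1950, 1950)), seed=53)
        with pytest.raises(ValueError, match="birth-year"):
            fit_trend(df, LATENT)

    def test_keller_leaves_main_effect_unmoved_under_noise_covariates(self, rng):
        df = generate_registry(clean_params(n_pairs=20_000), seed=54)
        df["z1"] = rng.standard_normal(len(df))
        df["z2"] = rng.standard_normal(len(df))
        df["m"] = rng.standard_normal(len(df))
        plain = fit_between(df, ModelSpec(outcome="edu_latent", covariates=(),
                                          keller=False))
        keller = fit_between(df, ModelSpec(outcome="edu_latent",
                                           moderators=("m",),
                                           covariates=("z1", "z2"), keller=True))
        joint_se = np.hypot(plain.se["pgi"], keller.se["pgi"])
        assert abs(plain.params["pgi"] - keller.params["pgi"]) < 2 * joint_se


class TestGLM:
    def test_ordered_logit_collapses_to_binary_logit(self):
        df = generate_registry(clean_params(n_pairs=3_000), seed=61)
        spec_o = ModelSpec(outcome="degree_upper_sec", family="ordered_logit",
                           covariates=(), keller=False)
        spec_l = ModelSpec(outcome="degree_upper_sec", family="logit",
                           covariates=(), keller=False)
        fo = fit_glm(df, spec_o)
        fl = fit_glm(df, spec_l)
        assert abs(fo.params["pgi"] - fl.params["pgi"]) < 1e-5

    def test_logistic_latent_slope_recovered(self, rng):
        n = 60_000
        x = rng.standard_normal(n)
        lat = 0.8 * x + rng.logistic(size=n)
        df = pd.DataFrame({"pgi": x, "y": (lat > 0).astype(float),
                           "pair_id": np.arange(n)})
        fit = fit_glm(df, ModelSpec(outcome="y", family="logit",
                                    covariates=(), keller=False))
        assert abs(fit.params["pgi"] - 0.8) / 0.8 < 0.05

    def test_zero_effect_generator_null(self, rng):
        n = 5_000
        df = pd.DataFrame({"pgi": rng.standard_normal(n),
                           "y": (rng.random(n) < 0.4).astype(float),
                           "pair_id": np.arange(n)})
        fit = fit_glm(df, ModelSpec(outcome="y", family="logit",
                                    covariates=(), keller=False))
        assert abs(fit.params["pgi"]) < 2 * fit.se["pgi"]

    def test_separation_raises_with_diagnostic(self):
        df = pd.DataFrame({"pgi": np.linspace(-2, 2, 100),
                           "y": (np.linspace(-2, 2, 100) > 0).astype(float),
                           "pair_id": np.arange(100)})
        with pytest.raises(ValueError, match="separation"):
            fit_glm(df, ModelSpec(outcome="y", family="logit",
                                  covariates=(), keller=False))

    def test_logit_requires_binary_outcome(self, small_registry):
        with pytest.raises(ValueError, match="binary"):
            fit_glm(small_registry, ModelSpec(outcome="edu_decile",
                                              family="logit", covariates=(),
                                              keller=False))
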