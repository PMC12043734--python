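"""Generator mechanics: mating, transmission, observation, ascertainment."""

import numpy as np
import pandas as pd
import pytest

from twingxe.scenarios import clean_params
from twingxe.synthetic_registry import (
    GenerativeParams,
    ascertain_sample,
    assign_cohort_batch,
    draw_parents,
    generate_registry,
    observe_pgi,
    read_registry,
    transmit_genotypes,
    write_registry,
)


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(r_am=1.0), dict(r_am=-1.2), dict(p_mz=1.5),
        dict(sigma_meas_unique=-0.1), dict(n_pairs=-3),
        dict(birth_year_range=(1980, 1920)),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            clean_params(**bad)

    def test_schedule_must_cover_birth_decades(self):
        with pytest.raises(ValueError, match="gamma_schedule"):
            GenerativeParams(gamma_schedule={1920: 0.0})

    def test_batch_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            clean_params(batch_birthyear_map={1950: {"omni": 0.5, "core": 0.3}})

    def test_json_roundtrip(self):
        p = clean_params(n_pairs=10)
        q = GenerativeParams.from_dict(__import__("json").loads(p.to_json()))
        assert q == p


class TestParents:
    @pytest.mark.parametrize("r_am", [0.0, 0.2])
    def test_parental_correlation_matches_r_am(self, rng, r_am):
        p = clean_params(n_pairs=100_000, r_am=r_am)
        par = draw_parents(p, rng)
        r_hat = np.corrcoef(par["g_mother"], par["g_father"])[0, 1]
        assert abs(r_hat - r_am) < 0.01

    def test_zero_pairs_gives_empty_frame(self, rng):
        par = draw_parents(clean_params(n_pairs=0), rng)
        assert len(par) == 0

    def test_parent_education_monotone_in_genetic_value(self, rng):
        p = clean_params(n_pairs=50_000, parent_edu_loading=0.5)
        par = draw_parents(p, rng)
        # deciles uniform and positively associated with g
        counts = par["mother_edu"].value_counts(normalize=True)
        assert counts.max() < 0.11 and counts.min() > 0.09
        assert np.corrcoef(par["g_mother"], par["mother_edu"])[0, 1] > 0.3


class TestTransmission:
    def test_mz_twins_share_genotype(self, rng):
        p = clean_params(n_pairs=1_000)
        par = draw_parents(p, rng)
        g1, g2 = transmit_genotypes(par, np.full(1_000, "MZ"), p, rng)
        np.testing.assert_array_equal(g1, g2)

    @pytest.mark.parametrize("r_am,expected", [(0.0, 0.5), (0.2, 0.6)])
    def test_dz_cotwin_correlation(self, rng, r_am, expected):
        p = clean_params(n_pairs=100_000, r_am=r_am)
        par = draw_parents(p, rng)
        g1, g2 = transmit_genotypes(par, np.full(100_000, "DZ"), p, rng)
        assert abs(np.corrcoef(g1, g2)[0, 1] - expected) < 0.01
        assert abs(np.var(g1) - 1.0) < 0.02  # unit offspring variance


class TestObservation:
    def test_noise_free_pgi_equals_genetic_value(self, rng):
        p = clean_params(n_pairs=100)
        g = rng.standard_normal(200)
        pgi = observe_pgi(g, np.repeat(np.arange(100), 2),
                          np.full(200, "omni"), np.empty((200, 0)), p, rng)
        np.testing.assert_allclose(pgi, g)

    def test_unique_error_inflates_variance(self, rng):
        p = clean_params(n_pairs=100_000, sigma_meas_unique=0.5)
        g = rng.standard_normal(200_000)
        pgi = observe_pgi(g, np.repeat(np.arange(100_000), 2),
                          np.full(200_000, "omni"), np.empty((200_000, 0)), p, rng)
        assert abs(np.var(pgi) - 1.25) < 0.01

    def test_shared_error_correlates_within_pair(self, rng):
        p = clean_params(n_pairs=100_000, sigma_meas_unique=0.5,
                         sigma_meas_shared=0.5)
        g = np.zeros(200_000)
        pgi = observe_pgi(g, np.repeat(np.arange(100_000), 2),
                          np.full(200_000, "omni"), np.empty((200_000, 0)), p, rng)
        err = pgi.reshape(-1, 2)
        r = np.corrcoef(err[:, 0], err[:, 1])[0, 1]
        assert abs(r - 0.5) < 0.02  # shared/(shared+unique) with equal SDs


class TestBatchAssignment:
    def test_deterministic_map(self, rng):
        p = clean_params(batch_birthyear_map={1950: {"a": 1.0}},
                         batch_shift={"a": 0.0})
        years = np.full(5_000, 1955)
        assert set(assign_cohort_batch(years, p, rng)) == {"a"}

    def test_graded_map_matches_probabilities(self, rng):
        p = clean_params(
            birth_year_range=(1950, 1969),
            batch_birthyear_map={1950: {"a": 0.7, "b": 0.3},
                                 1960: {"a": 0.2, "b": 0.8}},
            batch_shift={"a": 0.0, "b": 0.0})
        years = np.concatenate([np.full(50_000, 1955), np.full(50_000, 1965)])
        batch = assign_cohort_batch(years, p, rng)
        assert abs((batch[:50_000] == "a").mean() - 0.7) < 0.02
        assert abs((batch[50_000:] == "b").mean() - 0.8) < 0.02

    def test_missing_decade_raises(self, rng):
        p = clean_params()
        with pytest.raises(ValueError, match="decade"):
            assign_cohort_batch(np.array([1850]), p, rng)


class TestPhenotypes:
    def test_null_generator_uncorrelated(self):
        p = clean_params(n_pairs=20_000, beta0=0.0)
        df = generate_registry(p, seed=5)
        r = np.corrcoef(df["edu_latent"], df["g_true"])[0, 1]
        assert abs(r) < 0.02

    def test_direct_effect_recovered_by_ols(self):
        p = clean_params(n_pairs=50_000)
        df = generate_registry(p, seed=6)
        x = df["g_true"].to_numpy()
        y = df["edu_latent"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x)
        assert abs(slope - 0.3) < 0.01

    def test_nurture_and_am_inflate_population_slope(self):
        # closed form beta + delta*(1+r_am) = 0.3 + 0.1*1.2 = 0.42
        p = clean_params(n_pairs=50_000, delta_nurture=0.1, r_am=0.2)
        df = generate_registry(p, seed=8)
        x = df["g_true"].to_numpy()
        y = df["edu_latent"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x)
        assert abs(slope - 0.42) < 0.01

    def test_latent_variance_near_one(self, full_registry):
        assert abs(full_registry["edu_latent"].var() - 1.0) < 0.12


class TestAscertainment:
    def test_zero_bias_is_identity(self, small_registry, rng):
        p = clean_params(ascertain_edu_bias=0.0)
        out = ascertain_sample(small_registry, p, rng)
        pd.testing.assert_frame_equal(out, small_registry)

    def test_bias_shifts_sampled_mean(self, rng):
        p = clean_params(n_pairs=50_000, ascertain_edu_bias=0.4, years_per_sd=3.0)
        df = generate_registry(clean_params(n_pairs=50_000), seed=9)
        out = ascertain_sample(df, p, rng)
        shift = out["edu_latent"].mean() - df["edu_latent"].mean()
        assert abs(shift - 0.4 / 3.0) < 0.02
        assert len(out) < len(df)

    def test_unreachable_bias_warns(self, small_registry, rng):
        p = clean_params(ascertain_edu_bias=30.0, years_per_sd=1.0)
        with pytest.warns(RuntimeWarning, match="best effort"):
            ascertain_sample(small_registry, p, rng)


class TestRegistryContract:
    def test_bit_reproducible(self):
        p = clean_params(n_pairs=500, p_mz=0.4)
        a = generate_registry(p, seed=42)
        b = generate_registry(p, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_pair_shared_fields(self, full_registry):
        grp = full_registry.groupby("pair_id")
        for col in ("birth_year", "batch", "parent_edu"):
            assert (grp[col].nunique(dropna=False) == 1).all()
        mz = full_registry[full_registry["zygosity"] == "MZ"]
        assert (mz.groupby("pair_id")["g_true"].nunique() == 1).all()
        assert (mz.groupby("pair_id")["sex"].nunique() == 1).all()

    def test_decile_range_and_missingness(self, full_registry):
        dec = full_registry["edu_decile"].dropna()
        assert dec.between(1, 10).all()
        old = full_registry["birth_year"] < 1940
        assert full_registry.loc[old, "parent_edu"].isna().all()

    def test_tsv_roundtrip(self, tmp_path, small_registry):
        p = clean_params(n_pairs=2_000, p_mz=0.3)
        path = tmp_path / "reg.tsv"
        write_registry(small_registry, path, params=p, seed=11)
        back = read_registry(path)
        assert len(back) == len(small_registry)
        assert "g_true" not in back.columns  # simulation-only fields stay private
        np.testing.assert_allclose(back["pgi"], small_registry["pgi"], rtol=1e-9)
        sidecar = path.with_suffix(".tsv.json")
        assert sidecar.exists()
        meta = __import__("json").loads(sidecar.read_text())
        assert meta["seed"] == 11 and meta["n_pairs"] == 2_000
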