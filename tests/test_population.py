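import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from empasim import mease2, population
from empasim.population import (
    CovariateSpec,
    Endpoint,
    ResidualSpec,
    StudyDesign,
    fit_distribution_from_quantiles,
    generate_observations,
    sample_population,
)


class TestQuantileFit:
    def test_lognormal_matches_published_hba1c_interval(self):
        # median 8.00, 95% interval (7.20, 9.50): median exact, tails within 5%
        dist = fit_distribution_from_quantiles(8.00, 7.20, 9.50, "lognormal")
        assert dist.median() == pytest.approx(8.00, rel=1e-12)
        assert dist.ppf(0.025) == pytest.approx(7.20, rel=0.05)
        assert dist.ppf(0.975) == pytest.approx(9.50, rel=0.05)

    def test_symmetric_log_interval_gives_exact_scale(self):
        a, b = np.exp(-0.3), np.exp(0.3)
        dist = fit_distribution_from_quantiles(1.0, a, b, "lognormal")
        assert dist.kwds["s"] == pytest.approx(np.log(b / 1.0) / stats.norm.ppf(0.975))
        assert dist.ppf(0.975) == pytest.approx(b, rel=1e-9)

    def test_least_squares_optimum_against_numerical_inversion(self):
        # weight spec 84 (55, 126): the fitted sigma must beat any nearby
        # sigma in summed squared log-quantile error (quantile-inversion oracle)
        dist = fit_distribution_from_quantiles(84.0, 55.0, 126.0, "lognormal")
        s_hat = dist.kwds["s"]

        def sse(s):
            d = stats.lognorm(s=s, scale=84.0)
            return (np.log(d.ppf(0.025)) - np.log(55.0)) ** 2 + \
                   (np.log(d.ppf(0.975)) - np.log(126.0)) ** 2

        for s in (0.8 * s_hat, 0.95 * s_hat, 1.05 * s_hat, 1.2 * s_hat):
            assert sse(s_hat) <= sse(s) + 1e-12

    def test_truncated_normal_median_near_requested(self):
        dist = fit_distribution_from_quantiles(46.0, 21.0, 69.0, "truncnorm")
        assert dist.median() == pytest.approx(46.0, abs=0.2)

    @pytest.mark.parametrize("bad", [(8.0, 9.0, 7.0), (8.0, 8.5, 9.0)])
    def test_inverted_quantiles_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_distribution_from_quantiles(*bad, "lognormal")

    def test_nonpositive_lognormal_quantile_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution_from_quantiles(1.0, -0.5, 2.0, "lognormal")

    @settings(derandomize=True, max_examples=40)
    @given(median=st.floats(0.5, 500), lo_f=st.floats(0.3, 0.95), hi_f=st.floats(1.05, 3.0))
    def test_median_always_exact(self, median, lo_f, hi_f):
        dist = fit_distribution_from_quantiles(median, median * lo_f, median * hi_f,
                                               "lognormal")
        assert dist.median() == pytest.approx(median, rel=1e-9)


class TestSamplePopulation:
    def test_ease2_structure(self, ease2_patients):
        assert len(ease2_patients) == 721
        assert set(ease2_patients["arm"].unique()) == {0.0, 10.0, 25.0}
        placebo = ease2_patients[ease2_patients["arm"] == 0]
        assert (placebo["auc_ss"] == 0).all()
        assert (ease2_patients.loc[ease2_patients["arm"] > 0, "auc_ss"] > 0).all()

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign("EASE2", (0.0, 10.0), 52, 0)

    def test_empty_covariate_list_rejected(self, ease2_design):
        with pytest.raises(ValueError):
            sample_population(ease2_design, covariate_specs=[], seed=0)

    def test_seed_reproducibility(self, ease2_design):
        a = sample_population(ease2_design, seed=3)
        b = sample_population(ease2_design, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_median_converges(self):
        # Monte-Carlo oracle: 1e5 draws from the fitted baseline-HbA1c
        # distribution have a sample median within 0.02 of 8.00
        spec = CovariateSpec("hba1c0", "lognormal", 8.00, 7.20, 9.50)
        draws = spec.sample(100_000, np.random.default_rng(0))
        assert np.median(draws) == pytest.approx(8.00, abs=0.02)

    def test_modality_frequency_near_configured(self, ease2_patients):
        # 64% of patients use multiple daily injections
        assert ease2_patients["modality_csii"].mean() == pytest.approx(0.36, abs=0.06)


class TestGenerateObservations:
    def test_placebo_zero_noise_is_linear_in_time(self, ease2_design):
        # placebo, no residual, no IIV: HbA1c(t) = baseline + slope * t exactly
        pats = sample_population(ease2_design, seed=1).head(20)
        pats = pats.assign(arm=0.0, auc_ss=0.0, eta_emax=0.0, modality_csii=0)
        params = mease2.MEase2Params()
        obs = generate_observations(pats, "MEASE2", params, ease2_design,
                                    error_model=ResidualSpec(0.0, 0.0, 0.0), seed=0)
        merged = obs.merge(pats[["id", "hba1c0"]], left_on="ID", right_on="id")
        expected = merged["hba1c0"] + params.placebo_slope * merged["TIME"]
        assert np.allclose(merged["DV"], expected)

    def test_reference_patient_week26_arithmetic(self, ease2_design):
        # baseline - Emax/2 + slope * t at the half-maximal exposure
        pats = pd.DataFrame({
            "id": [0], "study": "EASE2", "arm": [2.5], "hba1c0": [8.14],
            "egfr": [98.0], "modality_csii": [0], "eta_emax": [0.0],
            "auc_ss": [498.0],
        })
        params = mease2.MEase2Params(ref_hba1c=8.14)
        obs = generate_observations(pats, "MEASE2", params, ease2_design,
                                    error_model=ResidualSpec(0.0, 0.0, 0.0), seed=0)
        wk26 = obs[obs["TIME"] == 26 * 168.0]["DV"].iloc[0]
        assert wk26 == pytest.approx(8.14 - 0.2895 + 2.61e-5 * 4368, abs=1e-9)

    def test_time_zero_equals_baseline_before_residual(self, ease2_patients, ease2_design):
        obs = generate_observations(ease2_patients, "MEASE2", mease2.MEase2Params(),
                                    ease2_design, error_model=ResidualSpec(0, 0, 0), seed=0)
        at0 = obs[obs["TIME"] == 0].merge(ease2_patients[["id", "hba1c0"]],
                                          left_on="ID", right_on="id")
        assert np.allclose(at0["DV"], at0["hba1c0"])

    def test_observation_count_matches_reported_sizing(self, ease2_patients, ease2_design):
        # 4750 HbA1c observations reported for the 52-week study
        obs = generate_observations(ease2_patients, "MEASE2", mease2.MEase2Params(),
                                    ease2_design, seed=0)
        n = (obs["DVID"] == Endpoint.HBA1C.value).sum()
        assert abs(n - 4750) / 4750 < 0.20

    def test_no_duplicate_records_and_finite(self, ease2_patients, ease2_design):
        obs = generate_observations(ease2_patients, "MEASE2", mease2.MEase2Params(),
                                    ease2_design, seed=0)
        assert not obs.duplicated(["ID", "TIME", "DVID"]).any()
        assert np.isfinite(obs["DV"]).all()
        assert (obs["TIME"] >= 0).all()
        assert obs["TIME"].max() <= ease2_design.duration_weeks * 168.0

    def test_unknown_generator_rejected(self, ease2_patients, ease2_design):
        with pytest.raises(ValueError):
            generate_observations(ease2_patients, "NOPE", None, ease2_design, seed=0)

    def test_seed_identical_tables(self, ease2_patients, ease2_design):
        a = generate_observations(ease2_patients, "MEASE2", mease2.MEase2Params(),
                                  ease2_design, seed=5)
        b = generate_observations(ease2_patients, "MEASE2", mease2.MEase2Params(),
                                  ease2_design, seed=5)
        assert a.to_csv() == b.to_csv()


def test_nonmem_csv_roundtrip(tmp_path, ease2_patients, ease2_design):
    obs = generate_observations(ease2_patients.head(30), "MEASE2",
                                mease2.MEase2Params(), ease2_design, seed=0)
    path = tmp_path / "obs.csv"
    population.write_nonmem_csv(obs, ease2_patients, path)
    back = population.read_nonmem_csv(path)
    assert {"ID", "TIME", "DV", "DVID", "AMT", "MDV", "hba1c0"} <= set(back.columns)
    assert len(back) == len(obs)
    assert np.allclose(np.sort(back["DV"]), np.sort(obs["DV"]))
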