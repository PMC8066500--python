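import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from empasim import mease2
from empasim.mease2 import (
    MEase2Params,
    PriorSpec,
    derive_covariate_exponents,
    emax_individual,
    fit_nuts,
    log_density,
    predict_hba1c,
)


class TestCovariateModel:
    def test_reference_patient_emax(self):
        from empasim.reference import MEASE2_REFERENCE_PATIENT
        assert emax_individual(MEase2Params(), MEASE2_REFERENCE_PATIENT) == \
            pytest.approx(0.579, abs=1e-9)

    def test_back_solved_exponents(self):
        d = derive_covariate_exponents()
        assert d["hba1c_on_emax"] == pytest.approx(1.000, abs=0.01)
        assert d["egfr_on_emax"] == pytest.approx(0.508, abs=0.01)
        assert d["csii_on_placebo"] == pytest.approx(1.47)

    def test_high_baseline_raises_emax(self):
        val = emax_individual(MEase2Params(), {"hba1c0": 9.0, "egfr": 98.0})
        assert val == pytest.approx(0.579 * (9.0 / 8.1), rel=0.005)

    def test_reference_covariates_identity(self):
        p = MEase2Params(hba1c_on_emax=0.0, egfr_on_emax=0.0)
        assert emax_individual(p, {"hba1c0": 12.0, "egfr": 40.0}) == pytest.approx(p.emax)

    def test_nonpositive_covariate_rejected(self):
        with pytest.raises(ValueError):
            emax_individual(MEase2Params(), {"hba1c0": -1.0, "egfr": 98.0})


class TestPrediction:
    def test_reference_baseline(self):
        from empasim.reference import MEASE2_REFERENCE_PATIENT
        assert predict_hba1c(MEase2Params(), MEASE2_REFERENCE_PATIENT, 0.0, 0.0) == \
            pytest.approx(8.14)

    def test_half_maximal_identity(self):
        from empasim.reference import MEASE2_REFERENCE_PATIENT
        p = MEase2Params()
        drug = predict_hba1c(p, MEASE2_REFERENCE_PATIENT, 0.0, 0.0) - \
            predict_hba1c(p, MEASE2_REFERENCE_PATIENT, p.auc50, 0.0)
        assert drug == pytest.approx(0.2895, abs=1e-9)

    def test_placebo_drift_week26(self):
        from empasim.reference import MEASE2_REFERENCE_PATIENT
        val = predict_hba1c(MEase2Params(), MEASE2_REFERENCE_PATIENT, 0.0, 26 * 168.0)
        assert val == pytest.approx(8.14 + 2.61e-5 * 4368, abs=1e-9)

    def test_emax_algebra_limits(self):
        from empasim.reference import MEASE2_REFERENCE_PATIENT
        p = MEase2Params(placebo_slope=0.0)
        at0 = predict_hba1c(p, MEASE2_REFERENCE_PATIENT, 0.0, 0.0)
        at_inf = predict_hba1c(p, MEASE2_REFERENCE_PATIENT, 1e12, 0.0)
        assert at0 - at_inf == pytest.approx(p.emax, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            predict_hba1c(MEase2Params(), {}, 0.0, -1.0)


def _tiny_dataset(n=12, seed=0, sigma=0.0):
    rng = np.random.default_rng(seed)
    p = MEase2Params()
    recs, expos = [], []
    for i in range(n):
        auc = [0.0, 800.0, 3000.0][i % 3]
        expos.append({"id": i, "auc_ss": auc})
        for t in (0.0, 4 * 168.0, 26 * 168.0):
            drug = p.emax * auc / (p.auc50 + auc) if t > 0 else 0.0
            dv = p.baseline - drug + p.placebo_slope * t + rng.normal(0, sigma)
            recs.append({"ID": i, "TIME": t, "DVID": "HBA1C", "DV": dv, "ARM": auc,
                         "hba1c0": p.ref_hba1c, "egfr": p.ref_egfr, "modality_csii": 0})
    return pd.DataFrame(recs), pd.DataFrame(expos)


class TestLogDensity:
    def test_doubling_data_doubles_likelihood_term(self):
        data, expos = _tiny_dataset(sigma=0.1)
        p = MEase2Params()
        pri = PriorSpec()
        single = log_density(p, data, expos, pri)
        doubled = log_density(p, pd.concat([data, data]), expos, pri)
        # the prior terms are identical, so the difference is the pure
        # Gaussian observation log likelihood of one copy
        pred = data["DV"] * 0.0
        rows = data.merge(expos.rename(columns={"id": "ID"}), on="ID")
        drug = p.emax * rows["auc_ss"] / (p.auc50 + rows["auc_ss"]) * (rows["TIME"] > 0)
        mu = p.baseline - drug + p.placebo_slope * rows["TIME"]
        loglik = stats.norm.logpdf(rows["DV"], mu, p.sigma).sum()
        assert doubled - single == pytest.approx(loglik, rel=1e-9)

    def test_prior_mode_at_informative_location(self):
        # placebo-only data make the data term independent of AUC50, so the
        # profile over AUC50 peaks exactly at the prior location
        data, expos = _tiny_dataset(sigma=0.1)
        keep = expos[expos["auc_ss"] == 0]["id"]
        data = data[data["ID"].isin(keep)]
        expos = expos[expos["id"].isin(keep)]
        pri = PriorSpec()
        vals = {a: log_density(MEase2Params(auc50=a), data, expos, pri)
                for a in (352.0, 704.0, 1056.0, 2000.0)}
        assert max(vals, key=vals.get) == 704.0

    def test_optimizer_oracle_on_clean_data(self):
        # with flat priors, least squares on noise-free data recovers the
        # generating fixed effects
        data, expos = _tiny_dataset(sigma=0.0)
        rows = data.merge(expos.rename(columns={"id": "ID"}), on="ID")

        def resid(x):
            base, la50, emax, slope4 = x
            drug = emax * rows["auc_ss"] / (np.exp(la50) + rows["auc_ss"]) * (rows["TIME"] > 0)
            return rows["DV"] - (base - drug + slope4 * 1e-4 * rows["TIME"])

        sol = optimize.least_squares(resid, [8.0, np.log(600.0), 0.5, 0.3])
        assert sol.x[0] == pytest.approx(8.14, abs=1e-6)
        assert np.exp(sol.x[1]) == pytest.approx(498.0, rel=1e-4)
        assert sol.x[2] == pytest.approx(0.579, abs=1e-5)

    def test_nan_rejected(self):
        data, expos = _tiny_dataset()
        data.loc[0, "DV"] = np.nan
        with pytest.raises(ValueError):
            log_density(MEase2Params(), data, expos, PriorSpec())


class TestMarginalLikelihood:
    def test_matches_dense_gaussian_construction(self, mease2_synth):
        # oracle: per-patient moment-matched Gaussian assembled with dense
        # linear algebra, versus the sufficient-statistic Woodbury version
        obs, expos, pats = mease2_synth
        sub_ids = pats["id"].iloc[:40]
        obs = obs[obs["ID"].isin(sub_ids)]
        expos = expos[expos["id"].isin(sub_ids)]
        tmpl = MEase2Params()
        ss = mease2._SuffStats(obs, expos, tmpl)
        pri = PriorSpec()
        x = np.array([np.log(8.0), np.log(650.0), np.log(0.55), 0.28,
                      np.log(0.07), np.log(0.22), np.log(0.26)])
        ll, _ = mease2._marginal_logp_grad(x, ss, pri)

        lta, lA, ltc, td4, lwz, lws, lsg = x
        ta, A, tc, td = np.exp(lta), np.exp(lA), np.exp(ltc), td4 * 1e-4
        wz, ws, sg = np.exp(lwz), np.exp(lws), np.exp(lsg)
        kz, ks = np.exp(wz**2 / 2), np.exp(ws**2 / 2)
        Vz = np.exp(2 * wz**2) - np.exp(wz**2)
        Vs = np.exp(2 * ws**2) - np.exp(ws**2)
        ll_dense = 0.0
        merged = obs.merge(expos.rename(columns={"id": "ID2", "auc_ss": "auc2"}),
                           left_on="ID", right_on="ID2")
        for pid, sub in merged.groupby("ID"):
            y = sub["DV"].to_numpy()
            t = sub["TIME"].to_numpy()
            tau = t * tmpl.csii_on_placebo ** sub["modality_csii"].to_numpy()
            m = (t > 0).astype(float)
            a = sub["auc2"].iloc[0]
            h = ((sub["hba1c0"].iloc[0] / tmpl.ref_hba1c) ** tmpl.hba1c_on_emax
                 * (sub["egfr"].iloc[0] / tmpl.ref_egfr) ** tmpl.egfr_on_emax)
            w = a / (A + a)
            mu = ta * kz - tc * h * ks * w * m + td * tau
            wvec = w * m
            cov = (ta**2 * Vz * np.ones((len(y), len(y)))
                   + (tc * h) ** 2 * Vs * np.outer(wvec, wvec)
                   + sg**2 * np.eye(len(y)))
            r = y - mu
            ll_dense += -0.5 * (len(y) * np.log(2 * np.pi)
                                + np.linalg.slogdet(cov)[1]
                                + r @ np.linalg.solve(cov, r))
        for val, ms in [(lta, pri.baseline_log), (ltc, pri.emax_log),
                        (td4, pri.placebo_slope_e4), (lwz, pri.omega_baseline_log),
                        (lws, pri.omega_emax_log), (lsg, pri.sigma_log),
                        (lA, (np.log(pri.auc50_location), pri.auc50_effective_sd))]:
            ll_dense += stats.norm.logpdf(val, *ms)
        assert ll == pytest.approx(ll_dense, rel=1e-10)

    def test_gradient_matches_finite_differences(self, mease2_synth):
        obs, expos, _ = mease2_synth
        ss = mease2._SuffStats(obs, expos, MEase2Params())
        pri = PriorSpec()
        x0 = np.array([np.log(8.1), np.log(600.0), np.log(0.5), 0.3,
                       np.log(0.08), np.log(0.25), np.log(0.3)])
        ll, g = mease2._marginal_logp_grad(x0, ss, pri)
        eps = 1e-6
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (mease2._marginal_logp_grad(xp, ss, pri)[0]
                  - mease2._marginal_logp_grad(xm, ss, pri)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestFitNuts:
    def test_requires_two_chains(self, mease2_synth):
        obs, expos, _ = mease2_synth
        with pytest.raises(ValueError):
            fit_nuts(obs, expos, chains=1)

    def test_seed_determinism(self, mease2_synth):
        obs, expos, pats = mease2_synth
        sub = pats["id"].iloc[:60]
        o = obs[obs["ID"].isin(sub)]
        e = expos[expos["id"].isin(sub)]
        a = fit_nuts(o, e, chains=2, warmup=100, draws=100, seed=4)
        b = fit_nuts(o, e, chains=2, warmup=100, draws=100, seed=4)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_posterior_recovers_generating_parameters(self, mease2_synth):
        obs, expos, _ = mease2_synth
        post = fit_nuts(obs, expos, chains=2, warmup=300, draws=500, seed=8)
        assert post.median("emax") == pytest.approx(0.579, abs=0.1)
        assert 296.0 < post.median("auc50") < 819.0
        lo, hi = post.interval("baseline_hba1c")
        assert lo < 8.0 < hi or abs(post.median("baseline_hba1c") - 8.0) < 0.1
        assert post.median("sigma") == pytest.approx(0.25, abs=0.05)

    def test_repeated_recovery_covers_truth(self):
        # repeated small experiments: the 95% interval should cover the
        # generating fixed effects in most runs
        from empasim import population
        hits = 0
        for rep in range(3):
            design = population.StudyDesign("EASE2", (0.0, 10.0, 25.0), 52, 150)
            pats = population.sample_population(design, seed=60 + rep)
            obs = population.generate_observations(pats, "MEASE2", MEase2Params(),
                                                   design, seed=70 + rep)
            obs = obs.merge(pats[["id", "hba1c0", "egfr", "modality_csii"]],
                            left_on="ID", right_on="id")
            post = fit_nuts(obs, pats[["id", "auc_ss"]], chains=2, warmup=250,
                            draws=400, seed=80 + rep)
            ok = True
            for name, truth in [("baseline_hba1c", 8.0), ("emax", 0.579),
                                ("placebo_slope", 2.61e-5)]:
                lo, hi = post.interval(name, 0.95)
                ok &= lo <= truth <= hi
            hits += ok
        assert hits >= 2
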