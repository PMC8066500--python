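"""Semi-mechanistic insulin -> glucose -> HbA1c exposure-response model.

The chain is a set of direct-effect (steady-state) models driven by the
individual steady-state exposure ``AUC_ss``:

* insulin: ``TDID = TDID0 * Inc * (1 - Emax_T * AUC/(AUC50_T + AUC))``,
  where the amplitude scale ``Inc`` applies only during the first week of
  the short phase-II study;
* glucose: ``MDG = MDG0 * (TDID/TDID0)**gamma + PBO * t
  - Emax_M * AUC/(AUC50_M + AUC)``, i.e. insulin down-titration feeds back
  on glucose through the power ``gamma``, a linear placebo drift acts on
  MDG, and the drug lowers MDG directly through an Emax term;
* HbA1c: ``HbA1c = HbA1c0 * (MDG/MDG0)**theta_b * exp(eta2)``, with the
  typical baseline adjusted by a weight power and a sex multiplier.

``theta_b`` (the MDG -> HbA1c power) is not part of the published estimate
table; :func:`calibrate_theta_b` anchors it so the typical-value chain
reproduces the reported week-26 placebo-adjusted change for a chosen dose.

Estimation follows the original stepwise strategy: insulin first, then the
glucose sub-model with insulin parameters fixed, then HbA1c on the derived
individual MDG profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import reference
from .population import Endpoint, StudyDesign
from .reference import HOURS_PER_WEEK

EASE1_WEEK1 = "ease1_week1"


@dataclass(frozen=True)
class MEase1Params:
    """Parameters of the insulin -> glucose -> HbA1c chain.

    ``flip_gamma_sign`` negates the insulin-effect exponent in the glucose
    sub-model.  As printed, insulin down-titration lowers MDG, which makes
    a hypothetical stable-insulin regimen *less* effective on HbA1c than an
    adjusted regimen; the published simulations report the opposite
    ordering.  The printed form is the default; the flipped configuration
    reproduces the published stable > adjusted ordering qualitatively.
    """

    tdid0: float = 0.660            # IU/kg, typical baseline insulin dose
    inc: float = 1.15               # amplitude scale, EASE-1 week 1 only (not printed)
    emax_tdid: float = reference.MEASE1_ESTIMATES["emax_tdid"]
    auc50_tdid: float = reference.MEASE1_ESTIMATES["auc50_tdid"]
    mdg0: float = reference.MDG0_MEDIAN          # mg*day/dL, typical baseline MDG
    gamma: float = reference.MEASE1_ESTIMATES["gamma"]
    flip_gamma_sign: bool = False
    pbo_mdg: float = 0.01           # (mg*day/dL)/h placebo drift on MDG (not printed)
    emax_mdg: float = reference.MEASE1_ESTIMATES["emax_mdg"]
    auc50_mdg: float = reference.MEASE1_ESTIMATES["auc50_mdg"]
    hba1c0: float = reference.MEASE1_ESTIMATES["hba1c0"]
    theta_b: float = 0.0            # MDG -> HbA1c power; calibrated, not printed
    wt_hba1c: float = reference.MEASE1_ESTIMATES["wt_hba1c"]
    sex_hba1c: float = reference.MEASE1_ESTIMATES["sex_hba1c"]
    ref_weight: float = 82.0
    eta2_sd: float = 0.0            # log-scale SD of the HbA1c random effect

    def __post_init__(self) -> None:
        if not (0.0 <= self.emax_tdid < 1.0):
            raise ValueError("emax_tdid must be in [0, 1)")
        if self.auc50_tdid <= 0 or self.auc50_mdg <= 0:
            raise ValueError("AUC50 values must be positive")
        if self.emax_mdg < 0:
            raise ValueError("emax_mdg must be nonnegative")

    @property
    def gamma_eff(self) -> float:
        return -self.gamma if self.flip_gamma_sign else self.gamma

    @classmethod
    def reference(cls, calibrate: bool = True, **kw) -> "MEase1Params":
        """Published estimates; ``theta_b`` calibrated to the 10-mg result."""
        p = cls(**kw)
        if calibrate:
            p = replace(p, theta_b=calibrate_theta_b(
                reference.MEASE1_WEEK26_ADJUSTED[10.0], 10.0, p))
        return p


@dataclass
class MEase1Fit:
    """Result of one estimation step (or of the assembled chain)."""

    step: str
    estimates: dict
    cov: pd.DataFrame | None = None
    objective: float = np.nan
    converged: bool = False
    identifiable: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# structural model


def tdid_model(params: MEase1Params, auc_ss, study_phase: str = "maintenance"):
    """Insulin-dose ratio to baseline as a function of exposure."""
    auc = np.asarray(auc_ss, dtype=float)
    if np.any(auc < 0):
        raise ValueError("auc_ss must be nonnegative")
    inc = params.inc if study_phase == EASE1_WEEK1 else 1.0
    return inc * (1.0 - params.emax_tdid * auc / (params.auc50_tdid + auc))


def mdg_model(params: MEase1Params, tdid_ratio, auc_ss, t):
    """Cumulative mean daily glucose (mg*day/dL) at time ``t`` hours."""
    ratio = np.asarray(tdid_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("tdid_ratio must be positive")
    auc = np.asarray(auc_ss, dtype=float)
    out = (
        params.mdg0 * ratio**params.gamma_eff
        + params.pbo_mdg * np.asarray(t, dtype=float)
        - params.emax_mdg * auc / (params.auc50_mdg + auc)
    )
    if np.any(out <= 0):
        raise ValueError("MDG prediction is nonpositive; parameters or exposures misspecified")
    return out


def baseline_hba1c_individual(params: MEase1Params, weight=None, sexf=0):
    """Typical baseline HbA1c adjusted by weight power and sex multiplier."""
    base = params.hba1c0
    if weight is not None:
        base = base * (np.asarray(weight, dtype=float) / params.ref_weight) ** params.wt_hba1c
    return base * params.sex_hba1c ** np.asarray(sexf)


def hba1c_model(params: MEase1Params, mdg_ratio, weight=None, sexf=0, eta2=0.0):
    """HbA1c (%) given the MDG ratio to baseline."""
    ratio = np.asarray(mdg_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("mdg_ratio must be positive")
    return baseline_hba1c_individual(params, weight, sexf) * ratio**params.theta_b * np.exp(eta2)


def typical_chain_hba1c(params: MEase1Params, auc_ss: float, t_hours: float,
                        insulin_mode: str = "adjusted") -> float:
    """Typical-value HbA1c at ``t_hours`` for a given exposure.

    ``insulin_mode="stable"`` switches the drug effect on insulin off
    (the hypothetical no-down-titration scenario), so the TDID ratio is 1.
    """
    if insulin_mode == "stable":
        ratio = 1.0
    else:
        ratio = float(tdid_model(params, auc_ss))
    mdg = float(mdg_model(params, ratio, auc_ss, t_hours))
    return float(hba1c_model(params, mdg / params.mdg0))


def typical_placebo_adjusted(params: MEase1Params, auc_ss: float,
                             t_hours: float = 26 * HOURS_PER_WEEK,
                             insulin_mode: str = "adjusted") -> float:
    """Typical placebo-adjusted HbA1c change from baseline (%)."""
    active = typical_chain_hba1c(params, auc_ss, t_hours, insulin_mode)
    placebo = typical_chain_hba1c(params, 0.0, t_hours)
    return active - placebo


def calibrate_theta_b(
    target_change: float,
    target_dose: float,
    params: MEase1Params,
    t_weeks: float = 26.0,
    typical_auc_2p5: float = reference.TYPICAL_AUC_2P5,
) -> float:
    """Solve for the MDG -> HbA1c power reproducing a target drug effect.

    Finds ``theta_b`` in (0, 5) such that the typical-value week-``t_weeks``
    placebo-adjusted change at ``target_dose`` (dose-proportional exposure)
    equals ``target_change``.  A zero target gives exactly 0.
    """
    if target_change == 0.0:
        return 0.0
    auc = typical_auc_2p5 * target_dose / 2.5
    t = t_weeks * HOURS_PER_WEEK

    def f(theta_b: float) -> float:
        p = replace(params, theta_b=theta_b)
        return typical_placebo_adjusted(p, auc, t) - target_change

    lo, hi = 1e-12, 5.0
    if f(lo) * f(hi) > 0:
        raise ValueError("no root for theta_b in (0, 5); check target and parameters")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# synthetic-profile generation (used by population.generate_observations)


def structural_profiles(params: MEase1Params, patients: pd.DataFrame,
                        design: StudyDesign, visits: np.ndarray) -> dict:
    """Noise-free longitudinal predictions per endpoint for a population.

    Individual baselines come from the patient table (``tdid0``, ``mdg0``,
    ``hba1c0``); at time 0 every endpoint equals its individual baseline.
    Returns ``{endpoint: DataFrame(ID, TIME, DVID, DV, ARM)}``.
    """
    auc = patients["auc_ss"].to_numpy(dtype=float)
    n = len(patients)
    if design.tdid_daily:
        tdid_times = np.arange(0.0, design.duration_weeks * 7 * 24 + 1e-9, 24.0)
    else:
        tdid_times = visits
    out = {}

    def ratio_at(times: np.ndarray) -> np.ndarray:
        # (n, t) insulin ratio; Inc only in EASE-1 week 1; baseline visit = 1
        r = tdid_model(params, auc)[:, None] * np.ones((n, len(times)))
        if design.study_id == "EASE1" and params.inc != 1.0:
            wk1 = (times > 0) & (times <= HOURS_PER_WEEK)
            r[:, wk1] *= params.inc
        r[:, times == 0] = 1.0
        return r

    def frame(times, dvid, values):
        return pd.DataFrame({
            "ID": np.repeat(patients["id"].to_numpy(), len(times)),
            "TIME": np.tile(times, n),
            "DVID": dvid,
            "DV": values.ravel(),
            "ARM": np.repeat(patients["arm"].to_numpy(), len(times)),
        })

    r_tdid = ratio_at(tdid_times)
    out[Endpoint.TDID.value] = frame(
        tdid_times, Endpoint.TDID.value,
        patients["tdid0"].to_numpy()[:, None] * r_tdid)

    r_vis = ratio_at(visits)
    mdg0 = patients["mdg0"].to_numpy()[:, None]
    drug_mdg = (params.emax_mdg * auc / (params.auc50_mdg + auc))[:, None]
    post = (visits > 0)[None, :]
    # at t=0 the prediction is the baseline itself
    mdg = np.where(post,
                   mdg0 * r_vis**params.gamma_eff + params.pbo_mdg * visits[None, :] - drug_mdg,
                   mdg0)
    if np.any(mdg <= 0):
        raise ValueError("MDG prediction is nonpositive; parameters or exposures misspecified")
    out[Endpoint.MDG.value] = frame(visits, Endpoint.MDG.value, mdg)

    base = patients["hba1c0"].to_numpy()[:, None] * np.exp(
        patients.get("eta_hba1c", pd.Series(np.zeros(n))).to_numpy()[:, None])
    if "weight" in patients:
        base = base * ((patients["weight"].to_numpy()[:, None] / params.ref_weight)
                       ** params.wt_hba1c)
    if "sexf" in patients:
        base = base * params.sex_hba1c ** patients["sexf"].to_numpy(dtype=float)[:, None]
    hba1c = base * (mdg / mdg0) ** params.theta_b
    out[Endpoint.HBA1C.value] = frame(visits, Endpoint.HBA1C.value, hba1c)
    return out


# ---------------------------------------------------------------------------
# stepwise estimation


def _merge_exposures(data: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    ex = exposures.rename(columns={"id": "ID"})[["ID", "auc_ss"]]
    return data.merge(ex, on="ID", how="left")


def _baselines(rows: pd.DataFrame) -> pd.Series:
    base = rows[rows["TIME"] == 0].groupby("ID")["DV"].first()
    if base.empty:
        raise ValueError("no baseline (TIME == 0) records")
    return base


def fit_step1_tdid(data: pd.DataFrame, exposures: pd.DataFrame,
                   init: MEase1Params | None = None) -> MEase1Fit:
    """Step 1: exposure effect on insulin dose.

    Nonlinear least squares on the log insulin-dose ratio to the observed
    individual baseline, estimating ``Emax_T`` (logit scale), ``AUC50_T``
    (log scale) and, when phase-II week-1 records are present, ``Inc``.
    Placebo-only data leave the drug effect unidentifiable; this is flagged
    rather than silently returned.
    """
    init = init or MEase1Params()
    rows = data[data["DVID"] == Endpoint.TDID.value]
    if rows.empty:
        raise ValueError("no TDID records in data")
    rows = _merge_exposures(rows, exposures)
    base = _baselines(rows)
    act = rows[rows["TIME"] > 0].copy()
    act["base"] = act["ID"].map(base)
    act = act.dropna(subset=["base", "auc_ss"])
    y = np.log(act["DV"].to_numpy() / act["base"].to_numpy())
    auc = act["auc_ss"].to_numpy()
    if not np.any(auc > 0):
        return MEase1Fit("tdid", {"emax_tdid": np.nan, "auc50_tdid": np.nan},
                         converged=True, identifiable=False,
                         message="no exposure contrast: drug effect on TDID unidentifiable")
    wk1 = ((act.get("STUDY", pd.Series("", index=act.index)) == "EASE1")
           & (act["TIME"] <= HOURS_PER_WEEK)).to_numpy()
    fit_inc = bool(wk1.any())

    def resid(x):
        emax = 1.0 / (1.0 + np.exp(-x[0]))
        a50 = np.exp(x[1])
        pred = np.log1p(-emax * auc / (a50 + auc))
        if fit_inc:
            pred = pred + x[2] * wk1
        return y - pred

    x0 = [np.log(init.emax_tdid / (1 - init.emax_tdid)), np.log(init.auc50_tdid)]
    if fit_inc:
        x0.append(np.log(init.inc))
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
    emax = 1.0 / (1.0 + np.exp(-sol.x[0]))
    est = {"emax_tdid": float(emax), "auc50_tdid": float(np.exp(sol.x[1]))}
    names = ["logit_emax_tdid", "log_auc50_tdid"]
    if fit_inc:
        est["inc"] = float(np.exp(sol.x[2]))
        names.append("log_inc")
    cov = _ls_covariance(sol, names)
    return MEase1Fit("tdid", est, cov, float(sol.cost), bool(sol.success),
                     message=sol.message)


def _ls_covariance(sol, names) -> pd.DataFrame | None:
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(sol.fun.size - len(names), 1)
        cov = np.linalg.inv(jtj) * (2 * sol.cost / dof)
        return pd.DataFrame(cov, index=names, columns=names)
    except np.linalg.LinAlgError:
        return None


def fit_step2_mdg(data: pd.DataFrame, exposures: pd.DataFrame, step1: MEase1Fit,
                  init: MEase1Params | None = None) -> MEase1Fit:
    """Step 2: glucose sub-model with the insulin effect fixed from step 1.

    The linear placebo drift is estimated from placebo MDG records; the
    insulin-effect power ``gamma`` and the drug Emax/AUC50 on MDG are then
    estimated from active-arm records (proportional residuals) with the
    step-1 insulin parameters held fixed.
    """
    if not step1.converged:
        raise ValueError("step 1 did not converge")
    init = init or MEase1Params()
    p1 = replace(init, emax_tdid=step1.estimates["emax_tdid"],
                 auc50_tdid=step1.estimates["auc50_tdid"]) if step1.identifiable else init
    rows = _merge_exposures(data[data["DVID"] == Endpoint.MDG.value], exposures)
    if rows.empty:
        raise ValueError("no MDG records in data")
    base = _baselines(rows)
    rows = rows[rows["TIME"] > 0].copy()
    rows["base"] = rows["ID"].map(base)
    rows = rows.dropna(subset=["base"])

    plc = rows[rows["auc_ss"] == 0]
    if plc.empty:
        raise ValueError("no placebo MDG records; placebo drift not estimable")
    t = plc["TIME"].to_numpy()
    pbo = float(np.sum(t * (plc["DV"].to_numpy() - plc["base"].to_numpy())) / np.sum(t * t))

    act = rows[rows["auc_ss"] > 0]
    if act.empty:
        return MEase1Fit("mdg", {"pbo_mdg": pbo}, converged=True, identifiable=False,
                         message="no active-arm MDG records: drug terms unidentifiable")
    auc = act["auc_ss"].to_numpy()
    y = act["DV"].to_numpy()
    b = act["base"].to_numpy()
    tt = act["TIME"].to_numpy()
    ratio = np.asarray(tdid_model(p1, auc))

    def resid(x):
        gamma, lemax, la50 = x
        pred = b * ratio**gamma + pbo * tt - np.exp(lemax) * auc / (np.exp(la50) + auc)
        return (y - pred) / np.maximum(pred, 1e-6)

    x0 = [init.gamma_eff, np.log(init.emax_mdg), np.log(init.auc50_mdg)]
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
    est = {"pbo_mdg": pbo, "gamma": float(sol.x[0]),
           "emax_mdg": float(np.exp(sol.x[1])), "auc50_mdg": float(np.exp(sol.x[2]))}
    cov = _ls_covariance(sol, ["gamma", "log_emax_mdg", "log_auc50_mdg"])
    return MEase1Fit("mdg", est, cov, float(sol.cost), bool(sol.success), message=sol.message)


def derive_mdg_ratio_profiles(params: MEase1Params, exposures: pd.DataFrame,
                              times: np.ndarray, baselines: pd.Series | None = None) -> pd.DataFrame:
    """Individual predicted MDG-to-baseline ratios at the given times."""
    recs = []
    base = baselines if baselines is not None else pd.Series(params.mdg0, index=exposures["id"])
    for pid, auc in zip(exposures["id"], exposures["auc_ss"]):
        b = float(base.loc[pid]) if pid in base.index else params.mdg0
        for t in times:
            if t == 0:
                ratio = 1.0
            else:
                r = float(tdid_model(params, auc))
                mdg = b * r**params.gamma_eff + params.pbo_mdg * t \
                    - params.emax_mdg * auc / (params.auc50_mdg + auc)
                ratio = mdg / b
            recs.append((pid, float(t), ratio))
    return pd.DataFrame(recs, columns=["ID", "TIME", "mdg_ratio"])


def fit_step3_hba1c(data: pd.DataFrame, mdg_profiles: pd.DataFrame,
                    init: MEase1Params | None = None) -> MEase1Fit:
    """Step 3: HbA1c on derived individual MDG profiles.

    Linear mixed model on the log scale (random intercept per patient):
    ``log HbA1c = log HbA1c0 + wt * log(WT/82) + log(sexmult) * female
    + theta_b * log(MDG ratio) + b_i + eps``.  Weight/sex terms are included
    when the corresponding columns are present in ``data``.
    """
    init = init or MEase1Params()
    rows = data[data["DVID"] == Endpoint.HBA1C.value].merge(
        mdg_profiles, on=["ID", "TIME"], how="inner")
    if rows.empty:
        raise ValueError("no HbA1c records matching the MDG profiles")
    y = np.log(rows["DV"].to_numpy())
    cols = {"const": np.ones(len(rows)), "log_mdg_ratio": np.log(rows["mdg_ratio"].to_numpy())}
    if "weight" in rows.columns:
        cols["log_wt"] = np.log(rows["weight"].to_numpy() / init.ref_weight)
    if "sexf" in rows.columns:
        cols["sexf"] = rows["sexf"].to_numpy(dtype=float)
    exog = pd.DataFrame(cols)
    import statsmodels.api as sm

    try:
        model = sm.MixedLM(y, exog, groups=rows["ID"].to_numpy())
        res = model.fit(reml=True, method="lbfgs")
        params_hat = res.fe_params
        cov = pd.DataFrame(np.asarray(res.cov_params())[: len(cols), : len(cols)],
                           index=list(cols), columns=list(cols))
        eta2_var = float(np.asarray(res.cov_re).ravel()[0])
        sigma = float(np.sqrt(res.scale))
        converged = bool(res.converged)
    except Exception:  # singular random effects on noise-free data
        res = sm.OLS(y, exog).fit()
        params_hat = res.params
        cov = pd.DataFrame(np.asarray(res.cov_params()), index=list(cols), columns=list(cols))
        eta2_var = 0.0
        sigma = float(np.sqrt(res.scale))
        converged = True
    est = {
        "hba1c0": float(np.exp(params_hat["const"])),
        "theta_b": float(params_hat["log_mdg_ratio"]),
        "eta2_sd": float(np.sqrt(max(eta2_var, 0.0))),
        "sigma_log": sigma,
    }
    if "log_wt" in cols:
        est["wt_hba1c"] = float(params_hat["log_wt"])
    if "sexf" in cols:
        est["sex_hba1c"] = float(np.exp(params_hat["sexf"]))
    return MEase1Fit("hba1c", est, cov, converged=converged)


def combine_fits(step1: MEase1Fit, step2: MEase1Fit, step3: MEase1Fit) -> MEase1Fit:
    """Assemble the full chain fit with a block-diagonal covariance."""
    est = {**step1.estimates, **step2.estimates, **step3.estimates}
    blocks = [f.cov for f in (step1, step2, step3) if f.cov is not None]
    if blocks:
        names = [n for c in blocks for n in c.index]
        cov = pd.DataFrame(0.0, index=names, columns=names)
        for c in blocks:
            cov.loc[c.index, c.columns] = c.values
    else:
        cov = None
    return MEase1Fit("full", est, cov,
                     converged=all(f.converged for f in (step1, step2, step3)),
                     identifiable=all(f.identifiable for f in (step1, step2, step3)))
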