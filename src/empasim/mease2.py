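"""Descriptive Bayesian Emax exposure-response model for HbA1c.

Structural model for patient *i* at time *t* (hours):

.. math::

    HbA1c_{ij} = B_i - E_i \\cdot \\frac{AUC_{ss,i}}{AUC_{50} + AUC_{ss,i}}
                 + \\theta_d c_i t,

with individual baseline ``B_i = theta_a * g_i * exp(eta_z)`` and
individual maximal effect ``E_i = theta_c * h_i * exp(eta_s)`` where
``g_i``/``h_i`` are products of covariate powers/multipliers relative to a
reference patient and the etas are log-normal inter-individual random
effects.  The placebo drift is linear in time with a multiplier ``c_i`` for
pump (CSII) users.  The additive (percentage-point) Emax form is the
primary model; a proportional variant exists behind a flag for comparison.

Estimation is Bayesian: an informative log-normal prior on ``AUC50``
(location 704 nmol*h/L, from a type-2-diabetes analysis) and weak priors
elsewhere, sampled with the in-package No-U-Turn sampler.  The sampler
targets the marginal likelihood obtained by moment-matching the log-normal
random effects to a per-patient multivariate Gaussian (a first-order
marginalization, exact in the mean/covariance of the random effects); its
gradient is analytic.  See ``docs/methods.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc, reference
from .population import Endpoint


def derive_covariate_exponents() -> dict:
    """Back-solve the covariate coefficients from reported effect ranges.

    The baseline-HbA1c and eGFR powers on Emax follow from the reported
    relative Emax increases over the observed covariate ranges
    (``exponent = log(increase) / log(high/low)``); the CSII multiplier on
    the placebo slope is reported directly.
    """
    lo_h, hi_h = reference.EMAX_HBA1C_RANGE
    lo_g, hi_g = reference.EMAX_EGFR_RANGE
    return {
        "hba1c_on_emax": float(np.log(reference.EMAX_HBA1C_INCREASE) / np.log(hi_h / lo_h)),
        "egfr_on_emax": float(np.log(reference.EMAX_EGFR_INCREASE) / np.log(hi_g / lo_g)),
        "csii_on_placebo": reference.CSII_PLACEBO_MULTIPLIER,
    }


_DERIVED = derive_covariate_exponents()


@dataclass(frozen=True)
class MEase2Params:
    """Parameters of the descriptive Emax model (reference-patient scale).

    Reference patient: male, MDI insulin, baseline TDID 0.660 IU/kg,
    baseline HbA1c 8.1%, eGFR 98, weight 82 kg.  Covariate coefficients
    other than the three derivable from the reported effect ranges are
    null (their published values are not available).
    """

    baseline: float = reference.MEASE2_ESTIMATES["baseline_hba1c"]   # %, theta_a
    auc50: float = reference.MEASE2_ESTIMATES["auc50"]               # nmol*h/L, theta_b
    emax: float = reference.MEASE2_ESTIMATES["emax"]                 # %, theta_c
    placebo_slope: float = reference.MEASE2_ESTIMATES["placebo_slope"]  # %/h, theta_d
    hba1c_on_emax: float = _DERIVED["hba1c_on_emax"]
    egfr_on_emax: float = _DERIVED["egfr_on_emax"]
    csii_on_placebo: float = _DERIVED["csii_on_placebo"]
    ref_hba1c: float = 8.1
    ref_egfr: float = 98.0
    omega_baseline: float = 0.0707   # log-scale SD of eta_z
    omega_emax: float = 0.25         # log-scale SD of eta_s
    sigma: float = 0.25              # additive residual SD, %
    proportional: bool = False       # proportional Emax variant (comparison only)

    def __post_init__(self) -> None:
        if self.auc50 <= 0:
            raise ValueError("auc50 must be positive")
        if self.emax < 0:
            raise ValueError("emax must be nonnegative")

    @classmethod
    def reference(cls, **kw) -> "MEase2Params":
        return cls(**kw)


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration, centered on the informative AUC50 prior.

    ``variance_inflation`` scales the prior *variance* on log-AUC50
    (0 fixes AUC50 to the location; 1 is the final-model default);
    ``noninformative`` replaces it by an essentially flat prior.
    """

    auc50_location: float = reference.AUC50_PRIOR_LOCATION
    auc50_log_sd: float = 0.25
    variance_inflation: float = 1.0
    noninformative: bool = False
    # weak priors for the remaining parameters, (mean, sd) on the sampled scale
    baseline_log: tuple = (np.log(8.1), 1.0)
    emax_log: tuple = (np.log(0.5), 1.5)
    placebo_slope_e4: tuple = (0.0, 10.0)       # on theta_d * 1e4
    omega_baseline_log: tuple = (np.log(0.10), 1.0)
    omega_emax_log: tuple = (np.log(0.25), 1.0)
    sigma_log: tuple = (np.log(0.25), 1.0)

    def __post_init__(self) -> None:
        if self.variance_inflation < 0:
            raise ValueError("variance_inflation must be nonnegative")

    @property
    def auc50_fixed(self) -> bool:
        return self.variance_inflation == 0 and not self.noninformative

    @property
    def auc50_effective_sd(self) -> float:
        if self.noninformative:
            return 10.0
        return self.auc50_log_sd * np.sqrt(self.variance_inflation)


# ---------------------------------------------------------------------------
# structural predictions


def _get(covariates, key, default):
    if hasattr(covariates, "get"):
        v = covariates.get(key, default)
        return default if v is None else v
    return getattr(covariates, key, default)


def emax_individual(params: MEase2Params, covariates, eta_s=0.0):
    """Individual maximal HbA1c decrease (%), covariates at patient values."""
    h = np.asarray(_get(covariates, "hba1c0", params.ref_hba1c), dtype=float)
    g = np.asarray(_get(covariates, "egfr", params.ref_egfr), dtype=float)
    if np.any(h <= 0) or np.any(g <= 0):
        raise ValueError("continuous covariates must be positive")
    return (params.emax
            * (h / params.ref_hba1c) ** params.hba1c_on_emax
            * (g / params.ref_egfr) ** params.egfr_on_emax
            * np.exp(eta_s))


def baseline_individual(params: MEase2Params, covariates=None, eta_z=0.0):
    """Individual model-based baseline HbA1c (%); baseline covariate powers
    are null by default, so this is the typical value times ``exp(eta_z)``."""
    return params.baseline * np.exp(eta_z)


def placebo_slope_individual(params: MEase2Params, covariates):
    csii = np.asarray(_get(covariates, "modality_csii", 0))
    return params.placebo_slope * params.csii_on_placebo**csii


def predict_hba1c(params: MEase2Params, covariates, auc_ss, t, etas=(0.0, 0.0)):
    """HbA1c (%) at time ``t`` hours: baseline - Emax term + placebo drift."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    auc = np.asarray(auc_ss, dtype=float)
    eta_z, eta_s = etas
    base = baseline_individual(params, covariates, eta_z)
    drug = emax_individual(params, covariates, eta_s) * auc / (params.auc50 + auc)
    if params.proportional:
        drug = drug / 100.0 * base
    return base - drug + placebo_slope_individual(params, covariates) * t


def structural_hba1c(params: MEase2Params, patients: pd.DataFrame,
                     times: np.ndarray) -> pd.DataFrame:
    """Noise-free HbA1c profiles for a virtual population.

    The individual baseline is the patient's sampled baseline-HbA1c
    covariate (its spread plays the role of ``exp(eta_z)``); the individual
    Emax uses the patient's covariates and ``eta_emax``.  The drug term is
    absent at the baseline visit (t = 0).
    """
    n = len(patients)
    times = np.asarray(times, dtype=float)
    base = patients["hba1c0"].to_numpy(dtype=float)
    eta_s = patients["eta_emax"].to_numpy(dtype=float) if "eta_emax" in patients else 0.0
    emax_i = emax_individual(params, patients, eta_s)
    auc = patients["auc_ss"].to_numpy(dtype=float)
    drug = emax_i * auc / (params.auc50 + auc)
    if params.proportional:
        drug = drug / 100.0 * base
    slope = np.asarray(placebo_slope_individual(params, patients), dtype=float)
    post = (times > 0).astype(float)[None, :]
    values = (base[:, None]
              - drug[:, None] * post
              + slope[:, None] * times[None, :])
    return pd.DataFrame({
        "ID": np.repeat(patients["id"].to_numpy(), len(times)),
        "TIME": np.tile(times, n),
        "DVID": Endpoint.HBA1C.value,
        "DV": values.ravel(),
        "ARM": np.repeat(patients["arm"].to_numpy(), len(times)),
    })


# ---------------------------------------------------------------------------
# joint log density (explicit, with random effects)


def log_density(params: MEase2Params, data: pd.DataFrame, exposures: pd.DataFrame,
                priors: PriorSpec, etas: pd.DataFrame | None = None) -> float:
    """Joint log density: observation likelihood + random effects + priors.

    ``etas`` is an optional per-patient frame (columns ``id``, ``eta_z``,
    ``eta_s``); omitted etas are zero.  Gaussian additive residual on the
    HbA1c percentage scale.  The AUC50 prior is evaluated on the log scale,
    so for finite variance and location L its mode in AUC50 is exactly L.
    """
    rows = data[data["DVID"] == Endpoint.HBA1C.value]
    if rows.empty:
        raise ValueError("data contains no HbA1c records")
    rows = rows.merge(exposures.rename(columns={"id": "ID"})[["ID", "auc_ss"]],
                      on="ID", how="left")
    if rows[["DV", "TIME", "auc_ss"]].isna().any().any():
        raise ValueError("NaN in data or unmatched exposures")
    ez = es = None
    if etas is not None:
        ez = rows["ID"].map(etas.set_index("id")["eta_z"]).to_numpy()
        es = rows["ID"].map(etas.set_index("id")["eta_s"]).to_numpy()
    else:
        ez = np.zeros(len(rows))
        es = np.zeros(len(rows))
    t = rows["TIME"].to_numpy(dtype=float)
    auc = rows["auc_ss"].to_numpy(dtype=float)
    base = params.baseline * np.exp(ez)
    emax_i = emax_individual(params, rows, es)
    csii = rows["modality_csii"].to_numpy() if "modality_csii" in rows else 0
    slope = params.placebo_slope * params.csii_on_placebo**np.asarray(csii)
    pred = base - emax_i * auc / (params.auc50 + auc) * (t > 0) + slope * t
    resid = rows["DV"].to_numpy(dtype=float) - pred
    n = resid.size
    ll = -0.5 * n * np.log(2 * np.pi * params.sigma**2) - 0.5 * np.sum(resid**2) / params.sigma**2

    if etas is not None:
        per = etas
        for col, om in [("eta_z", params.omega_baseline), ("eta_s", params.omega_emax)]:
            if om > 0:
                ll += np.sum(-0.5 * np.log(2 * np.pi * om**2) - 0.5 * per[col].to_numpy()**2 / om**2)

    def nlogpdf(x, m, s):
        return -0.5 * np.log(2 * np.pi * s**2) - 0.5 * (x - m) ** 2 / s**2

    if not priors.auc50_fixed:
        ll += nlogpdf(np.log(params.auc50), np.log(priors.auc50_location),
                      priors.auc50_effective_sd)
    ll += nlogpdf(np.log(params.baseline), *priors.baseline_log)
    ll += nlogpdf(np.log(params.emax), *priors.emax_log) if params.emax > 0 else -np.inf
    ll += nlogpdf(params.placebo_slope * 1e4, *priors.placebo_slope_e4)
    return float(ll)


# ---------------------------------------------------------------------------
# marginal likelihood on per-patient sufficient statistics


class _SuffStats:
    """Per-patient sufficient statistics of the HbA1c records.

    The marginal likelihood is Gaussian per patient with a rank-2
    (baseline + drug random effect) plus diagonal covariance; every
    bilinear form it needs reduces to the scalar sums stored here.
    """

    def __init__(self, data: pd.DataFrame, exposures: pd.DataFrame,
                 template: MEase2Params):
        rows = data[data["DVID"] == Endpoint.HBA1C.value].copy()
        if rows.empty:
            raise ValueError("data contains no HbA1c records")
        rows = rows.merge(exposures.rename(columns={"id": "ID"})[["ID", "auc_ss"]],
                          on="ID", how="left")
        if rows["auc_ss"].isna().any():
            raise ValueError("exposures missing for some patients")
        csii = rows["modality_csii"].to_numpy(dtype=float) if "modality_csii" in rows else np.zeros(len(rows))
        rows["_tau"] = rows["TIME"] * template.csii_on_placebo**csii
        rows["_m"] = (rows["TIME"] > 0).astype(float)
        y = rows["DV"].to_numpy(dtype=float)
        rows["_y"] = y
        rows["_my"] = rows["_m"] * y
        rows["_ty"] = rows["_tau"] * y
        rows["_yy"] = y * y
        rows["_mt"] = rows["_m"] * rows["_tau"]
        rows["_tt"] = rows["_tau"] ** 2
        g = rows.groupby("ID", sort=True)
        agg = g.agg(
            k=("_y", "size"), Sm=("_m", "sum"), Sy=("_y", "sum"), My=("_my", "sum"),
            Ty=("_ty", "sum"), yy=("_yy", "sum"), St=("_tau", "sum"), Mt=("_mt", "sum"),
            tt=("_tt", "sum"), auc=("auc_ss", "first"),
        )
        first = g.first()
        h = np.ones(len(agg))
        if "hba1c0" in rows:
            h = h * (first["hba1c0"].to_numpy(dtype=float) / template.ref_hba1c) ** template.hba1c_on_emax
        if "egfr" in rows:
            h = h * (first["egfr"].to_numpy(dtype=float) / template.ref_egfr) ** template.egfr_on_emax
        self.h = h
        self.g = np.ones(len(agg))  # baseline covariate multiplier (null model)
        for name in ("k", "Sm", "Sy", "My", "Ty", "yy", "St", "Mt", "tt", "auc"):
            setattr(self, name, agg[name].to_numpy(dtype=float))
        self.n_patients = len(agg)
        self.n_obs = int(self.k.sum())
        self.ids = agg.index.to_numpy()


def _marginal_logp_grad(x: np.ndarray, ss: _SuffStats, priors: PriorSpec,
                        fixed_log_auc50: float | None = None):
    """Marginal log posterior and gradient in the sampled coordinates.

    Coordinates: ``[log theta_a, log AUC50, log theta_c, theta_d*1e4,
    log omega_z, log omega_s, log sigma]`` (log-AUC50 omitted when the
    prior variance is fixed to zero).
    """
    if fixed_log_auc50 is None:
        lta, lA, ltc, td4, lwz, lws, lsg = x
    else:
        lta, ltc, td4, lwz, lws, lsg = x
        lA = fixed_log_auc50
    # reject numerically hopeless regions (exp overflow in the moment matching)
    if np.max(np.abs(x)) > 30 or lwz > 1.0 or lws > 1.5 or lsg > 3.0:
        return -np.inf, np.zeros_like(x)
    ta, A, tc = np.exp(lta), np.exp(lA), np.exp(ltc)
    td = td4 * 1e-4
    wz, ws, sg = np.exp(lwz), np.exp(lws), np.exp(lsg)
    s2 = sg * sg

    kz = np.exp(0.5 * wz * wz)
    ks = np.exp(0.5 * ws * ws)
    Vz = np.exp(2 * wz * wz) - np.exp(wz * wz)
    Vs = np.exp(2 * ws * ws) - np.exp(ws * ws)

    k, Sm, Sy, My, Ty, yy = ss.k, ss.Sm, ss.Sy, ss.My, ss.Ty, ss.yy
    St, Mt, tt, auc = ss.St, ss.Mt, ss.tt, ss.auc
    g, h = ss.g, ss.h

    w = auc / (A + auc)
    mB = ta * g * kz
    mE = tc * h * ks
    vB = (ta * g) ** 2 * Vz
    vE = (tc * h) ** 2 * Vs

    # inner products with the mean vector mu = mB*1 - mE*w*m + td*tau
    one_mu = mB * k - mE * w * Sm + td * St
    m_mu = mB * Sm - mE * w * Sm + td * Mt
    tau_mu = mB * St - mE * w * Mt + td * tt
    y_mu = mB * Sy - mE * w * My + td * Ty
    mu_mu = (mB**2 * k + (mE * w) ** 2 * Sm + td**2 * tt
             - 2 * mB * mE * w * Sm + 2 * mB * td * St - 2 * mE * w * td * Mt)

    rr = yy - 2 * y_mu + mu_mu
    R1 = Sy - one_mu                  # 1' r
    Rw = w * (My - m_mu)              # wvec' r
    Rt = Ty - tau_mu                  # tau' r

    # Woodbury pieces: Sigma = vB 11' + vE wvec wvec' + s2 I
    # M = I + V A2/s2, A2 = [[k, w Sm], [w Sm, w^2 Sm]], N = M^{-1} V
    a11 = 1.0 + vB * k / s2
    a12 = vB * w * Sm / s2
    a21 = vE * w * Sm / s2
    a22 = 1.0 + vE * w * w * Sm / s2
    detM = a11 * a22 - a12 * a21
    N11 = a22 * vB / detM
    N12 = -a12 * vE / detM
    N22 = a11 * vE / detM

    def bilin(p1x, p2x, p1y, p2y, raw):
        # x' Sigma^{-1} y from F-projections and the raw inner product:
        # Sigma^{-1} = (I - F N F'/s2)/s2 with N = M^{-1} V
        corr = p1x * (N11 * p1y + N12 * p2y) + p2x * (N12 * p1y + N22 * p2y)
        return (raw - corr / s2) / s2

    F1r, F2r = R1, Rw
    F1o, F2o = k, w * Sm              # F' 1
    F1w, F2w = w * Sm, w * w * Sm     # F' wvec
    F1t, F2t = St, w * Mt             # F' tau

    quad = bilin(F1r, F2r, F1r, F2r, rr)
    S_u = bilin(F1o, F2o, F1r, F2r, R1)
    W_u = bilin(F1w, F2w, F1r, F2r, Rw)
    T_u = bilin(F1t, F2t, F1r, F2r, Rt)
    Q11 = bilin(F1o, F2o, F1o, F2o, k)
    Qww = bilin(F1w, F2w, F1w, F2w, w * w * Sm)

    tr_NA2 = (N11 * k + N12 * w * Sm) + (N12 * w * Sm + N22 * w * w * Sm)
    tr_inv = (k - tr_NA2 / s2) / s2
    # u'u = r' Sigma^{-2} r
    Ng1 = N11 * F1r + N12 * F2r
    Ng2 = N12 * F1r + N22 * F2r
    gNg = F1r * Ng1 + F2r * Ng2
    gNA2Ng = (Ng1 * (k * Ng1 + w * Sm * Ng2) + Ng2 * (w * Sm * Ng1 + w * w * Sm * Ng2))
    uu = (rr - 2 * gNg / s2 + gNA2Ng / (s2 * s2)) / (s2 * s2)

    logdet = k * np.log(s2) + np.log(detM)
    ll = -0.5 * np.sum(k * np.log(2 * np.pi) + logdet + quad)

    DvB = -0.5 * (Q11 - S_u**2)
    DvE = -0.5 * (Qww - W_u**2)
    Ds2 = -0.5 * (tr_inv - uu)

    d_ta = np.sum(S_u * g * kz + DvB * 2 * ta * g * g * Vz)
    d_tc = np.sum(-W_u * h * ks + DvE * 2 * tc * h * h * Vs)
    d_td = np.sum(T_u)
    kzp = wz * kz
    Vzp = 4 * wz * np.exp(2 * wz * wz) - 2 * wz * np.exp(wz * wz)
    ksp = ws * ks
    Vsp = 4 * ws * np.exp(2 * ws * ws) - 2 * ws * np.exp(ws * ws)
    d_wz = np.sum(S_u * ta * g * kzp + DvB * (ta * g) ** 2 * Vzp)
    d_ws = np.sum(-W_u * tc * h * ksp + DvE * (tc * h) ** 2 * Vsp)
    d_s2 = np.sum(Ds2)
    d_A = np.sum((mE * W_u - 2 * vE * DvE) / (A + auc))

    grad_nat = {
        "lta": d_ta * ta, "lA": d_A * A, "ltc": d_tc * tc, "td4": d_td * 1e-4,
        "lwz": d_wz * wz, "lws": d_ws * ws, "lsg": d_s2 * 2 * s2,
    }

    # priors (normal on the sampled coordinates)
    prior_terms = [
        ("lta", lta, priors.baseline_log),
        ("ltc", ltc, priors.emax_log),
        ("td4", td4, priors.placebo_slope_e4),
        ("lwz", lwz, priors.omega_baseline_log),
        ("lws", lws, priors.omega_emax_log),
        ("lsg", lsg, priors.sigma_log),
    ]
    if fixed_log_auc50 is None:
        prior_terms.append(("lA", lA, (np.log(priors.auc50_location),
                                       priors.auc50_effective_sd)))
    for name, val, (m0, s0) in prior_terms:
        ll += -0.5 * np.log(2 * np.pi * s0**2) - 0.5 * (val - m0) ** 2 / s0**2
        grad_nat[name] -= (val - m0) / s0**2

    order = (["lta", "lA", "ltc", "td4", "lwz", "lws", "lsg"]
             if fixed_log_auc50 is None else ["lta", "ltc", "td4", "lwz", "lws", "lsg"])
    return float(ll), np.array([grad_nat[n] for n in order])


# ---------------------------------------------------------------------------
# posterior sampling


_PARAM_COLUMNS = ["baseline_hba1c", "auc50", "emax", "placebo_slope",
                  "omega_baseline", "omega_emax", "sigma"]


@dataclass
class PosteriorSamples:
    """Post-warm-up draws of the descriptive-model parameters.

    ``draws`` holds natural-scale columns plus ``chain``/``draw`` indices;
    convergence metadata (divergences, step sizes) is attached.
    """

    draws: pd.DataFrame
    n_chains: int
    n_draws: int
    warmup: int
    divergences: list
    seed: int
    priors: PriorSpec

    def to_arviz(self):
        import arviz as az
        post = {
            c: self.draws.pivot(index="chain", columns="draw", values=c).to_numpy()
            for c in _PARAM_COLUMNS
        }
        return az.from_dict(posterior=post)

    def median(self, name: str) -> float:
        return float(self.draws[name].median())

    def interval(self, name: str, level: float = 0.95):
        a = (1 - level) / 2
        q = self.draws[name].quantile([a, 1 - a])
        return float(q.iloc[0]), float(q.iloc[1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in _PARAM_COLUMNS:
            lo, hi = self.interval(c)
            rows.append({"parameter": c, "median": self.median(c), "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(rows)

    def param_draws(self, rng: np.random.Generator) -> MEase2Params:
        """One posterior draw as a parameter object (for simulation reuse)."""
        row = self.draws.iloc[int(rng.integers(len(self.draws)))]
        return MEase2Params(
            baseline=row["baseline_hba1c"], auc50=row["auc50"], emax=row["emax"],
            placebo_slope=row["placebo_slope"], omega_baseline=row["omega_baseline"],
            omega_emax=row["omega_emax"], sigma=row["sigma"],
        )


def fit_nuts(
    data: pd.DataFrame,
    exposures: pd.DataFrame,
    priors: PriorSpec = PriorSpec(),
    chains: int = 4,
    warmup: int = 500,
    draws: int = 1000,
    seed: int = 0,
    template: MEase2Params = MEase2Params(),
    target_accept: float = 0.8,
) -> PosteriorSamples:
    """Sample the posterior of the descriptive model with NUTS.

    Each chain starts from independently jittered initial estimates.  A
    divergence rate above 5% post-warm-up raises a warning (never
    swallowed).  Identical seeds give identical draws.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for convergence diagnostics")
    ss = _SuffStats(data, exposures, template)
    fixed_lA = np.log(priors.auc50_location) if priors.auc50_fixed else None

    def logp_grad(x):
        return _marginal_logp_grad(x, ss, priors, fixed_lA)

    # data-driven central initial values
    base0 = float(np.median(ss.Sy / np.maximum(ss.k, 1)))
    x_center = {
        "lta": np.log(max(base0, 1.0)), "lA": np.log(priors.auc50_location),
        "ltc": np.log(0.5), "td4": 0.3, "lwz": np.log(0.08),
        "lws": np.log(0.25), "lsg": np.log(0.3),
    }
    order = (["lta", "lA", "ltc", "td4", "lwz", "lws", "lsg"]
             if fixed_lA is None else ["lta", "ltc", "td4", "lwz", "lws", "lsg"])
    rng = np.random.default_rng(seed)
    inits = []
    for _ in range(chains):
        jit = {k: v + rng.normal(0.0, 0.15) for k, v in x_center.items()}
        inits.append(np.array([jit[n] for n in order]))
    scales = {"lta": 0.01, "lA": 0.2, "ltc": 0.1, "td4": 0.1,
              "lwz": 0.1, "lws": 0.3, "lsg": 0.05}
    init_inv_mass = np.array([scales[n] ** 2 for n in order])

    chain_draws, results = mcmc.sample_chains(
        logp_grad, inits, n_warmup=warmup, n_draws=draws, seed=seed,
        target_accept=target_accept, init_inv_mass=init_inv_mass)

    frames = []
    for c in range(chains):
        x = chain_draws[c]
        cols = {n: x[:, i] for i, n in enumerate(order)}
        lA_col = cols["lA"] if fixed_lA is None else np.full(draws, fixed_lA)
        frames.append(pd.DataFrame({
            "chain": c, "draw": np.arange(draws),
            "baseline_hba1c": np.exp(cols["lta"]),
            "auc50": np.exp(lA_col),
            "emax": np.exp(cols["ltc"]),
            "placebo_slope": cols["td4"] * 1e-4,
            "omega_baseline": np.exp(cols["lwz"]),
            "omega_emax": np.exp(cols["lws"]),
            "sigma": np.exp(cols["lsg"]),
        }))
    div = [r.n_divergent for r in results]
    if sum(div) > 0.05 * chains * draws:
        warnings.warn(f"high divergence rate: {sum(div)} of {chains * draws} draws",
                      RuntimeWarning)
    return PosteriorSamples(pd.concat(frames, ignore_index=True), chains, draws,
                            warmup, div, seed, priors)
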