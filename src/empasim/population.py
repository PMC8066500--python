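"""Virtual EASE-like trial populations and synthetic longitudinal data.

Covariate distributions are fitted to published medians and 95% intervals
by quantile matching; patients are assembled into a ``PatientTable``
(a plain :class:`pandas.DataFrame`, one row per patient) and longitudinal
observations of HbA1c, mean daily glucose (MDG) and total daily insulin
dose (TDID) are generated from either exposure-response model plus a
residual-error model, yielding a long-format ``ObservationTable``.

All times are hours since first dose.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import exposure, reference
from .reference import HOURS_PER_WEEK


class Endpoint(str, enum.Enum):
    HBA1C = "HBA1C"   # %
    MDG = "MDG"       # mg*day/dL (cumulative over 24 h)
    TDID = "TDID"     # IU/kg
    CONC = "CONC"     # nmol/L


_Z95 = stats.norm.ppf(0.975)  # 1.959964...


def fit_distribution_from_quantiles(median: float, q_low: float, q_high: float, family: str):
    """Fit a two-parameter distribution to a median and a 95% interval.

    The returned frozen scipy distribution has the requested median exactly;
    the scale minimizes the squared error against the 2.5th/97.5th
    percentiles (for the log-normal this is on the log scale, giving
    ``sigma = log(q_high/q_low) / (2 * 1.96)``; the truncated normal is
    handled analogously on the natural scale with truncation at zero).
    """
    if not (q_low < median < q_high):
        raise ValueError("require q_low < median < q_high")
    if family in ("lognormal", "log-normal"):
        if q_low <= 0:
            raise ValueError("log-normal quantiles must be positive")
        sigma = np.log(q_high / q_low) / (2 * _Z95)
        return stats.lognorm(s=sigma, scale=median)
    if family in ("truncnorm", "normal-truncated"):
        sd = (q_high - q_low) / (2 * _Z95)
        a = (0.0 - median) / sd
        return stats.truncnorm(a, np.inf, loc=median, scale=sd)
    raise ValueError(f"unsupported family: {family!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """Sampling specification for one patient-level covariate.

    Continuous families are quantile-matched to (median, q_low, q_high);
    categorical covariates carry explicit category probabilities.
    """

    name: str
    family: str = "lognormal"
    median: float | None = None
    q_low: float | None = None
    q_high: float | None = None
    categories: tuple = ()
    probs: tuple = ()

    def __post_init__(self) -> None:
        if self.family == "categorical":
            if len(self.categories) != len(self.probs) or not self.categories:
                raise ValueError("categories and probs must align")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("probs must sum to 1")
        else:
            self.distribution()  # validates quantiles eagerly

    def distribution(self):
        return fit_distribution_from_quantiles(self.median, self.q_low, self.q_high, self.family)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "categorical":
            return rng.choice(np.asarray(self.categories), size=n, p=np.asarray(self.probs))
        return self.distribution().rvs(size=n, random_state=rng)


def default_covariate_specs(study_id: str) -> list[CovariateSpec]:
    """Published-demographics covariate specs for one study.

    Log-normal for weight, baseline TDID, baseline HbA1c and eGFR
    (right-skew implied by the published intervals), truncated normal for
    age, Bernoulli for sex (0.5 female) and insulin modality (64% MDI).
    """
    demo = reference.STUDY_DEMOGRAPHICS[study_id]
    specs = []
    for name, family in [
        ("age", "truncnorm"), ("weight", "lognormal"), ("egfr", "lognormal"),
        ("tdid0", "lognormal"), ("hba1c0", "lognormal"),
    ]:
        med, lo, hi = demo[name]
        specs.append(CovariateSpec(name, family, med, lo, hi))
    mdg_sigma = np.sqrt(np.log1p(reference.MDG0_CV**2))
    specs.append(CovariateSpec(
        "mdg0", "lognormal", reference.MDG0_MEDIAN,
        reference.MDG0_MEDIAN * np.exp(-_Z95 * mdg_sigma),
        reference.MDG0_MEDIAN * np.exp(_Z95 * mdg_sigma),
    ))
    specs.append(CovariateSpec("sexf", "categorical", categories=(0, 1), probs=(0.5, 0.5)))
    specs.append(CovariateSpec(
        "modality_csii", "categorical", categories=(0, 1),
        probs=(reference.MDI_FRACTION, 1.0 - reference.MDI_FRACTION),
    ))
    return specs


def _default_visit_weeks(duration_weeks: int) -> tuple:
    return tuple(w for w in (0, 4, 12, 26, 39, 52) if w <= duration_weeks)


@dataclass(frozen=True)
class StudyDesign:
    """Arm structure, duration and observation schedule of one trial."""

    study_id: str
    arms: tuple            # doses in mg; 0 = placebo
    duration_weeks: int
    n_patients: int
    visit_weeks: tuple = ()       # HbA1c/MDG visits
    tdid_daily: bool = True

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.visit_weeks:
            object.__setattr__(self, "visit_weeks", _default_visit_weeks(self.duration_weeks))

    @classmethod
    def from_reference(cls, study_id: str, n_patients: int | None = None) -> "StudyDesign":
        raw = reference.STUDY_DESIGNS[study_id]
        return cls(
            study_id=study_id,
            arms=tuple(raw["arms"]),
            duration_weeks=raw["duration_weeks"],
            n_patients=n_patients or raw["n_patients"],
        )

    @property
    def visit_hours(self) -> np.ndarray:
        return np.asarray(self.visit_weeks, dtype=float) * HOURS_PER_WEEK


@dataclass(frozen=True)
class IIVSpec:
    """Inter-individual variability switches for population assembly."""

    eta_emax_sd: float = 0.25     # log-scale SD on the individual Emax (descriptive model)
    eta_hba1c_sd: float = 0.0     # log-scale SD on HbA1c beyond the sampled baseline
    exposure_cv: float = reference.EXPOSURE_CV


def sample_population(
    design: StudyDesign,
    covariate_specs: list[CovariateSpec] | None = None,
    iiv: IIVSpec = IIVSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a virtual trial population (PatientTable).

    One row per patient with id, study, arm (dose in mg), covariates,
    individual random effects and individual steady-state exposure
    (``auc_ss``; exactly 0 on placebo).  Arms are allocated in equal
    proportions.  Reproducible: the same seed gives an identical table.
    """
    if covariate_specs is None:
        covariate_specs = default_covariate_specs(design.study_id)
    if not covariate_specs:
        raise ValueError("covariate_specs must be nonempty")
    rng = np.random.default_rng(seed)
    n = design.n_patients
    table = {"id": np.arange(n), "study": design.study_id}
    arms = np.asarray(design.arms, dtype=float)
    table["arm"] = arms[np.arange(n) % len(arms)]
    for spec in covariate_specs:
        table[spec.name] = spec.sample(n, rng)
    df = pd.DataFrame(table)
    df["eta_emax"] = rng.normal(0.0, iiv.eta_emax_sd, size=n) if iiv.eta_emax_sd > 0 else 0.0
    df["eta_hba1c"] = rng.normal(0.0, iiv.eta_hba1c_sd, size=n) if iiv.eta_hba1c_sd > 0 else 0.0
    df["auc_ss"] = 0.0
    for dose in arms[arms > 0]:
        mask = df["arm"] == dose
        draws = exposure.sample_auc_ss(int(mask.sum()), dose, cv=iiv.exposure_cv, seed=rng)
        df.loc[mask, "auc_ss"] = draws["auc_ss"].to_numpy()
    return df


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error magnitudes: additive (%) for HbA1c, proportional else."""

    hba1c_sd: float = 0.25
    mdg_cv: float = 0.05
    tdid_cv: float = 0.03


def generate_observations(
    patients: pd.DataFrame,
    generator: str,
    params,
    design: StudyDesign,
    error_model: ResidualSpec = ResidualSpec(),
    seed: int = 0,
    endpoints: tuple | None = None,
) -> pd.DataFrame:
    """Generate a long-format ObservationTable from a structural model.

    ``generator`` selects the structural model: ``"MEASE1"`` (insulin ->
    glucose -> HbA1c chain; produces TDID, MDG and HbA1c) or ``"MEASE2"``
    (direct Emax on HbA1c; produces HbA1c).  At time 0 the structural HbA1c
    equals the individual baseline (no drug term at the baseline visit);
    residual error is applied on top.  Reproducible given the seed.

    Columns: ID, TIME (h), DVID, DV, ARM (dose mg), STUDY.
    """
    from . import mease1 as m1
    from . import mease2 as m2

    rng = np.random.default_rng(seed)
    visits = design.visit_hours
    if visits.size == 0:
        raise ValueError("visit schedule must be nonempty")
    frames: list[pd.DataFrame] = []

    if generator == "MEASE2":
        endpoints = endpoints or (Endpoint.HBA1C,)
        if Endpoint.HBA1C in endpoints:
            pred = m2.structural_hba1c(params, patients, visits)
            frames.append(pred)
    elif generator == "MEASE1":
        endpoints = endpoints or (Endpoint.HBA1C, Endpoint.MDG, Endpoint.TDID)
        profiles = m1.structural_profiles(params, patients, design, visits)
        for ep in (Endpoint.TDID, Endpoint.MDG, Endpoint.HBA1C):
            if ep in endpoints:
                frames.append(profiles[ep.value])
    else:
        raise ValueError(f"unknown generator: {generator!r}")

    obs = pd.concat(frames, ignore_index=True)
    # residual error
    dv = obs["DV"].to_numpy(dtype=float, copy=True)
    for ep, kind, mag in [
        (Endpoint.HBA1C, "additive", error_model.hba1c_sd),
        (Endpoint.MDG, "proportional", error_model.mdg_cv),
        (Endpoint.TDID, "proportional", error_model.tdid_cv),
    ]:
        mask = (obs["DVID"] == ep.value).to_numpy()
        if mag > 0 and mask.any():
            eps = rng.normal(0.0, mag, size=int(mask.sum()))
            dv[mask] = dv[mask] + eps if kind == "additive" else dv[mask] * (1.0 + eps)
    obs["DV"] = dv
    obs["STUDY"] = design.study_id
    return obs.reset_index(drop=True)


def write_nonmem_csv(obs: pd.DataFrame, patients: pd.DataFrame, path) -> None:
    """Persist an ObservationTable as a NONMEM-style CSV.

    Columns ID, TIME, DV, DVID, AMT (dose in mg), MDV plus covariates
    merged from the patient table.
    """
    covs = [c for c in patients.columns if c not in ("id", "study")]
    merged = obs.merge(patients[["id"] + covs], left_on="ID", right_on="id", how="left")
    merged["AMT"] = merged["ARM"]
    merged["MDV"] = 0
    cols = ["ID", "TIME", "DV", "DVID", "AMT", "MDV"] + covs
    merged[cols].to_csv(path, index=False)


def read_nonmem_csv(path) -> pd.DataFrame:
    """Read an ObservationTable written by :func:`write_nonmem_csv`."""
    df = pd.read_csv(path)
    df["ARM"] = df["AMT"]
    return df
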