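"""Reference parameter set.

Published point estimates, 95% intervals, trial designs and demographic
summaries for the EASE empagliflozin type-1-diabetes program, used as the
ground truth of the synthetic-data generator and as the anchor of the
calibration and acceptance checks.

All exposures are steady-state AUCs in nmol*h/L, times are hours, HbA1c in
percent, MDG (mean daily glucose, cumulative over 24 h) in mg*day/dL and
TDID (total daily insulin dose) in IU/kg.
"""

from __future__ import annotations

HOURS_PER_WEEK = 168.0

# ---------------------------------------------------------------------------
# Descriptive Bayesian Emax model (M-EASE-2): posterior medians and 95% CIs.
# Reference patient: male, MDI insulin, baseline TDID 0.660 IU/kg,
# HbA1c 8.1%, eGFR 98 mL/min/1.73 m2, weight 82 kg.
MEASE2_ESTIMATES = {
    "baseline_hba1c": 8.14,      # %
    "auc50": 498.0,              # nmol*h/L
    "emax": 0.579,               # % (maximal HbA1c decrease, additive)
    "placebo_slope": 2.61e-5,    # %/h
}
MEASE2_CI = {
    "baseline_hba1c": (8.07, 8.22),
    "auc50": (296.0, 819.0),
    "emax": (0.491, 0.678),
    "placebo_slope": (1.96e-5, 3.29e-5),
}
MEASE2_REFERENCE_PATIENT = {
    "sexf": 0, "modality_csii": 0, "tdid0": 0.660,
    "hba1c0": 8.1, "egfr": 98.0, "weight": 82.0,
}

# Informative prior for AUC50 carried over from a type-2-diabetes
# exposure-response analysis of FPG/HbA1c.
AUC50_PRIOR_LOCATION = 704.0  # nmol*h/L

# Covariate effect summaries reported for the descriptive model: Emax rises
# 32% over the observed baseline-HbA1c range 7.2-9.5% and 50% over the eGFR
# range 54-120; CSII patients have a 47% larger placebo drift than MDI.
EMAX_HBA1C_RANGE = (7.2, 9.5)
EMAX_HBA1C_INCREASE = 1.32
EMAX_EGFR_RANGE = (54.0, 120.0)
EMAX_EGFR_INCREASE = 1.50
CSII_PLACEBO_MULTIPLIER = 1.47
MDI_FRACTION = 0.64

# ---------------------------------------------------------------------------
# Semi-mechanistic model (M-EASE-1): estimates and 95% CIs.
# Reference patient: male, eGFR 99, weight 82 kg, cumulative MDG 4266 mg*day/dL.
MEASE1_ESTIMATES = {
    "hba1c0": 8.15,          # %
    "auc50_tdid": 110.0,     # nmol*h/L
    "emax_tdid": 0.186,      # fraction of baseline TDID
    "auc50_mdg": 370.0,      # nmol*h/L
    "emax_mdg": 634.0,       # mg*day/dL
    "wt_hba1c": -0.0258,     # power of (weight/82) on baseline HbA1c
    "sex_hba1c": 0.99,       # multiplier on baseline HbA1c for females
    "gamma": 0.487,          # insulin-effect power linking TDID ratio to MDG
}
MEASE1_CI = {
    "hba1c0": (8.09, 8.21),
    "auc50_tdid": (14.3, 836.0),
    "emax_tdid": (0.145, 0.238),
    "auc50_mdg": (83.9, 1630.0),
    "emax_mdg": (534.0, 753.0),
    "wt_hba1c": (-0.0528, 0.00125),
    "sex_hba1c": (0.98, 1.0),
    "gamma": (0.445, 0.532),
}
MEASE1_REFERENCE_PATIENT = {"sexf": 0, "egfr": 99.0, "weight": 82.0, "mdg0": 4266.0}

# Week-26 placebo-adjusted HbA1c changes simulated with M-EASE-1 (adjusted
# insulin); the 10-mg value anchors the calibration of the unreported
# MDG->HbA1c power.
MEASE1_WEEK26_ADJUSTED = {2.5: -0.29, 10.0: -0.44, 25.0: -0.50}

# ---------------------------------------------------------------------------
# Trial designs and demographics: median (2.5th-97.5th percentile) per study.
STUDY_DESIGNS = {
    "EASE1": {"arms": [0.0, 2.5, 10.0, 25.0], "duration_weeks": 4, "n_patients": 75},
    "EASE2": {"arms": [0.0, 10.0, 25.0], "duration_weeks": 52, "n_patients": 721},
    "EASE3": {"arms": [0.0, 2.5, 10.0, 25.0], "duration_weeks": 26, "n_patients": 948},
}

STUDY_DEMOGRAPHICS = {
    "EASE1": {
        "age": (43.0, 21.7, 61.0),
        "weight": (79.0, 52.0, 107.0),
        "egfr": (102.0, 78.7, 128.0),
        "tdid0": (0.640, 0.361, 1.13),
        "hba1c0": (8.20, 7.18, 9.61),
    },
    "EASE2": {
        "age": (46.0, 21.0, 69.0),
        "weight": (84.0, 55.0, 126.0),
        "egfr": (97.0, 57.0, 127.0),
        "tdid0": (0.680, 0.370, 1.34),
        "hba1c0": (8.00, 7.20, 9.50),
    },
    "EASE3": {
        "age": (43.0, 21.0, 69.0),
        "weight": (81.0, 55.0, 121.0),
        "egfr": (99.0, 54.7, 129.0),
        "tdid0": (0.660, 0.360, 1.24),
        "hba1c0": (8.10, 7.20, 9.50),
    },
}

# Baseline cumulative MDG is not part of the published demographic table;
# the generator uses a log-normal centered on the reference value with a
# modest 15% CV (see docs/methods.md).
MDG0_MEDIAN = 4266.0
MDG0_CV = 0.15

# Typical steady-state exposure at the 2.5-mg dose (simulated 2.5-mg
# exposures were centered at the estimated AUC50).
TYPICAL_AUC_2P5 = 498.0
EXPOSURE_CV = 0.35

# Prior-sensitivity grid: variance inflation factors and alternate prior
# locations explored around the final informative AUC50 prior.
PRIOR_VARIANCE_GRID = {"fixed": 0.0, "base": 1.0, "x10": 10.0, "x50": 50.0, "x100": 100.0}
PRIOR_LOCATION_GRID = {
    "base": AUC50_PRIOR_LOCATION,
    "extreme_large": 22026.0,
    "extreme_small": 0.00005,
    "up50": 1.5 * AUC50_PRIOR_LOCATION,
    "down50": 0.5 * AUC50_PRIOR_LOCATION,
}
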