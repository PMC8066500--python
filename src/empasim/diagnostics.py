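"""Model-evaluation machinery.

Posterior/Monte-Carlo predictive checks summarized as longitudinal visual
predictive checks (VPCs), single-visit landmark checks, MCMC convergence
diagnostics (split-chain R-hat and effective sample size, via arviz) and a
patient-level nonparametric bootstrap for parameter precision.

Percentile convention: linear interpolation between order statistics
(numpy default), fixed package-wide; VPC binning is by nominal visit time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .population import Endpoint

DEFAULT_PERCENTILES = (2.5, 50.0, 97.5)


def _bin_percentiles(df: pd.DataFrame, percentiles) -> pd.DataFrame:
    g = df.groupby("TIME")["DV"]
    out = g.apply(lambda s: pd.Series(np.percentile(s, percentiles),
                                      index=[f"p{p:g}" for p in percentiles]))
    return out.unstack()


def ppc_vpc(
    observed: pd.DataFrame,
    simulate_fn,
    n_reps: int = 500,
    percentiles=DEFAULT_PERCENTILES,
    band: float = 95.0,
    endpoint: str = Endpoint.HBA1C.value,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive check summarized as a longitudinal VPC.

    ``simulate_fn(replicate_seed)`` must return an ObservationTable sharing
    the observed design.  For each nominal-time bin the observed
    percentiles are compared against the across-replicate band (central
    ``band``%) of the same simulated percentiles.  Empty observed bins are
    dropped with a warning.

    Returns one row per time bin with columns ``obs_p*``, ``sim_p*_lo``,
    ``sim_p*_med``, ``sim_p*_hi``.
    """
    obs = observed[observed["DVID"] == endpoint]
    if obs.empty:
        raise ValueError(f"no observed {endpoint} records")
    if obs["DV"].isna().any():
        warnings.warn("dropping bins with missing observations")
        obs = obs.dropna(subset=["DV"])
    obs_pct = _bin_percentiles(obs, percentiles)

    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    sims = []
    for s in seeds:
        rep = simulate_fn(int(s) % 2**31)
        rep = rep[rep["DVID"] == endpoint]
        sims.append(_bin_percentiles(rep, percentiles))
    stack = pd.concat(sims, keys=range(n_reps))

    a = (100.0 - band) / 2
    rows = {}
    for col in obs_pct.columns:
        rows[f"obs_{col}"] = obs_pct[col]
        per_rep = stack[col].unstack(level=0)  # index TIME, columns replicate
        rows[f"sim_{col}_lo"] = per_rep.quantile(a / 100, axis=1)
        rows[f"sim_{col}_med"] = per_rep.quantile(0.5, axis=1)
        rows[f"sim_{col}_hi"] = per_rep.quantile(1 - a / 100, axis=1)
    out = pd.DataFrame(rows)
    out.index.name = "TIME"
    return out.reset_index()


def landmark_check(observed: pd.DataFrame, vpc: pd.DataFrame, timepoint_weeks: float,
                   endpoint: str = Endpoint.HBA1C.value) -> pd.Series:
    """Observed-vs-simulated comparison at a single scheduled visit.

    ``vpc`` is the output of :func:`ppc_vpc` (shared machinery); the row at
    the requested visit is returned.  A visit absent from the schedule is
    an error.
    """
    t = timepoint_weeks * 168.0
    row = vpc[np.isclose(vpc["TIME"], t)]
    if row.empty:
        raise ValueError(f"timepoint week {timepoint_weeks} not in the VPC schedule")
    return row.iloc[0]


def _to_arviz_data(draws):
    import arviz as az
    from .mease2 import PosteriorSamples

    if isinstance(draws, PosteriorSamples):
        return draws.to_arviz()
    arr = np.asarray(draws)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    return az.from_dict(posterior={f"x{i}": arr[:, :, i] for i in range(arr.shape[2])})


def gelman_rubin(draws) -> pd.Series:
    """Split-chain R-hat per parameter (rank-normalized, via arviz).

    ``draws`` is either a :class:`~empasim.mease2.PosteriorSamples` or an
    array of shape (chains, draws[, params]); fewer than 2 chains is an
    error.  Parameters with zero variance (e.g. a prior-fixed AUC50) yield
    NaN and are left in place.
    """
    import arviz as az

    idata = _to_arviz_data(draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.rhat(idata)
    return pd.Series({v: float(res[v].values) for v in res.data_vars})


def effective_sample_size(draws) -> pd.Series:
    """Bulk effective sample size per parameter (via arviz)."""
    import arviz as az

    idata = _to_arviz_data(draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.ess(idata)
    return pd.Series({v: float(res[v].values) for v in res.data_vars})


def nonparametric_bootstrap(
    data: pd.DataFrame,
    fit_fn,
    n_iter: int = 250,
    seed: int = 0,
    id_col: str = "ID",
    ci: float = 95.0,
) -> dict:
    """Patient-level nonparametric bootstrap for parameter precision.

    Patients (all rows of an ID move together, preserving longitudinal
    dependence) are resampled with replacement; ``fit_fn(resampled)`` must
    return a mapping of parameter estimates.  Failed fits are excluded and
    counted.  Returns ``{"estimates": DataFrame, "ci": DataFrame,
    "n_failed": int}`` with percentile CIs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    ids = data[id_col].unique()
    indices = data.groupby(id_col).indices
    ests = []
    n_failed = 0
    for _ in range(n_iter):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = [indices[pid] for pid in chosen]
        boot = data.iloc[np.concatenate(parts)].reset_index(drop=True)
        boot[id_col] = np.repeat(np.arange(len(chosen)), [len(p) for p in parts])
        try:
            ests.append(dict(fit_fn(boot)))
        except Exception:
            n_failed += 1
    if not ests:
        raise RuntimeError("all bootstrap fits failed")
    est = pd.DataFrame(ests)
    a = (100.0 - ci) / 2
    ci_df = est.quantile([a / 100, 0.5, 1 - a / 100]).T
    ci_df.columns = ["lo", "median", "hi"]
    return {"estimates": est, "ci": ci_df, "n_failed": n_failed}
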