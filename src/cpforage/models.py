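"""The four hierarchical models linking foraging decisions to condition.

All four share one structure — fixed effects plus a per-bird random
intercept — and differ in response, family and year coding:

- ``M1_logrange``  gaussian, log(maximum range) per trip; treatment contrasts
  (reference year 2016, reference colony OBS).
- ``M2_outside``   Bernoulli-logit, trip outside the fjord (0/1); same
  contrasts.
- ``M3_firsttrip`` Bernoulli-logit, first trip after capture outside (0/1);
  body condition as covariate, per-year indicator columns (cell means).
- ``M4_bmc``       gaussian, relative body-mass change per bird; proportion
  of outside trips as covariate, per-year indicators.

The printed forms of M3/M4 carry an intercept alongside all three year
indicators, which is over-parameterised; the intercept column is dropped
here so the indicators are interpretable cell means.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from ._mcmc import MCMCSettings, PriorSpec, run_chains

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "MCMCSettings",
    "PriorSpec",
    "build_design",
    "MixedModel",
    "PosteriorFit",
    "diagnostics",
    "backtransform_median",
    "contrast",
    "posterior_predictive_check",
    "first_trip_table",
    "prepare_model_data",
]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    response: str  # source column
    family: str  # gaussian | bernoulli
    log_response: bool = False
    covariates: tuple = ()
    year_coding: str = "contrasts"  # contrasts | indicators
    group: str = "bird_id"

    def __post_init__(self):
        if self.family not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.log_response and self.family != "gaussian":
            raise ValueError("log response only makes sense for gaussian models")


MODEL_SPECS = {
    "M1_logrange": ModelSpec("M1_logrange", "max_range_km", "gaussian", log_response=True),
    "M2_outside": ModelSpec("M2_outside", "outside", "bernoulli"),
    "M3_firsttrip": ModelSpec(
        "M3_firsttrip", "firsttrip_outside", "bernoulli",
        covariates=("bc",), year_coding="indicators",
    ),
    "M4_bmc": ModelSpec(
        "M4_bmc", "bmc", "gaussian",
        covariates=("prop_outside",), year_coding="indicators",
    ),
}

REFERENCE_COLONY = "OBS"  # treatment-contrast reference when present


@dataclass(frozen=True)
class DesignInfo:
    columns: tuple
    years: tuple
    colonies: tuple
    year_coding: str
    covariates: tuple
    group_labels: tuple


def _design_matrix(df, spec, years, colonies):
    cols, names = [], []
    if spec.year_coding == "contrasts":
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for cv in spec.covariates:
        cols.append(df[cv].to_numpy(dtype=float))
        names.append(cv)
    if spec.year_coding == "contrasts":
        for yr in years[1:]:
            cols.append((df["year"] == yr).to_numpy(dtype=float))
            names.append(f"year{yr}")
    else:
        for yr in years:
            cols.append((df["year"] == yr).to_numpy(dtype=float))
            names.append(f"I(year{yr})")
    for col in colonies[1:]:
        cols.append((df["colony_id"] == col).to_numpy(dtype=float))
        names.append(f"colony_{col}")
    return np.column_stack(cols), tuple(names)


def build_design(spec: ModelSpec, data: pd.DataFrame):
    """Response vector, fixed-effect matrix and grouping index for a model.

    Rows with missing values in any used column are dropped.  Year levels
    come from the data (reference = earliest year under treatment contrasts);
    the reference colony is OBS when present.
    """
    used = [spec.response, "year", "colony_id", spec.group, *spec.covariates]
    df = data.dropna(subset=[c for c in used if c in data.columns]).copy()
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns for {spec.name}: {missing}")
    if len(df) == 0:
        raise ValueError("no complete rows for model")
    y = df[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y <= 0):
            raise ValueError("log response requires positive values")
        y = np.log(y)
    if spec.family == "bernoulli" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("bernoulli response must be coded 0/1")
    years = tuple(sorted(df["year"].unique()))
    colonies = sorted(df["colony_id"].unique())
    if REFERENCE_COLONY in colonies:
        colonies.remove(REFERENCE_COLONY)
        colonies.insert(0, REFERENCE_COLONY)
    colonies = tuple(colonies)
    X, names = _design_matrix(df, spec, years, colonies)
    groups, labels = pd.factorize(df[spec.group], sort=True)
    info = DesignInfo(
        columns=names,
        years=years,
        colonies=colonies,
        year_coding=spec.year_coding,
        covariates=spec.covariates,
        group_labels=tuple(labels),
    )
    return y, X, groups, info


@dataclass
class PosteriorFit:
    """MCMC output of one model with everything needed for post-processing."""

    spec: ModelSpec
    settings: MCMCSettings
    priors: PriorSpec
    info: DesignInfo
    draws: dict  # beta (C,D,p), tau (C,D), sigma (C,D) [gaussian], u (C,D,q)
    X: np.ndarray
    y: np.ndarray
    gidx: np.ndarray

    @property
    def param_names(self):
        names = list(self.info.columns) + ["sd_bird"]
        if self.spec.family == "gaussian":
            names.append("sd_resid")
        return names

    def _param_draws(self, name):
        cols = list(self.info.columns)
        if name in cols:
            return self.draws["beta"][:, :, cols.index(name)]
        if name == "sd_bird":
            return self.draws["tau"]
        if name == "sd_resid":
            return self.draws["sigma"]
        raise KeyError(name)

    def flat(self, name):
        return self._param_draws(name).reshape(-1)

    def design_rows(self, newdata: pd.DataFrame) -> np.ndarray:
        """Fixed-effect rows for new data, matching the fitted design."""
        unseen = set(newdata["colony_id"]) - set(self.info.colonies)
        if unseen:
            raise ValueError(f"unseen colony levels: {sorted(unseen)}")
        unseen_y = set(newdata["year"]) - set(self.info.years)
        if unseen_y:
            raise ValueError(f"unseen year levels: {sorted(unseen_y)}")
        X, _ = _design_matrix(newdata, self.spec, self.info.years, self.info.colonies)
        return X

    def linear_predictor(self, newdata: pd.DataFrame) -> np.ndarray:
        """Posterior draws of the population-level linear predictor (rows, draws)."""
        Xn = self.design_rows(newdata)
        beta = self.draws["beta"].reshape(-1, self.X.shape[1])
        return Xn @ beta.T


def fit(spec, data, priors=None, mcmc: MCMCSettings = MCMCSettings()) -> PosteriorFit:
    """Sample the posterior of a hierarchical model."""
    y, X, gidx, info = build_design(spec, data)
    if priors is None:
        priors = PriorSpec.auto(X, y, spec.family)
    draws = run_chains(spec.family, X, y, gidx, len(info.group_labels), priors, mcmc)
    return PosteriorFit(spec, mcmc, priors, info, draws, X, y, gidx)


class MixedModel:
    """Random-intercept mixed model with a Bayesian fit.

    Thin class front-end over :func:`fit`; holds the specification and MCMC
    configuration, and returns a :class:`PosteriorFit`.
    """

    def __init__(self, spec, priors=None, mcmc: MCMCSettings = MCMCSettings()):
        self.spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
        self.priors = priors
        self.mcmc = mcmc

    def fit(self, data: pd.DataFrame) -> PosteriorFit:
        return fit(self.spec, data, priors=self.priors, mcmc=self.mcmc)


def diagnostics(fit_result: PosteriorFit, rhat_max=1.1, ess_min=1000) -> pd.DataFrame:
    """Per-parameter posterior summary with split R-hat and bulk ESS.

    The returned frame's ``.attrs["convergence_ok"]`` is True iff every
    reported parameter satisfies both gates.
    """
    rows = []
    for name in fit_result.param_names:
        d = fit_result._param_draws(name)
        if d.shape[0] < 2:
            raise ValueError("R-hat requires at least 2 chains")
        data = az.convert_to_dataset({"x": d})
        rhat = float(az.rhat(data)["x"].values)
        ess = float(az.ess(data)["x"].values)
        flat = d.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": rhat,
                "ess": ess,
            }
        )
    out = pd.DataFrame(rows).set_index("parameter")
    out.attrs["convergence_ok"] = bool(
        (out["rhat"] < rhat_max).all() and (out["ess"] > ess_min).all()
    )
    return out


def backtransform_median(fit_result: PosteriorFit, newdata: pd.DataFrame) -> pd.DataFrame:
    """Response-scale predictions for a gaussian-on-log model.

    Exponentiates the posterior draws of the linear predictor per row of
    ``newdata`` and summarises by the median and central 95% interval; the
    median of exp(draws) is the median of the response distribution on the
    original scale.
    """
    if not (fit_result.spec.family == "gaussian" and fit_result.spec.log_response):
        raise ValueError("backtransform_median applies to gaussian-on-log models only")
    pred = np.exp(fit_result.linear_predictor(newdata))
    med = np.median(pred, axis=1)
    lo, hi = np.percentile(pred, [2.5, 97.5], axis=1)
    return pd.DataFrame({"median": med, "q2.5": lo, "q97.5": hi}, index=newdata.index)


def _response_scale(fit_result, eta):
    if fit_result.spec.family == "bernoulli":
        return 1.0 / (1.0 + np.exp(-eta))
    if fit_result.spec.log_response:
        return np.exp(eta)
    return eta


def contrast(fit_result: PosteriorFit, rowA: pd.DataFrame, rowB: pd.DataFrame) -> dict:
    """Posterior distribution of prediction(A) - prediction(B) on the
    reported (response) scale, with an evidence flag: True iff the central
    95% interval excludes zero."""
    dA = _response_scale(fit_result, fit_result.linear_predictor(rowA))[0]
    dB = _response_scale(fit_result, fit_result.linear_predictor(rowB))[0]
    diff = dA - dB
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return {
        "mean": float(diff.mean()),
        "median": float(np.median(diff)),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "evidence": bool(lo > 0 or hi < 0),
    }


def posterior_predictive_check(
    fit_result: PosteriorFit, n_rep: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Observed vs replicated data summaries with tail probabilities.

    For ``n_rep`` posterior draws, replicate responses from the fitted model
    (including the drawn random intercepts) and compare summary statistics of
    the replicates with the observed data.  The tail probability is
    P(replicate summary >= observed); values near 0 or 1 flag misfit.
    """
    rng = np.random.default_rng(seed)
    C, D, p = fit_result.draws["beta"].shape
    idx = rng.integers(0, C * D, size=n_rep)
    beta = fit_result.draws["beta"].reshape(-1, p)[idx]
    u = fit_result.draws["u"].reshape(C * D, -1)[idx]
    eta = (beta @ fit_result.X.T) + u[:, fit_result.gidx]  # (n_rep, n)
    if fit_result.spec.family == "gaussian":
        sigma = fit_result.draws["sigma"].reshape(-1)[idx]
        reps = eta + sigma[:, None] * rng.standard_normal(eta.shape)
    else:
        reps = (rng.random(eta.shape) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    y = fit_result.y
    stats = {"mean": np.mean, "sd": np.std, "min": np.min, "max": np.max}
    if fit_result.spec.family == "bernoulli":
        stats = {"mean": np.mean, "proportion": np.mean}
    rows = []
    for name, f in stats.items():
        obs = float(f(y))
        rep = np.array([f(r) for r in reps])
        rows.append(
            {
                "summary": name,
                "observed": obs,
                "rep_mean": float(rep.mean()),
                "tail_prob": float(np.mean(rep >= obs)),
            }
        )
    return pd.DataFrame(rows)


def first_trip_table(trips: pd.DataFrame) -> pd.DataFrame:
    """Per bird-year response for the first-trip model: was the first trip
    after capture an outside-fjord trip?  Uses the first deployment when a
    bird has several in a year."""
    tr = trips.copy()
    if "deployment_start" in tr.columns:
        firsts = tr.groupby(["bird_id", "year"])["deployment_start"].transform("min")
        tr = tr[tr["deployment_start"] == firsts]
    tr = tr.sort_values("start")
    first = tr.groupby(["bird_id", "year"], as_index=False).first()
    first["firsttrip_outside"] = (first["label"] == "outside").astype(float)
    return first[["bird_id", "year", "firsttrip_outside"]]


def prepare_model_data(name: str, trips: pd.DataFrame, condition: pd.DataFrame = None):
    """Assemble the analysis table each model is fitted on.

    M1 expects the caller to pass the trip subset of interest (e.g. only
    inside-fjord trips when modelling inside-trip ranges).
    """
    if name == "M1_logrange":
        return trips[["bird_id", "colony_id", "year", "max_range_km"]].copy()
    if name == "M2_outside":
        df = trips[["bird_id", "colony_id", "year", "label"]].copy()
        df["outside"] = (df["label"] == "outside").astype(float)
        return df
    if name == "M3_firsttrip":
        first = first_trip_table(trips)
        return condition.merge(first, on=["bird_id", "year"], how="inner")[
            ["bird_id", "colony_id", "year", "bc", "firsttrip_outside"]
        ]
    if name == "M4_bmc":
        df = condition.dropna(subset=["bmc"])
        return df[["bird_id", "colony_id", "year", "prop_outside", "bmc"]].copy()
    raise KeyError(name)
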