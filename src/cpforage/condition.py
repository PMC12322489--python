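"""Morphometric sexing and body-condition metrics.

Body condition is size-corrected mass: the residual of a pooled ordinary
least-squares regression of capture mass on head-bill length (a structural
size proxy).  Relative body-mass change (BMC) is the mass change between
capture and logger retrieval scaled by capture mass.  The trip-count-weighted
outside-fjord proportion aggregates per-bird proportions so that birds with
more recorded trips carry proportionally more weight; its identity with the
pooled trip count ratio is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HEADBILL_SEX_CUTOFF_MM",
    "sex_from_headbill",
    "body_condition",
    "relative_body_mass_change",
    "weighted_outside_proportion",
    "condition_table",
    "WeightedProportion",
]

HEADBILL_SEX_CUTOFF_MM = 90.5


def sex_from_headbill(head_bill_mm: float) -> str:
    """Morphometric sex: female if head-bill <= 90.5 mm, else male.

    Used only when molecular sex is unavailable; the cutoff itself counts as
    female.
    """
    if not head_bill_mm > 0:
        raise ValueError("head-bill length must be positive")
    return "female" if head_bill_mm <= HEADBILL_SEX_CUTOFF_MM else "male"


def body_condition(records: pd.DataFrame) -> pd.DataFrame:
    """Size-corrected mass: residuals of mass_capture_g ~ head_bill_mm.

    The regression pools all birds passed in (all years and colonies), giving
    a single slope; per-year condition can be obtained by calling this on
    year subsets.  Returns the input with a ``bc`` column plus the fitted
    slope/intercept in ``.attrs``.
    """
    df = records.dropna(subset=["head_bill_mm", "mass_capture_g"]).copy()
    if len(df) < 3:
        raise ValueError("body_condition needs at least 3 birds with mass and head-bill")
    hb = df["head_bill_mm"].to_numpy(dtype=float)
    if np.ptp(hb) == 0:
        raise ValueError("zero variance in head-bill length: slope undefined")
    X = sm.add_constant(hb)
    fit = sm.OLS(df["mass_capture_g"].to_numpy(dtype=float), X).fit()
    df["bc"] = fit.resid
    df.attrs["slope_g_per_mm"] = float(fit.params[1])
    df.attrs["intercept_g"] = float(fit.params[0])
    df.attrs["slope_ci95"] = tuple(np.asarray(fit.conf_int())[1])
    df.attrs["r_squared"] = float(fit.rsquared)
    return df


def relative_body_mass_change(mass_capture_g, mass_recapture_g):
    """BMC = (recapture mass - capture mass) / capture mass (dimensionless)."""
    mc = np.asarray(mass_capture_g, dtype=float)
    mr = np.asarray(mass_recapture_g, dtype=float)
    if np.any(mc[np.isfinite(mc)] <= 0):
        raise ValueError("capture mass must be positive")
    return (mr - mc) / mc


@dataclass(frozen=True)
class WeightedProportion:
    """Trip-count-weighted proportion with a percentile bootstrap CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def weighted_outside_proportion(
    prop_outside, n_trips, n_boot: int = 999, seed: int = 0
) -> WeightedProportion:
    """Average per-bird outside-trip proportions, weighted by trips recorded.

    The point estimate sum(w_i p_i)/sum(w_i) with w_i the bird's trip count
    equals the pooled outside-trips / total-trips ratio exactly.  The CI
    resamples birds (proportion and weight jointly) with replacement and
    takes 2.5/97.5 percentiles.
    """
    p = np.asarray(prop_outside, dtype=float)
    w = np.asarray(n_trips, dtype=float)
    if p.size == 0 or np.sum(w) <= 0:
        raise ValueError("need at least one bird with at least one trip")
    est = float(np.sum(w * p) / np.sum(w))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p.size, size=(n_boot, p.size))
    wb = w[idx]
    boot = np.sum(wb * p[idx], axis=1) / np.sum(wb, axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return WeightedProportion(est, float(lo), float(hi), n_boot, seed)


def condition_table(
    morphometrics: pd.DataFrame, trips: pd.DataFrame, first_deployment_only: bool = True
) -> pd.DataFrame:
    """Join morphometrics with per-bird trip summaries into the condition table.

    Adds per-bird ``bc`` (size-corrected mass), ``bmc`` (relative body-mass
    change; NaN when recapture mass is missing), ``n_trips``,
    ``n_outside_trips`` and ``prop_outside``.  ``sex`` uses the molecular
    assignment when present and the morphometric cutoff otherwise.  When a
    bird has repeat deployments in a year, only its first contributes trips.
    """
    tr = trips.copy()
    if first_deployment_only and "deployment_start" in tr.columns:
        firsts = tr.groupby(["bird_id", "year"])["deployment_start"].transform("min")
        tr = tr[tr["deployment_start"] == firsts]
    agg = (
        tr.assign(outside=(tr["label"] == "outside").astype(int))
        .groupby(["bird_id", "year"])
        .agg(n_trips=("outside", "size"), n_outside_trips=("outside", "sum"))
        .reset_index()
    )
    df = morphometrics.merge(agg, on=["bird_id", "year"], how="left")
    df[["n_trips", "n_outside_trips"]] = df[["n_trips", "n_outside_trips"]].fillna(0).astype(int)
    df["prop_outside"] = np.where(
        df["n_trips"] > 0, df["n_outside_trips"] / df["n_trips"].clip(lower=1), np.nan
    )
    if "sex_molecular" in df.columns:
        fallback = df["head_bill_mm"].map(sex_from_headbill)
        df["sex"] = df["sex_molecular"].where(df["sex_molecular"].notna(), fallback)
    else:
        df["sex"] = df["head_bill_mm"].map(sex_from_headbill)
    df = body_condition(df)
    df["bmc"] = relative_body_mass_change(df["mass_capture_g"], df["mass_recapture_g"])
    return df
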