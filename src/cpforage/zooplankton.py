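"""Seasonal zooplankton dry-biomass index with bootstrap confidence intervals.

Net samples from depth-stratified plankton hauls are reduced to a yearly,
fjord-level index: per station, species abundances (ind m^-3) are averaged
over depth strata (unweighted by stratum thickness) and converted to dry
biomass with per-species individual dry masses; station biomasses are then
averaged, and uncertainty comes from resampling stations with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BiomassIndex", "station_biomass", "yearly_index", "biomass_by_year"]


@dataclass(frozen=True)
class BiomassIndex:
    year: int
    index: float  # mg dry mass m^-3
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def station_biomass(
    samples: pd.DataFrame, dry_mass: pd.Series, thickness_weighted: bool = False
) -> float:
    """Dry biomass (mg m^-3) of one station-year.

    ``samples`` holds one row per (stratum, species) with columns
    ``top_depth_m``, ``bottom_depth_m``, ``species_id``,
    ``abundance_ind_m3``; ``dry_mass`` maps species_id to individual dry mass
    (mg).  Species abundance is averaged over the station's strata (optionally
    weighted by stratum thickness), multiplied by individual dry mass, and
    summed over species.  A stratum without a record for some species counts
    as zero abundance for it.
    """
    if len(samples) == 0:
        raise ValueError("station has no strata")
    missing = set(samples["species_id"]) - set(dry_mass.index)
    if missing:
        raise KeyError(f"species missing from dry-mass table: {sorted(missing)}")
    strata = samples[["top_depth_m", "bottom_depth_m"]].drop_duplicates()
    n_strata = len(strata)
    wide = samples.pivot_table(
        index=["top_depth_m", "bottom_depth_m"],
        columns="species_id",
        values="abundance_ind_m3",
        aggfunc="sum",
        fill_value=0.0,
    )
    if thickness_weighted:
        w = (wide.index.get_level_values(1) - wide.index.get_level_values(0)).to_numpy(float)
        mean_ab = (wide.to_numpy(float) * w[:, None]).sum(axis=0) / w.sum()
    else:
        # unweighted over the station's strata, including species-absent ones
        mean_ab = wide.to_numpy(float).sum(axis=0) / n_strata
    masses = dry_mass.loc[wide.columns].to_numpy(float)
    return float(np.sum(mean_ab * masses))


def yearly_index(
    station_values, year: int = 0, n_boot: int = 999, seed: int = 0
) -> BiomassIndex:
    """Fjord-level index: mean of station biomasses, with a percentile CI
    from resampling stations with replacement."""
    v = np.asarray(station_values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one station")
    rng = np.random.default_rng(seed)
    boot = v[rng.integers(0, v.size, size=(n_boot, v.size))].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return BiomassIndex(year, float(v.mean()), float(lo), float(hi), n_boot, seed)


def biomass_by_year(
    net_samples: pd.DataFrame,
    dry_mass: pd.DataFrame,
    n_boot: int = 999,
    seed: int = 0,
    thickness_weighted: bool = False,
) -> list:
    """Yearly biomass indices from the standard net-sample and dry-mass tables."""
    dm = dry_mass.set_index("species_id")["dry_mass_mg"]
    if (dm <= 0).any():
        raise ValueError("dry masses must be positive")
    out = []
    for year, per_year in net_samples.groupby("year"):
        stations = [
            station_biomass(g, dm, thickness_weighted)
            for _, g in per_year.groupby("station_id")
        ]
        out.append(yearly_index(stations, int(year), n_boot=n_boot, seed=seed))
    return out
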