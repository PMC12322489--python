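"""Bimodality analysis of per-individual maximum foraging ranges.

Combines Hartigan's dip test (is the range distribution unimodal?) with
critical-bandwidth mode location (where are the modes?) and a
one-trip-per-individual resampling check that guards the dip decision against
unequal trip counts among birds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dip import dip_pvalue, dip_statistic, dip_test

__all__ = [
    "ModeEstimate",
    "ResampleResult",
    "kde_on_grid",
    "count_modes",
    "critical_bandwidth",
    "mode_locations",
    "resample_bimodality",
]

DEFAULT_LIMITS = (0.0, 200.0)
GRID_SIZE = 512


@dataclass(frozen=True)
class ModeEstimate:
    """Mode locations from the critical-bandwidth KDE."""

    h_crit: float
    k: int
    modes: tuple
    limits: tuple


@dataclass(frozen=True)
class ResampleResult:
    """Distribution of dip p-values under one-trip-per-individual resampling."""

    p_values: np.ndarray
    iterations: int
    seed: int
    prop_significant: float = field(init=False)
    alpha: float = 0.05

    def __post_init__(self):
        object.__setattr__(
            self, "prop_significant", float(np.mean(self.p_values < self.alpha))
        )


def kde_on_grid(values, h: float, limits=DEFAULT_LIMITS, gridsize: int = GRID_SIZE):
    """Gaussian-kernel density with fixed bandwidth h, evaluated on a uniform
    grid over ``limits``.  All observations contribute, including those beyond
    the window; only the window is evaluated."""
    x = np.asarray(values, dtype=float)
    grid = np.linspace(limits[0], limits[1], gridsize)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2.0 * np.pi))
    return grid, dens


def count_modes(density: np.ndarray) -> int:
    """Number of interior local maxima of a gridded density.

    Grid endpoints are never counted as modes, so mass piling up against the
    window edge cannot masquerade as a mode.  Flat-topped maxima (exact ties
    on the grid) count once.
    """
    d = np.sign(np.diff(density))
    d = d[d != 0]  # collapse plateaus
    return int(np.sum((d[:-1] > 0) & (d[1:] < 0)))


def critical_bandwidth(
    values,
    k_target: int,
    limits=DEFAULT_LIMITS,
    tol: float = 1e-3,
    gridsize: int = GRID_SIZE,
) -> float:
    """Smallest Gaussian bandwidth at which the KDE has at most ``k_target``
    modes inside ``limits`` (found by bisection to ``tol``).

    Mode counting is restricted to the limits window to avoid identifying
    artificial modes in the long right tail of range distributions.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("critical_bandwidth needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: KDE scale degenerate")
    if k_target < 1:
        raise ValueError("k_target must be >= 1")

    def n_modes(h):
        return count_modes(kde_on_grid(x, h, limits, gridsize)[1])

    lo = tol
    if n_modes(lo) <= k_target:
        return lo
    hi = float(limits[1] - limits[0])
    tries = 0
    while n_modes(hi) > k_target:
        hi *= 2.0
        tries += 1
        if tries > 10:
            raise RuntimeError(
                f"no bandwidth up to {hi:.1f} yields <= {k_target} modes "
                f"(n={x.size}, window={limits})"
            )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_modes(mid) <= k_target:
            hi = mid
        else:
            lo = mid
    return hi


def mode_locations(
    values,
    limits=DEFAULT_LIMITS,
    alpha: float = 0.05,
    n_null: int = 10000,
    seed: int = 0,
    gridsize: int = GRID_SIZE,
) -> ModeEstimate:
    """Locate the distribution's modes inside ``limits``.

    The number of modes is tied to the dip decision: two when the dip test
    rejects unimodality at ``alpha``, one otherwise.  Mode locations are the
    grid positions of the KDE local maxima at the corresponding critical
    bandwidth.
    """
    x = np.asarray(values, dtype=float)
    res = dip_test(x, n_null=n_null, seed=seed)
    k = 2 if res.p_value < alpha else 1
    h = critical_bandwidth(x, k, limits=limits, gridsize=gridsize)
    grid, dens = kde_on_grid(x, h, limits, gridsize)
    d = np.diff(dens)
    rising = d > 0
    peaks = np.flatnonzero(rising[:-1] & ~rising[1:]) + 1
    modes = tuple(sorted(float(grid[i]) for i in peaks))
    return ModeEstimate(h_crit=h, k=len(modes), modes=modes, limits=tuple(limits))


def resample_bimodality(
    trip_ranges: pd.DataFrame,
    iterations: int = 999,
    seed: int = 0,
    n_null: int = 10000,
    alpha: float = 0.05,
) -> ResampleResult:
    """One-trip-per-individual dip-test resampling for a single year.

    ``trip_ranges`` must have columns ``bird_id`` and ``max_range_km`` with
    one row per retained trip.  Each iteration draws one trip uniformly per
    individual and computes the dip p-value of the resulting per-individual
    range sample; the p-value distribution summarises how robust the
    bimodality decision is to which trip represents each bird.
    """
    groups = [g["max_range_km"].to_numpy(dtype=float) for _, g in trip_ranges.groupby("bird_id")]
    n_birds = len(groups)
    if n_birds < 3:
        raise ValueError("resampling needs at least 3 individuals")
    rng = np.random.default_rng(seed)
    null_seed = int(rng.integers(2**31 - 1))
    pvals = np.empty(iterations)
    for it in range(iterations):
        sample = np.array([g[rng.integers(g.size)] for g in groups])
        D = dip_statistic(sample)
        pvals[it] = dip_pvalue(D, n_birds, n_null=n_null, seed=null_seed)
    return ResampleResult(p_values=pvals, iterations=iterations, seed=seed, alpha=alpha)
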