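"""Synthetic central-place foraging studies with known ground truth.

Generates complete studies — GPS fixes, deployments, morphometrics, net
samples — whose statistical structure matches what the analysis assumes: two
colonies inside a rectangular ~230 km^2 fjord opening onto the open sea,
three study years with year-specific mixtures of short inside-fjord and long
outside-fjord trips, bird-level random intercepts on both the outside-trip
probability (logit scale) and trip ranges (log scale), mass dynamics driven
by a linear model on the proportion of outside trips, optional battery
truncation and on-land excursion trips.

Movement is deliberately schematic (out-and-back along a bearing with the
range floor keeping every trip fix beyond the colony-attendance radius); the
paths only need to exercise the segmentation geometry, not to look like real
kittiwake tracks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeoPoint, PolygonRegion, StudyArea

__all__ = ["SimConfig", "SyntheticStudy", "default_study_area", "simulate_study", "write_study"]

_DEG_LAT_KM = 111.195  # spherical degree of latitude (2 pi 6371 / 360)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters; defaults encode the study conditions.

    Printed field calibrations: trip counts 1-16 per bird with mean 5.3 and
    sd 3.3; outside-trip proportions 0.07 / 0.02 / 0.31 for the three years;
    inside-trip ranges around a ~5-6 km median with outside trips an order of
    magnitude farther; mass-change model slope 0.054 on the outside-trip
    proportion with year levels -0.02 / -0.08 / -0.03, residual sd 0.04 and
    bird sd 0.01; condition regression slope 5.96 g/mm; ~8% of trips
    truncated by battery failure.  Log-scale spreads are generator choices.
    """

    years: tuple = (2016, 2017, 2018)
    colonies: tuple = ("OBS", "OSS")
    n_birds_per_colony_year: int = 12
    trips_mean: float = 5.3
    trips_sd: float = 3.3
    trips_range: tuple = (1, 16)
    fix_interval_min: float = 10.0
    p_outside: dict = field(
        default_factory=lambda: {2016: 0.07, 2017: 0.02, 2018: 0.31}
    )
    outside_logit_sd: float = 1.5
    inside_median_km: float = 5.6
    inside_log_sd: float = 0.55
    outside_median_km: float = 90.0
    outside_log_sd: float = 0.12
    bird_range_log_sd: float = 0.10
    flight_speed_kmh: float = 30.0
    handling_time_h: tuple = (0.8, 0.6)  # lognormal median, log-sd of on-patch time
    bmc_prop_slope: float = 0.054
    bmc_year_levels: dict = field(
        default_factory=lambda: {2016: -0.02, 2017: -0.08, 2018: -0.03}
    )
    bmc_colony_effect: float = 0.0
    bmc_resid_sd: float = 0.04
    bmc_bird_sd: float = 0.01
    condition_slope_g_mm: float = 5.96
    condition_intercept_g: float = -162.0
    mass_resid_sd_g: float = 38.0
    headbill_mean_mm: dict = field(default_factory=lambda: {"female": 88.0, "male": 93.0})
    headbill_sd_mm: float = 1.5
    round_mass_g: float = 5.0
    battery_failure_prob: float = 0.08
    land_excursion_prob: float = 0.05
    zoop_year_scale: dict = field(
        default_factory=lambda: {2016: 1.0, 2017: 1.2, 2018: 0.4}
    )
    seed: int = 0

    def clean(self, **overrides) -> "SimConfig":
        """A copy with truncation and land excursions disabled (plus overrides)."""
        d = asdict(self)
        d.update(battery_failure_prob=0.0, land_excursion_prob=0.0)
        d.update(overrides)
        for key in ("years", "colonies", "trips_range", "handling_time_h"):
            d[key] = tuple(d[key])
        return SimConfig(**d)


@dataclass
class SyntheticStudy:
    fixes: pd.DataFrame
    deployments: pd.DataFrame
    morphometrics: pd.DataFrame
    net_samples: pd.DataFrame
    dry_mass: pd.DataFrame
    ground_truth: dict
    area: StudyArea
    config: SimConfig


# --- geometry -------------------------------------------------------------

_FJORD_LON = (11.0, 12.6)
_FJORD_LAT = (78.90, 78.96)  # ~34 km x ~6.7 km at 79 N: ca. 230 km^2
_COLONY_POS = {"OBS": (12.28, 78.93), "OSS": (12.44, 78.92)}


def default_study_area(cfg: SimConfig = SimConfig()) -> StudyArea:
    """Rectangular fjord opening west onto the open sea, flanked by land."""

    def rect(lon0, lon1, lat0, lat1, label):
        return PolygonRegion(
            ring=tuple(
                GeoPoint(lo, la)
                for lo, la in [(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1), (lon0, lat0)]
            ),
            label=label,
        )

    fjord = rect(*_FJORD_LON, *_FJORD_LAT, "fjord")
    land = (
        rect(_FJORD_LON[0], _FJORD_LON[1] + 0.4, _FJORD_LAT[1], _FJORD_LAT[1] + 0.08, "land"),
        rect(_FJORD_LON[0], _FJORD_LON[1] + 0.4, _FJORD_LAT[0] - 0.08, _FJORD_LAT[0], "land"),
        rect(_FJORD_LON[1], _FJORD_LON[1] + 0.4, _FJORD_LAT[0], _FJORD_LAT[1], "land"),
    )
    colonies = {c: GeoPoint(*_COLONY_POS[c]) for c in cfg.colonies}
    return StudyArea(fjord=fjord, land=land, colonies=colonies)


# --- trips ----------------------------------------------------------------


@dataclass
class TripTemplate:
    kind: str  # inside | outside | land
    range_km: float
    duration_h: float


def _n_trips(cfg, rng) -> int:
    lo, hi = cfg.trips_range
    k = int(round(rng.normal(cfg.trips_mean, cfg.trips_sd)))
    return int(np.clip(k, lo, hi))


def simulate_trips(cfg: SimConfig, year: int, u_out: float, u_range: float, rng) -> list:
    """Trip templates for one bird-year.

    Trip type is Bernoulli with the year's outside probability shifted by the
    bird's logit-scale random intercept; ranges are lognormal around the
    type-specific median with the bird's log-scale intercept; durations are
    commute time at cruise speed plus lognormal on-patch time, which makes
    range and duration strongly correlated, as in real trips.
    """
    p = cfg.p_outside[year]
    if 0.0 < p < 1.0:
        # the intercept is chosen so that p is the population-average
        # probability after marginalising the bird intercepts (logit-normal
        # mean correction, probit approximation to the logistic)
        icpt = np.log(p / (1 - p)) * np.sqrt(1.0 + 0.346 * cfg.outside_logit_sd**2)
        p = 1.0 / (1.0 + np.exp(-(icpt + u_out)))
    templates = []
    for _ in range(_n_trips(cfg, rng)):
        outside = rng.random() < p
        land = (not outside) and rng.random() < cfg.land_excursion_prob
        if land:
            # deep enough onto the land strip that most fixes overlap land
            r = float(rng.uniform(9.5, 12.0))
        elif outside:
            r = cfg.outside_median_km * np.exp(u_range + cfg.outside_log_sd * rng.standard_normal())
            r = max(r, 36.0)  # an outside trip must clear the fjord mouth
        else:
            r = cfg.inside_median_km * np.exp(u_range + cfg.inside_log_sd * rng.standard_normal())
            r = float(np.clip(r, 0.6, 24.0))  # stay within the fjord
        handling = cfg.handling_time_h[0] * np.exp(cfg.handling_time_h[1] * rng.standard_normal())
        dur = max(2.0 * r / cfg.flight_speed_kmh + handling, 1.2)
        templates.append(TripTemplate("land" if land else ("outside" if outside else "inside"), float(r), float(dur)))
    return templates


def _apex_for_range(colony: GeoPoint, range_km: float, bearing: str) -> GeoPoint:
    """Apex point at an exact haversine distance from the colony."""
    if bearing == "west":  # along the fjord axis and out the mouth
        lat = colony.lat
        dlam = 2.0 * np.arcsin(
            min(np.sin(range_km / (2 * 6371.0)) / np.cos(np.radians(lat)), 1.0)
        )
        return GeoPoint(colony.lon - np.degrees(dlam), lat)
    # north: onto the land strip
    return GeoPoint(colony.lon, colony.lat + range_km / _DEG_LAT_KM)


def render_track(
    template: TripTemplate, colony: GeoPoint, start, fix_interval_min: float, rng
) -> pd.DataFrame:
    """Out-and-back fixes for one trip.

    The distance-from-colony profile is a triangle with a 0.25 km floor, so
    every trip fix sits beyond the 0.2 km attendance radius; the apex hits the
    template range exactly.  Inside trips head down-fjord but stop short of
    the mouth; outside trips continue through it; land-excursion trips head
    onto the northern land strip.
    """
    bearing = "north" if template.kind == "land" else "west"
    apex = _apex_for_range(colony, template.range_km, bearing)
    step = np.timedelta64(int(round(fix_interval_min * 60)), "s")
    n_steps = max(int(round(template.duration_h * 60.0 / fix_interval_min)), 6)
    n_steps += n_steps % 2  # even step count so a fix lands exactly on the apex
    t = start + step * np.arange(n_steps + 1)
    frac = np.minimum(np.arange(n_steps + 1), n_steps - np.arange(n_steps + 1)) / (n_steps / 2.0)
    floor = 0.25 / max(template.range_km, 0.26)
    frac = np.clip(frac, floor, 1.0)
    frac[0] = frac[-1] = floor
    lon = colony.lon + frac * (apex.lon - colony.lon)
    lat = colony.lat + frac * (apex.lat - colony.lat)
    return pd.DataFrame({"timestamp": t, "lon": lon, "lat": lat})


def _render_deployment(cfg, colony, templates, capture, rng):
    """Fixes for one deployment: colony attendance alternating with trips."""
    step = np.timedelta64(int(round(cfg.fix_interval_min * 60)), "s")
    frames = []
    truth = []
    t = capture + step
    for k, tpl in enumerate(templates):
        # colony attendance before each trip (a whole number of fix intervals)
        n_att = rng.integers(3, 12)
        att_t = t + step * np.arange(n_att)
        frames.append(
            pd.DataFrame(
                {"timestamp": att_t, "lon": colony.lon, "lat": colony.lat}
            )
        )
        trip_start = att_t[-1] + step
        tf = render_track(tpl, colony, trip_start, cfg.fix_interval_min, rng)
        frames.append(tf)
        truth.append(
            {
                "trip_index": k,
                "kind": tpl.kind,
                "range_km": tpl.range_km,
                "duration_h": tpl.duration_h,
                "start": str(tf["timestamp"].iloc[0]),
                "end": str(tf["timestamp"].iloc[-1]),
            }
        )
        t = tf["timestamp"].to_numpy()[-1] + step
    # final attendance so the last trip has a colony fix after it
    n_att = rng.integers(3, 12)
    frames.append(
        pd.DataFrame(
            {"timestamp": t + step * np.arange(n_att), "lon": colony.lon, "lat": colony.lat}
        )
    )
    fixes = pd.concat(frames, ignore_index=True)
    truncated = False
    if rng.random() < cfg.battery_failure_prob and truth:
        # battery dies somewhere inside the last trip
        last = truth[-1]
        lo = np.datetime64(last["start"])
        hi = np.datetime64(last["end"])
        cut = lo + (hi - lo) * rng.random()
        fixes = fixes[fixes["timestamp"] <= cut].reset_index(drop=True)
        truncated = True
    return fixes, truth, truncated


# --- masses and morphometrics --------------------------------------------


def simulate_masses(cfg: SimConfig, birds: pd.DataFrame, rng) -> pd.DataFrame:
    """Morphometrics rows for birds with realised outside-trip proportions.

    Head-bill lengths are sex-specific normals straddling the 90.5 mm cutoff;
    capture mass follows the condition regression; recapture mass applies a
    relative mass change drawn from the configured linear model.
    """
    n = len(birds)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    hb = np.array([cfg.headbill_mean_mm[s] for s in sex]) + cfg.headbill_sd_mm * rng.standard_normal(n)
    mass_c = (
        cfg.condition_intercept_g
        + cfg.condition_slope_g_mm * hb
        + cfg.mass_resid_sd_g * rng.standard_normal(n)
    )
    bmc = (
        cfg.bmc_prop_slope * birds["prop_outside"].to_numpy(float)
        + np.array([cfg.bmc_year_levels[y] for y in birds["year"]])
        + np.where(birds["colony_id"].to_numpy() == "OSS", cfg.bmc_colony_effect, 0.0)
        + cfg.bmc_bird_sd * rng.standard_normal(n)
        + cfg.bmc_resid_sd * rng.standard_normal(n)
    )
    mass_r = mass_c * (1.0 + bmc)
    if cfg.round_mass_g:
        mass_c = np.round(mass_c / cfg.round_mass_g) * cfg.round_mass_g
        mass_r = np.round(mass_r / cfg.round_mass_g) * cfg.round_mass_g
    out = birds[["bird_id", "colony_id", "year"]].copy()
    out["sex_molecular"] = sex
    out["head_bill_mm"] = np.round(hb)  # measured to the nearest mm
    out["mass_capture_g"] = mass_c
    out["mass_recapture_g"] = mass_r
    out.attrs["bmc_true"] = bmc
    return out


# --- zooplankton ----------------------------------------------------------

_SPECIES = {
    "calanus_glacialis": {"dry_mass_mg": 0.45, "mean_abundance": 40.0},
    "calanus_finmarchicus": {"dry_mass_mg": 0.20, "mean_abundance": 80.0},
    "thysanoessa_inermis": {"dry_mass_mg": 6.0, "mean_abundance": 1.5},
}
_STRATA = [(0, 20), (20, 50), (50, 100), (100, 200), (200, 300)]


def simulate_netsamples(cfg: SimConfig, rng) -> tuple:
    """Net-sample rows (5 stations, depth strata, diet species) plus the
    dry-mass table.  Abundances are gamma-distributed around year-level
    means scaled by the configured year factors."""
    rows = []
    for year in cfg.years:
        scale = cfg.zoop_year_scale[year]
        for st in range(1, 6):
            for top, bot in _STRATA:
                depth_factor = np.exp(-top / 150.0)  # plankton concentrate near surface
                for sp, pars in _SPECIES.items():
                    mean = pars["mean_abundance"] * scale * depth_factor
                    ab = rng.gamma(shape=4.0, scale=mean / 4.0) if mean > 0 else 0.0
                    rows.append(
                        {
                            "year": year,
                            "station_id": f"KB{st}",
                            "top_depth_m": top,
                            "bottom_depth_m": bot,
                            "species_id": sp,
                            "abundance_ind_m3": ab,
                        }
                    )
    dry = pd.DataFrame(
        [{"species_id": sp, "dry_mass_mg": p["dry_mass_mg"]} for sp, p in _SPECIES.items()]
    )
    return pd.DataFrame(rows), dry


# --- whole study ----------------------------------------------------------


def simulate_study(cfg: SimConfig = SimConfig()) -> SyntheticStudy:
    """Generate a full synthetic study deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    area = default_study_area(cfg)
    fixes_frames, dep_rows, bird_rows, truth_birds = [], [], [], {}
    bird_no = 0
    for year in cfg.years:
        season_start = np.datetime64(f"{year}-07-01T06:00:00")
        for colony_id in cfg.colonies:
            colony = area.colonies[colony_id]
            for _ in range(cfg.n_birds_per_colony_year):
                bird_no += 1
                bird_id = f"B{bird_no:03d}"
                u_out = cfg.outside_logit_sd * rng.standard_normal()
                u_range = cfg.bird_range_log_sd * rng.standard_normal()
                templates = simulate_trips(cfg, year, u_out, u_range, rng)
                capture = season_start + np.timedelta64(int(rng.integers(0, 20 * 24 * 60)), "m")
                fixes, truth, truncated = _render_deployment(cfg, colony, templates, capture, rng)
                fixes.insert(0, "bird_id", bird_id)
                recapture = fixes["timestamp"].to_numpy()[-1] + np.timedelta64(30, "m")
                fixes_frames.append(fixes)
                dep_rows.append(
                    {
                        "bird_id": bird_id,
                        "colony_id": colony_id,
                        "year": year,
                        "capture_time": capture,
                        "recapture_time": recapture,
                        "deployment_id": f"{bird_id}-{year}",
                    }
                )
                n_out = sum(t["kind"] == "outside" for t in truth)
                bird_rows.append(
                    {
                        "bird_id": bird_id,
                        "colony_id": colony_id,
                        "year": year,
                        "n_trips": len(truth),
                        "n_outside": n_out,
                        "prop_outside": n_out / len(truth) if truth else 0.0,
                    }
                )
                truth_birds[bird_id] = {
                    "u_out": u_out,
                    "u_range": u_range,
                    "truncated": truncated,
                    "trips": truth,
                }
    fixes = pd.concat(fixes_frames, ignore_index=True)
    deployments = pd.DataFrame(dep_rows)
    birds = pd.DataFrame(bird_rows)
    morpho = simulate_masses(cfg, birds, rng)
    net, dry = simulate_netsamples(cfg, rng)
    truth = {
        "coefficients": {
            "bmc_prop_slope": cfg.bmc_prop_slope,
            "bmc_year_levels": {str(k): v for k, v in cfg.bmc_year_levels.items()},
            "condition_slope_g_mm": cfg.condition_slope_g_mm,
            "p_outside": {str(k): v for k, v in cfg.p_outside.items()},
        },
        "birds": truth_birds,
    }
    return SyntheticStudy(fixes, deployments, morpho, net, dry, truth, area, cfg)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Emit the four CSVs, the study-area GeoJSON and ground_truth.json."""
    from pathlib import Path

    from .geometry import study_area_to_geojson

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.fixes.to_csv(out / "fixes.csv", index=False)
    study.deployments.to_csv(out / "deployments.csv", index=False)
    study.morphometrics.to_csv(out / "morphometrics.csv", index=False)
    study.net_samples.to_csv(out / "net_samples.csv", index=False)
    study.dry_mass.to_csv(out / "dry_mass.csv", index=False)
    study_area_to_geojson(study.area, out / "area.geojson")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(study.ground_truth, fh, indent=1)
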