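"""End-to-end orchestration: simulate -> segment -> bimodality -> condition
-> models -> zooplankton, with a consolidated JSON report.

Every stage can be toggled and seeded independently through one
:class:`RunConfig`; there is no hidden global random state, so a config run
twice produces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bimodality as bim
from . import condition as cond
from . import models as mdl
from . import tracks, zooplankton
from .dip import dip_test
from .geometry import load_study_area
from .synthetic import SimConfig, simulate_study, write_study

__all__ = ["RunConfig", "run", "load_config", "validate_report", "REPORT_SCHEMA"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    ``stages`` toggles each pipeline step; ``seeds`` hold one seed per
    stochastic stage; the analysis constants carry their standard values
    (0.2 km / 50 min trip rule, 50% land rule, 75% return rule, 0-200 km mode
    window, 999 bootstrap/resampling iterations, alpha 0.05).
    """

    outdir: str = "run_output"
    data_dir: str = ""  # where input CSVs live when simulate is off
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "segment": True,
            "bimodality": True,
            "condition": True,
            "models": True,
            "zooplankton": True,
        }
    )
    seeds: dict = field(
        default_factory=lambda: {
            "simulate": 1,
            "bimodality": 2,
            "condition": 3,
            "models": 4,
            "zooplankton": 5,
        }
    )
    sim: dict = field(default_factory=dict)
    interval_min: float = 10.0
    min_dist_km: float = 0.2
    min_duration_min: float = 50.0
    return_fraction: float = 0.75
    limits_km: tuple = (0.0, 200.0)
    iterations: int = 999
    n_null: int = 10000
    alpha: float = 0.05
    models_to_fit: tuple = ("M1_inside", "M1_outside", "M2_outside", "M3_firsttrip", "M4_bmc")
    mcmc: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    return obj


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the Report."""
    report = {"config": {"seeds": dict(config.seeds)}, "years": {}, "models": {}}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    on = config.stages

    area = trips_df = condition_df = None
    if on.get("simulate"):
        sim_cfg = SimConfig(**{"seed": config.seeds["simulate"], **config.sim})
        study = simulate_study(sim_cfg)
        write_study(study, outdir / "data")
        area = study.area
        fixes, deployments = study.fixes, study.deployments
        morpho, net, dry = study.morphometrics, study.net_samples, study.dry_mass
    else:
        d = Path(config.data_dir or outdir / "data")
        area = load_study_area(d / "area.geojson")
        fixes = tracks.read_fixes_csv(d / "fixes.csv")
        deployments = tracks.read_deployments_csv(d / "deployments.csv")
        morpho = pd.read_csv(d / "morphometrics.csv")
        net = pd.read_csv(d / "net_samples.csv")
        dry = pd.read_csv(d / "dry_mass.csv")

    if on.get("segment"):
        trip_list, counts = tracks.process_deployments(
            fixes,
            deployments,
            area,
            interval_min=config.interval_min,
            min_dist_km=config.min_dist_km,
            min_duration_min=config.min_duration_min,
            return_fraction=config.return_fraction,
        )
        trips_df = tracks.trips_to_frame(trip_list)
        trips_df.to_csv(outdir / "trips.csv", index=False)
        report["segmentation"] = counts
        per_year = trips_df.groupby("year")["bird_id"].agg(["size", "nunique"])
        for year, row in per_year.iterrows():
            report["years"][int(year)] = {
                "n_trips": int(row["size"]),
                "n_individuals": int(row["nunique"]),
            }

    if on.get("bimodality") and trips_df is not None:
        seed = config.seeds["bimodality"]
        ranges = tracks.individual_max_range(
            [t for t in trip_list], first_deployment_only=True
        )
        for year, g in ranges.groupby("year"):
            vals = g["max_range_km"].to_numpy()
            block = report["years"].setdefault(int(year), {})
            if len(vals) < 3:
                block["bimodality"] = None
                continue
            dres = dip_test(vals, n_null=config.n_null, seed=seed)
            mode = bim.mode_locations(
                vals, limits=config.limits_km, alpha=config.alpha,
                n_null=config.n_null, seed=seed,
            )
            res = bim.resample_bimodality(
                trips_df[trips_df["year"] == year],
                iterations=config.iterations, seed=seed, n_null=config.n_null,
            )
            block["dip"] = {"D": dres.D, "p_value": dres.p_value, "n": dres.n}
            block["modes"] = {"h_crit": mode.h_crit, "k": mode.k, "modes": list(mode.modes)}
            block["resampling"] = {
                "prop_significant": res.prop_significant,
                "iterations": res.iterations,
            }

    if on.get("condition") and trips_df is not None:
        seed = config.seeds["condition"]
        condition_df = cond.condition_table(morpho, trips_df)
        condition_df.to_csv(outdir / "condition.csv", index=False)
        report["condition_regression"] = {
            "slope_g_per_mm": condition_df.attrs["slope_g_per_mm"],
            "slope_ci95": list(condition_df.attrs["slope_ci95"]),
            "r_squared": condition_df.attrs["r_squared"],
        }
        for year, g in condition_df.groupby("year"):
            g = g[g["n_trips"] > 0]
            if len(g) == 0:
                continue
            wp = cond.weighted_outside_proportion(
                g["prop_outside"], g["n_trips"], n_boot=config.iterations, seed=seed
            )
            report["years"].setdefault(int(year), {})["outside_proportion"] = {
                "estimate": wp.estimate, "ci": [wp.ci_low, wp.ci_high],
            }

    if on.get("models") and trips_df is not None and condition_df is not None:
        settings = mdl.MCMCSettings(seed=config.seeds["models"], **config.mcmc)
        for name in config.models_to_fit:
            base = name.replace("M1_inside", "M1_logrange").replace(
                "M1_outside", "M1_logrange"
            )
            if name == "M1_inside":
                data = mdl.prepare_model_data(base, trips_df[trips_df["label"] == "inside"])
            elif name == "M1_outside":
                data = mdl.prepare_model_data(base, trips_df[trips_df["label"] == "outside"])
            else:
                data = mdl.prepare_model_data(base, trips_df, condition_df)
            try:
                fit = mdl.MixedModel(base, mcmc=settings).fit(data)
            except ValueError as exc:
                log.warning("model %s skipped: %s", name, exc)
                report["models"][name] = {"skipped": str(exc)}
                continue
            summ = mdl.diagnostics(fit)
            entry = {
                "summary": _jsonable(summ),
                "convergence_ok": summ.attrs["convergence_ok"],
            }
            if base == "M1_logrange":
                cells = pd.DataFrame(
                    {"year": list(fit.info.years), "colony_id": fit.info.colonies[0]}
                )
                med = mdl.backtransform_median(fit, cells)
                entry["median_range_km"] = {
                    str(y): _jsonable(med.loc[i].to_dict())
                    for i, y in zip(med.index, fit.info.years)
                }
            if base == "M4_bmc":
                yr = fit.info.years[0]
                rowA = pd.DataFrame({"year": [yr], "colony_id": fit.info.colonies[0], "prop_outside": 1.0})
                rowB = rowA.assign(prop_outside=0.0)
                entry["contrast_all_outside_vs_inside"] = mdl.contrast(fit, rowA, rowB)
            entry["ppc"] = _jsonable(mdl.posterior_predictive_check(fit, seed=settings.seed))
            report["models"][name] = entry

    if on.get("zooplankton"):
        for res in zooplankton.biomass_by_year(
            net, dry, n_boot=config.iterations, seed=config.seeds["zooplankton"]
        ):
            report["years"].setdefault(int(res.year), {})["zooplankton"] = {
                "index_mg_m3": res.index, "ci": [res.ci_low, res.ci_high],
            }

    report = _jsonable(report)
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    log.info("report written to %s", outdir / "report.json")
    return report


REPORT_SCHEMA = {
    "type": "object",
    "required": ["config", "years", "models"],
    "properties": {
        "config": {"type": "object"},
        "years": {
            "type": "object",
            "additionalProperties": {
                "type": "object",
                "properties": {
                    "n_trips": {"type": "integer"},
                    "n_individuals": {"type": "integer"},
                    "dip": {"type": "object"},
                    "modes": {"type": "object"},
                    "resampling": {"type": "object"},
                    "outside_proportion": {"type": "object"},
                    "zooplankton": {"type": "object"},
                },
            },
        },
        "models": {"type": "object"},
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def validate_report(report, schema=None, path="$"):
    """Minimal JSON-schema validation (type / required / properties /
    additionalProperties subset) of the report structure."""
    schema = REPORT_SCHEMA if schema is None else schema
    t = schema.get("type")
    if t and not isinstance(report, _TYPES[t]):
        raise ValueError(f"{path}: expected {t}, got {type(report).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, value in report.items():
            if key in props:
                validate_report(value, props[key], f"{path}.{key}")
            elif isinstance(extra, dict):
                validate_report(value, extra, f"{path}.{key}")
    return True
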