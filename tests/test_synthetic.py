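import numpy as np
import pandas as pd
import pytest

from cpforage import tracks
from cpforage.condition import body_condition
from cpforage.dip import dip_test
from cpforage.geometry import points_in_polygon
from cpforage.synthetic import (
    SimConfig,
    default_study_area,
    simulate_masses,
    simulate_study,
    simulate_trips,
    write_study,
)


class TestTripTemplates:
    def test_p_outside_zero_all_inside(self, rng):
        cfg = SimConfig(p_outside={2016: 0.0, 2017: 0.0, 2018: 0.0})
        tpls = simulate_trips(cfg, 2018, u_out=1.0, u_range=0.0, rng=rng)
        assert all(t.kind != "outside" for t in tpls)

    def test_p_outside_one_all_outside(self, rng):
        cfg = SimConfig(p_outside={2016: 1.0, 2017: 1.0, 2018: 1.0})
        tpls = simulate_trips(cfg, 2018, u_out=-1.0, u_range=0.0, rng=rng)
        assert all(t.kind == "outside" for t in tpls)

    def test_marginal_outside_fraction(self, rng):
        cfg = SimConfig(land_excursion_prob=0.0)
        kinds = []
        for _ in range(2000):
            u = cfg.outside_logit_sd * rng.standard_normal()
            kinds += [t.kind for t in simulate_trips(cfg, 2018, u, 0.0, rng)]
        frac = np.mean([k == "outside" for k in kinds])
        assert frac == pytest.approx(0.31, abs=0.02)

    def test_trip_counts_within_printed_range(self, rng):
        cfg = SimConfig()
        counts = [len(simulate_trips(cfg, 2016, 0.0, 0.0, rng)) for _ in range(500)]
        assert min(counts) >= 1 and max(counts) <= 16
        assert np.mean(counts) == pytest.approx(5.3, abs=0.5)

    def test_range_duration_correlation(self, rng):
        cfg = SimConfig()
        tpls = []
        for _ in range(400):
            u = cfg.outside_logit_sd * rng.standard_normal()
            tpls += simulate_trips(cfg, 2018, u, 0.0, rng)
        r = np.corrcoef([t.range_km for t in tpls], [t.duration_h for t in tpls])[0, 1]
        assert 0.7 < r <= 1.0


class TestGroundTruthConsistency:
    def test_labels_match_geometry(self, clean_study):
        area = clean_study.area
        for bird_id, b in clean_study.ground_truth["birds"].items():
            fx = clean_study.fixes[clean_study.fixes["bird_id"] == bird_id]
            for tr in b["trips"]:
                seg = fx[
                    (fx["timestamp"] >= np.datetime64(tr["start"]))
                    & (fx["timestamp"] <= np.datetime64(tr["end"]))
                ]
                inside = points_in_polygon(seg["lon"], seg["lat"], area.fjord)
                if tr["kind"] == "outside":
                    assert not inside.all()
                else:
                    assert inside.all()

    def test_determinism_byte_identical(self, tmp_path, clean_config):
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_study(simulate_study(clean_config), a)
        write_study(simulate_study(clean_config), b)
        for name in ("fixes.csv", "deployments.csv", "morphometrics.csv",
                     "net_samples.csv", "ground_truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_dip_separates_study_years(self):
        """A bimodal-year config rejects unimodality in most seeds; a
        low-outside year rarely does."""
        reject_2018, reject_2016 = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed).clean(n_birds_per_colony_year=12)
            study = simulate_study(cfg)
            trips, _ = tracks.process_deployments(study.fixes, study.deployments, study.area)
            ranges = tracks.individual_max_range(trips)
            joined = ranges.merge(study.deployments[["bird_id", "year"]], on="bird_id")
            for year, flag in ((2018, "hi"), (2016, "lo")):
                vals = joined[joined["year_y"] == year]["max_range_km"].to_numpy()
                res = dip_test(vals, n_null=999, seed=seed)
                if year == 2018:
                    reject_2018 += res.p_value < 0.05
                else:
                    reject_2016 += res.p_value < 0.05
        assert reject_2018 >= 0.9 * n_seeds
        assert reject_2016 <= 0.2 * n_seeds


class TestMasses:
    def _birds(self, rng, n=200):
        return pd.DataFrame(
            {
                "bird_id": [f"b{i}" for i in range(n)],
                "colony_id": rng.choice(["OBS", "OSS"], n),
                "year": rng.choice([2016, 2017, 2018], n),
                "prop_outside": rng.random(n),
            }
        )

    def test_zero_coefficients_give_equal_masses(self, rng):
        cfg = SimConfig(
            bmc_prop_slope=0.0,
            bmc_year_levels={2016: 0.0, 2017: 0.0, 2018: 0.0},
            bmc_resid_sd=0.0,
            bmc_bird_sd=0.0,
            round_mass_g=0.0,
        )
        out = simulate_masses(cfg, self._birds(rng), rng)
        assert np.allclose(out["mass_capture_g"], out["mass_recapture_g"])

    def test_prop_slope_recovered_in_group_means(self, rng):
        cfg = SimConfig(round_mass_g=0.0)
        birds = self._birds(rng, 4000)
        birds["prop_outside"] = np.where(np.arange(4000) % 2 == 0, 1.0, 0.0)
        birds["year"] = 2016
        out = simulate_masses(cfg, birds, rng)
        bmc = (out["mass_recapture_g"] - out["mass_capture_g"]) / out["mass_capture_g"]
        diff = bmc[birds["prop_outside"] == 1].mean() - bmc[birds["prop_outside"] == 0].mean()
        assert diff == pytest.approx(0.054, abs=0.005)

    def test_condition_slope_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = SimConfig()
            out = simulate_masses(cfg, self._birds(rng, 80), rng)
            fitted = body_condition(out)
            lo, hi = fitted.attrs["slope_ci95"]
            hits += lo <= cfg.condition_slope_g_mm <= hi
        assert hits >= 18  # 95% CI coverage across seeds

    def test_headbill_straddles_sex_cutoff(self, rng):
        out = simulate_masses(SimConfig(), self._birds(rng, 500), rng)
        f = out[out["sex_molecular"] == "female"]["head_bill_mm"]
        m = out[out["sex_molecular"] == "male"]["head_bill_mm"]
        assert f.mean() < 90.5 < m.mean()


def test_study_area_has_fjord_scale_of_study_system():
    area = default_study_area()
    import shapely

    # planar degree area converted at 79 N: ~230 km^2
    lon0, lat0, lon1, lat1 = area.fjord.shapely.bounds
    width_km = (lon1 - lon0) * 111.195 * np.cos(np.radians(78.93))
    height_km = (lat1 - lat0) * 111.195
    assert width_km * height_km == pytest.approx(230, rel=0.05)
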