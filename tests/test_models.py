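import numpy as np
import pandas as pd
import pytest

from cpforage import models as mdl
from cpforage.models import MCMCSettings, PriorSpec
from oracles import logistic_regression_map


def gaussian_frame(rng, n=120):
    years = rng.choice([2016, 2017, 2018], n)
    colony = rng.choice(["OBS", "OSS"], n)
    mu = np.log(5.2) + 0.4 * (years == 2018) + 0.2 * (colony == "OSS")
    return pd.DataFrame(
        {
            "bird_id": [f"b{i}" for i in range(n)],
            "year": years,
            "colony_id": colony,
            "max_range_km": np.exp(mu + 0.5 * rng.standard_normal(n)),
        }
    )


class TestBuildDesign:
    def frame(self):
        return pd.DataFrame(
            {
                "bird_id": ["b1", "b2", "b3"],
                "year": [2016, 2018, 2017],
                "colony_id": ["OBS", "OSS", "OBS"],
                "max_range_km": [5.0, 100.0, 7.0],
                "bmc": [-0.02, 0.01, -0.08],
                "prop_outside": [0.0, 0.5, 0.25],
            }
        )

    def test_m1_reference_row_is_intercept_only(self):
        y, X, g, info = mdl.build_design(mdl.MODEL_SPECS["M1_logrange"], self.frame())
        assert info.columns == ("intercept", "year2017", "year2018", "colony_OSS")
        assert list(X[0]) == [1.0, 0.0, 0.0, 0.0]  # 2016, OBS
        assert y[0] == pytest.approx(np.log(5.0))

    def test_m1_2018_oss_row(self):
        _, X, _, info = mdl.build_design(mdl.MODEL_SPECS["M1_logrange"], self.frame())
        assert list(X[1]) == [1.0, 0.0, 1.0, 1.0]

    def test_m4_cell_means_row(self):
        y, X, g, info = mdl.build_design(mdl.MODEL_SPECS["M4_bmc"], self.frame())
        assert info.columns == (
            "prop_outside", "I(year2016)", "I(year2017)", "I(year2018)", "colony_OSS",
        )
        # 2017 row: proportion plus its own year indicator only
        assert list(X[2]) == [0.25, 0.0, 1.0, 0.0, 0.0]

    def test_unseen_colony_rejected_at_prediction(self, rng, fast_mcmc):
        fit = mdl.fit(mdl.MODEL_SPECS["M1_logrange"], gaussian_frame(rng), mcmc=fast_mcmc)
        bad = pd.DataFrame({"year": [2016], "colony_id": ["ELSEWHERE"]})
        with pytest.raises(ValueError):
            fit.design_rows(bad)

    def test_bernoulli_requires_binary(self):
        df = self.frame().assign(outside=[0.0, 0.5, 1.0], label="x")
        with pytest.raises(ValueError):
            mdl.build_design(mdl.MODEL_SPECS["M2_outside"], df)


class TestOracleEquivalence:
    def test_gaussian_matches_ols_when_variance_pinned(self, rng, fast_mcmc):
        df = gaussian_frame(rng)
        spec = mdl.MODEL_SPECS["M1_logrange"]
        y, X, g, info = mdl.build_design(spec, df)
        priors = PriorSpec(
            beta_scale=np.full(X.shape[1], 100.0), sigma_rate=1e-6, tau_scale=1e-8
        )
        fit = mdl.fit(spec, df, priors=priors, mcmc=fast_mcmc)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = fit.draws["beta"].reshape(-1, X.shape[1])
        z = np.abs(beta.mean(axis=0) - ols) / beta.std(axis=0)
        assert np.all(z < 2.0)

    def test_bernoulli_matches_penalized_logistic(self, rng, fast_mcmc):
        n = 300
        years = rng.choice([2016, 2017, 2018], n)
        colony = rng.choice(["OBS", "OSS"], n)
        eta = -1.5 + 1.2 * (years == 2018) + 0.5 * (colony == "OSS")
        lab = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "outside", "inside")
        df = pd.DataFrame(
            {"bird_id": [f"b{i}" for i in range(n)], "year": years,
             "colony_id": colony, "label": lab}
        )
        data = mdl.prepare_model_data("M2_outside", df)
        spec = mdl.MODEL_SPECS["M2_outside"]
        y, X, g, info = mdl.build_design(spec, data)
        auto = PriorSpec.auto(X, y, "bernoulli")
        priors = PriorSpec(beta_scale=auto.beta_scale, sigma_rate=0.0, tau_scale=1e-8)
        fit = mdl.fit(spec, data, priors=priors, mcmc=fast_mcmc)
        bmap, _ = logistic_regression_map(X, y, priors.beta_scale)
        beta = fit.draws["beta"].reshape(-1, X.shape[1])
        z = np.abs(beta.mean(axis=0) - bmap) / beta.std(axis=0)
        assert np.all(z < 2.0)


class TestDiagnostics:
    def _fake_fit(self, draws_beta):
        spec = mdl.MODEL_SPECS["M4_bmc"]
        info = mdl.DesignInfo(("prop_outside",), (2016,), ("OBS",), "indicators",
                              ("prop_outside",), ("b1",))
        C, D = draws_beta.shape[:2]
        return mdl.PosteriorFit(
            spec, MCMCSettings(chains=C), None, info,
            {"beta": draws_beta, "tau": np.abs(draws_beta[..., 0]) + 0.5,
             "sigma": np.abs(draws_beta[..., 0]) + 0.5},
            np.ones((3, 1)), np.zeros(3), np.zeros(3, dtype=int),
        )

    def test_iid_chains_pass_gates(self, rng):
        fit = self._fake_fit(rng.standard_normal((4, 2000, 1)))
        out = mdl.diagnostics(fit)
        assert out.loc["prop_outside", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert out.loc["prop_outside", "ess"] > 0.8 * 8000
        assert out.attrs["convergence_ok"]

    def test_shifted_chain_fails_rhat(self, rng):
        d = rng.standard_normal((4, 2000, 1))
        d[0] += 5.0
        out = mdl.diagnostics(self._fake_fit(d))
        assert out.loc["prop_outside", "rhat"] > 1.1
        assert not out.attrs["convergence_ok"]

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            mdl.diagnostics(self._fake_fit(rng.standard_normal((1, 2000, 1))))


@pytest.fixture(scope="module")
def m1_fit():
    rng = np.random.default_rng(77)
    fast = MCMCSettings(chains=2, iterations=1600, warmup=800, seed=42)
    return mdl.fit(mdl.MODEL_SPECS["M1_logrange"], gaussian_frame(rng), mcmc=fast)


class TestPostprocessing:
    def test_backtransform_reference_cell(self, m1_fit):
        cell = pd.DataFrame({"year": [2016], "colony_id": ["OBS"]})
        out = mdl.backtransform_median(m1_fit, cell)
        # generating 2016/OBS median is exp(log 5.2) = 5.2 km
        assert out["median"].iloc[0] == pytest.approx(5.2, rel=0.15)
        assert out["q2.5"].iloc[0] < out["median"].iloc[0] < out["q97.5"].iloc[0]

    def test_backtransform_shift_scales_median(self, m1_fit):
        rows = pd.DataFrame({"year": [2016, 2018], "colony_id": ["OBS", "OBS"]})
        out = mdl.backtransform_median(m1_fit, rows)
        beta = m1_fit.flat("year2018")
        ratio = out["median"].iloc[1] / out["median"].iloc[0]
        assert ratio == pytest.approx(np.exp(np.median(beta)), rel=0.05)

    def test_backtransform_rejects_logit_models(self, rng, fast_mcmc):
        n = 120
        df = pd.DataFrame(
            {"bird_id": [f"b{i}" for i in range(n)],
             "year": rng.choice([2016, 2017], n),
             "colony_id": "OBS",
             "label": np.where(rng.random(n) < 0.3, "outside", "inside")}
        )
        fit = mdl.fit(
            mdl.MODEL_SPECS["M2_outside"], mdl.prepare_model_data("M2_outside", df),
            mcmc=fast_mcmc,
        )
        with pytest.raises(ValueError):
            mdl.backtransform_median(fit, pd.DataFrame({"year": [2016], "colony_id": ["OBS"]}))

    def test_contrast_identical_rows_is_null(self, m1_fit):
        row = pd.DataFrame({"year": [2016], "colony_id": ["OBS"]})
        out = mdl.contrast(m1_fit, row, row)
        assert out["mean"] == 0.0 and not out["evidence"]

    def test_contrast_detects_built_in_effect(self, m1_fit):
        a = pd.DataFrame({"year": [2018], "colony_id": ["OBS"]})
        b = pd.DataFrame({"year": [2016], "colony_id": ["OBS"]})
        out = mdl.contrast(m1_fit, a, b)
        assert out["evidence"] and out["mean"] > 0

    def test_ppc_self_consistency(self, m1_fit):
        out = mdl.posterior_predictive_check(m1_fit, n_rep=200, seed=1)
        mids = out[out["summary"].isin(["mean", "sd"])]["tail_prob"]
        assert ((mids > 0.05) & (mids < 0.95)).all()

    def test_ppc_flags_constant_response_misfit(self, rng, fast_mcmc):
        df = gaussian_frame(rng, n=60)
        df["max_range_km"] = 5.2  # zero-variance response
        fit = mdl.fit(mdl.MODEL_SPECS["M1_logrange"], df, mcmc=fast_mcmc)
        fit.y = fit.y + 0.5 * np.random.default_rng(0).standard_normal(len(fit.y))
        out = mdl.posterior_predictive_check(fit, n_rep=200, seed=1)
        sd_tail = out[out["summary"] == "sd"]["tail_prob"].iloc[0]
        assert sd_tail < 0.05 or sd_tail > 0.95


class TestFirstTripTable:
    def test_earliest_trip_of_first_deployment(self):
        trips = pd.DataFrame(
            {
                "bird_id": ["b1", "b1", "b1"],
                "year": [2018] * 3,
                "label": ["inside", "outside", "outside"],
                "start": pd.to_datetime(["2018-07-02", "2018-07-03", "2018-07-20"]),
                "deployment_start": pd.to_datetime(
                    ["2018-07-01", "2018-07-01", "2018-07-19"]
                ),
            }
        )
        out = mdl.first_trip_table(trips)
        assert len(out) == 1
        assert out["firsttrip_outside"].iloc[0] == 0.0  # first trip was inside
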