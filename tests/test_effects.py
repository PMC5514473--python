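"""Rate-ratio reporting, suites, subgroups, and two-pollutant adjustment."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import airdlm
from airdlm.config import SimConfig
from airdlm.design import LagStructure
from airdlm.effects import Z_95, rr_from_coef

from conftest import BETA_UNIT


class TestRrFromCoef:
    def test_null_coefficient_gives_unit_rr(self):
        est = rr_from_coef(0.0, 0.01, 10.0)
        assert est.rr == 1.0
        assert est.ci_low < 1.0 < est.ci_high
        assert np.isclose(np.sqrt(est.ci_low * est.ci_high), 1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_table_style_example(self):
        # beta 0.0031511 per unit, increment 10 -> RR 1.032 (1.004-1.061)
        est = rr_from_coef(0.0031511, 0.0014, 10.0)
        assert est.rr == pytest.approx(np.exp(0.031511), rel=1e-12)
        assert est.rr == pytest.approx(1.0320, abs=5e-5)
        assert est.ci_low == pytest.approx(1.0041, abs=5e-4)
        assert est.ci_high == pytest.approx(1.0609, abs=5e-4)
        assert est.p_value < 0.05

    def test_increment_scaling_identity(self):
        one = rr_from_coef(0.004, 0.002, 1.0)
        ten = rr_from_coef(0.004, 0.002, 10.0)
        assert ten.rr == pytest.approx(one.rr**10, rel=1e-12)
        assert ten.ci_low == pytest.approx(one.ci_low**10, rel=1e-12)

    @given(
        beta=st.floats(-0.05, 0.05),
        se=st.floats(1e-6, 0.02),
        inc=st.sampled_from([1.0, 10.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_wald_duality(self, beta, se, inc):
        est = rr_from_coef(beta, se, inc)
        assert est.ci_low <= est.rr <= est.ci_high
        excludes_one = est.ci_low > 1.0 or est.ci_high < 1.0
        # p < 0.05 exactly when the 95% CI excludes 1 (z_crit vs 1.959964)
        assert (est.p_value < 2 * (1 - 0.975)) == excludes_one or np.isclose(
            abs(beta) / se, Z_95, atol=1e-9
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rr_from_coef(0.1, -0.1, 10.0)
        with pytest.raises(ValueError):
            rr_from_coef(0.1, 0.1, 0.0)


class TestSuites:
    def test_single_lag_suite_recovers_pure_lag0_effect(self, default_panel):
        panel, truth, _ = default_panel
        ests = airdlm.run_single_lag_suite(panel, "pm10")
        assert [e.lag for e in ests] == list(range(8))
        lag0 = ests[0]
        assert abs(lag0.beta - BETA_UNIT) < 3 * lag0.se
        others_covering_one = sum(e.ci_low <= 1.0 <= e.ci_high for e in ests[1:])
        assert others_covering_one >= 5

    def test_co_uses_1mg_increment(self, default_panel):
        panel, _, _ = default_panel
        est = airdlm.run_single_lag_suite(panel, "co", lags=[0])[0]
        assert est.increment == 1.0
        assert est.rr == pytest.approx(np.exp(est.beta), rel=1e-12)

    def test_constrained_repeats_stratum_estimate(self, default_panel):
        panel, _, _ = default_panel
        ests = airdlm.run_dlm_suite(panel, "pm10", structure="constrained")
        assert len(ests) == 8
        by_lag = {e.lag: e for e in ests}
        assert by_lag[1].rr == by_lag[2].rr
        assert len({by_lag[l].rr for l in (3, 4, 5, 6, 7)}) == 1
        assert by_lag[1].lag_group == (1, 2)

    def test_saturated_strata_reproduce_unconstrained(self, default_panel):
        panel, _, _ = default_panel
        saturated = LagStructure("constrained", strata=tuple((l,) for l in range(8)))
        con = airdlm.run_dlm_suite(panel, "pm10", structure=saturated)
        unc = airdlm.run_dlm_suite(panel, "pm10", structure="unconstrained")
        for a, b in zip(con, unc):
            assert a.rr == pytest.approx(b.rr, abs=1e-8)
            assert a.se == pytest.approx(b.se, rel=1e-6)

    def test_constant_exposure_raises_per_lag(self, default_panel):
        panel, _, _ = default_panel
        flat = panel.copy()
        flat["so2"] = 50.0
        with pytest.warns(UserWarning, match="rank"):
            with pytest.raises(RuntimeError, match="lag 0"):
                airdlm.run_single_lag_suite(flat, "so2", lags=[0])


class TestSubgroups:
    def test_all_stratum_equals_unstratified(self, default_panel):
        panel, _, _ = default_panel
        direct = airdlm.run_single_lag_suite(panel, "pm10", lags=[0])[0]
        via_subgroup = airdlm.run_subgroups(panel, "pm10", strata=("all",), lags=[0])[0]
        assert via_subgroup.rr == direct.rr

    def test_sex_strata_share_common_effect(self, default_panel):
        # male/female are binomial thinnings of the total, which preserves
        # the log-linear effect; estimates must agree within joint 3 SE
        panel, _, _ = default_panel
        ests = airdlm.run_subgroups(panel, "pm10", strata=("male", "female"), lags=[0])
        male, female = ests
        joint_se = np.hypot(male.se, female.se)
        assert abs(male.beta - female.beta) < 3 * joint_se

    def test_doubled_elderly_effect_detected(self):
        # build age strata with different true effects by summing two
        # independently generated count series on shared exposures
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_days=800, seed=seed,
                lag_log_rr=(BETA_UNIT, 0, 0, 0, 0, 0, 0, 0),
                overdispersion=1.5,
            )
            panel, truth = airdlm.simulate_panel(cfg)
            rng = np.random.default_rng(seed + 1000)
            # over-60 counts: Poisson with twice the lag-0 log-RR
            pm = panel["pm10"].to_numpy()
            eta = truth.linear_predictor + BETA_UNIT * pm  # doubles the lag-0 slope
            over = rng.poisson(0.31 * np.exp(eta))
            under = rng.poisson(0.69 * truth.mu)
            panel = panel.copy()
            panel["over60"] = over
            panel["under60"] = under
            panel["all"] = over + under
            panel["male"] = 0
            panel["female"] = panel["all"]
            ests = airdlm.run_subgroups(panel, "pm10", strata=("over60", "under60"), lags=[0])
            wins += ests[0].beta > ests[1].beta
        assert wins >= 9

    def test_zero_stratum_rejected(self, default_panel):
        panel, _, _ = default_panel
        dead = panel.copy()
        dead["female"] = 0
        with pytest.raises((ValueError, RuntimeError)):
            airdlm.run_subgroups(dead, "pm10", strata=("female",), lags=[0])


class TestTwoPollutant:
    def test_same_pollutant_rejected(self, default_panel):
        panel, _, _ = default_panel
        with pytest.raises(ValueError, match="differ"):
            airdlm.run_two_pollutant(panel, "no2", "no2")

    def test_independent_copollutant_leaves_estimate_alone(self):
        # with an uncorrelated co-pollutant there is nothing to adjust for
        diffs = []
        for seed in range(5):
            corr = np.eye(6)
            cfg = SimConfig(
                n_days=800, seed=seed, pollutant_correlation=corr,
                lag_log_rr=(BETA_UNIT, 0, 0, 0, 0, 0, 0, 0),
            )
            panel, _ = airdlm.simulate_panel(cfg)
            unadj = airdlm.run_single_lag_suite(panel, "pm10", lags=[0])[0]
            adj = airdlm.run_two_pollutant(panel, "pm10", "so2")
            diffs.append(abs(adj.beta - unadj.beta) / unadj.se)
        assert np.mean(diffs) < 1.0

    def test_confounded_null_pollutant_corrected_by_adjustment(self):
        # NO2 has no effect but is strongly correlated with PM10, which
        # does; adjustment should pull the NO2 estimate back toward null
        covered_adj = 0
        biased_unadj = 0
        n_rep = 20
        for seed in range(n_rep):
            corr = np.eye(6)
            i, j = 2, 5  # no2, pm10
            corr[i, j] = corr[j, i] = 0.9
            cfg = SimConfig(
                n_days=800, seed=seed, pollutant_correlation=corr,
                lag_log_rr=(2 * BETA_UNIT, 0, 0, 0, 0, 0, 0, 0),
                effect_pollutant="pm10",
            )
            panel, _ = airdlm.simulate_panel(cfg)
            unadj = airdlm.run_single_lag_suite(panel, "no2", lags=[0])[0]
            adj = airdlm.run_two_pollutant(panel, "no2", "pm10")
            covered_adj += adj.ci_low <= 1.0 <= adj.ci_high
            biased_unadj += unadj.ci_low > 1.0
        assert biased_unadj >= n_rep * 0.6
        assert covered_adj >= n_rep * 0.8

    def test_estimate_is_labelled(self, default_panel):
        panel, _, _ = default_panel
        est = airdlm.run_two_pollutant(panel, "pm10", "o3")
        assert est.co_pollutant == "o3"
        assert est.variant == "two-pollutant"


def test_forest_plot_renders_estimates(default_panel, tmp_path):
    from airdlm.plots import save_forest

    panel, _, _ = default_panel
    ests = airdlm.run_dlm_suite(panel, "pm10", structure="unconstrained")
    out = tmp_path / "forest.png"
    save_forest(ests, out)
    assert out.stat().st_size > 0
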