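"""Spline bases, lag structures, day-of-week terms, and assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import airdlm
from airdlm.config import SimConfig
from airdlm.design import (
    LagStructure,
    SplineSpec,
    assemble,
    dow_terms,
    lag_basis,
    natural_cubic_basis,
    time_spline,
)
from airdlm.glm import fit


def truncated_power_natural_spline(x, knots, coefs):
    """Hand-built natural cubic spline (independent span oracle).

    Truncated-power representation: f = c0 + c1*x + sum_k theta_k (x-xi_k)+^3
    subject to sum theta_k = 0 and sum theta_k xi_k = 0, which enforce
    linearity beyond the last knot; linearity below the first knot holds
    because the cubic terms vanish there.
    """
    K = len(knots)
    theta_free = np.asarray(coefs, dtype=float)  # K-2 free values
    A = np.array([[1.0, 1.0], [knots[-2], knots[-1]]])
    b = -np.array([theta_free.sum(), (theta_free * knots[:-2]).sum()])
    tail = np.linalg.solve(A, b)
    theta = np.concatenate([theta_free, tail])
    f = 0.3 + 0.7 * x
    for t, xi in zip(theta, knots):
        f = f + t * np.maximum(x - xi, 0.0) ** 3
    return f


class TestNaturalCubicBasis:
    def test_df1_is_affine_in_x(self):
        x = np.linspace(3.0, 9.0, 40)
        basis, _ = natural_cubic_basis(x, SplineSpec("x", 1))
        assert basis.shape == (40, 1)
        fit_ab = np.polyfit(x, basis[:, 0], 1)
        np.testing.assert_allclose(np.polyval(fit_ab, x), basis[:, 0], atol=1e-12)

    @pytest.mark.parametrize("df", [1, 2, 3, 4, 6, 8])
    def test_column_count_equals_df(self, df):
        x = np.linspace(0, 100, 120)
        basis, _ = natural_cubic_basis(x, SplineSpec("x", df))
        assert basis.shape[1] == df

    @pytest.mark.parametrize("df", [2, 4, 6])
    def test_linear_beyond_boundary_knots(self, df):
        # second differences outside the boundary knots must vanish
        x = np.linspace(0, 10, 200)
        _, knots = natural_cubic_basis(x, SplineSpec("x", df))
        h = 0.05
        for side in (knots[0] - 2.0, knots[-1] + 2.0):
            pts = np.array([side - h, side, side + h])
            basis, _ = natural_cubic_basis(pts, SplineSpec("x", df), knots=knots)
            second = basis[0] - 2 * basis[1] + basis[2]
            np.testing.assert_allclose(second, 0.0, atol=1e-6)

    def test_spans_hand_built_natural_spline(self):
        x = np.linspace(1.0, 100.0, 100)
        spec = SplineSpec("x", 4)
        basis, knots = natural_cubic_basis(x, spec)
        target = truncated_power_natural_spline(x, knots, [2e-4, -3e-4, 1.5e-4])
        design = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        assert np.abs(design @ coef - target).max() < 1e-8

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_cubic_basis(np.array([1.0, 1.0, 2.0]), SplineSpec("x", 4))


class TestTimeSpline:
    @pytest.mark.parametrize(
        "n_days,df_per_year,expected",
        [(2191, 7, 42), (365, 1, 1), (730, 7, 14)],
    )
    def test_total_df(self, n_days, df_per_year, expected):
        dates = pd.date_range("2010-01-01", periods=n_days, freq="D")
        basis, _, total = time_spline(dates, df_per_year)
        assert total == expected
        assert basis.shape == (n_days, expected)

    def test_excessive_df_rejected(self):
        dates = pd.date_range("2010-01-01", periods=40, freq="D")
        with pytest.raises(ValueError, match="df"):
            time_spline(dates, 365)


class TestLagBasis:
    def test_unconstrained_row_is_reversed_window(self):
        mat, valid = lag_basis(np.array([1.0, 2, 3, 4, 5]), LagStructure(max_lag=2))
        np.testing.assert_array_equal(mat[2], [3.0, 2.0, 1.0])
        assert list(valid) == [False, False, True, True, True]

    def test_column_counts(self):
        assert lag_basis(np.arange(10.0), LagStructure("constrained"))[0].shape[1] == 3
        assert lag_basis(np.arange(10.0), LagStructure("unconstrained"))[0].shape[1] == 8
        assert lag_basis(np.arange(10.0), LagStructure("single", lag=3))[0].shape[1] == 1

    def test_constant_exposure_gives_stratum_sums(self):
        c = 4.0
        mat, valid = lag_basis(np.full(20, c), LagStructure("constrained"))
        np.testing.assert_allclose(mat[valid], np.tile([c, 2 * c, 5 * c], (valid.sum(), 1)))

    @given(st.integers(0, 7))
    @settings(max_examples=8, deadline=None)
    def test_single_lag_shifts_by_lag(self, lag):
        x = np.arange(30.0)
        mat, valid = lag_basis(x, LagStructure("single", lag=lag))
        np.testing.assert_array_equal(mat[valid, 0], x[: 30 - lag])

    def test_strata_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            LagStructure("constrained", strata=((0,), (1, 2), (3, 4)))


class TestDowTerms:
    def test_indicator_week(self):
        dates = pd.date_range("2012-01-01", periods=7, freq="D")
        block = dow_terms(dates)
        assert block.shape == (7, 6)
        assert (block.sum(axis=0) == 1.0).all()
        saturday = dates[dates.weekday == 5][0]
        assert block.loc[saturday].sum() == 0.0

    def test_holiday_every_day_gives_zeros(self):
        dates = pd.date_range("2012-01-01", periods=5, freq="D")
        block = dow_terms(dates, mode="days-since-holiday", holidays=dates)
        np.testing.assert_array_equal(block.to_numpy().ravel(), np.zeros(5))

    def test_single_holiday_counts_up(self):
        dates = pd.date_range("2012-01-01", periods=5, freq="D")
        block = dow_terms(dates, mode="days-since-holiday", holidays=dates[:1])
        np.testing.assert_array_equal(block.to_numpy().ravel(), [0, 1, 2, 3, 4])

    def test_holiday_mode_requires_calendar(self):
        dates = pd.date_range("2012-01-01", periods=5, freq="D")
        with pytest.raises(ValueError, match="holiday"):
            dow_terms(dates, mode="days-since-holiday")


@pytest.fixture(scope="module")
def panel():
    panel, _ = airdlm.simulate_panel(SimConfig(n_days=2191, seed=17))
    return panel


class TestAssemble:
    def test_unconstrained_column_count(self, panel):
        dm = assemble(panel, "pm10", LagStructure("unconstrained"))
        assert dm.X.shape[1] == 1 + 8 + 42 + 4 + 4 + 6  # 65
        assert len(dm.X) == 2191 - 7

    def test_single_lag_column_count(self, panel):
        dm = assemble(panel, "no2", LagStructure("single", lag=7))
        assert dm.X.shape[1] == 58

    def test_two_pollutant_adds_one_column(self, panel):
        dm = assemble(panel, "no2", LagStructure("single", lag=0), second_pollutant="co")
        assert dm.X.shape[1] == 59
        assert dm.blocks["co_pollutant"] == ["co_lag0"]

    def test_lag_map_covers_exposure_columns_once(self, panel):
        dm = assemble(panel, "pm10", LagStructure("constrained"))
        covered = [l for col in dm.exposure_columns for l in dm.lag_map[col]]
        assert sorted(covered) == list(range(8))

    def test_no_missing_entries(self, panel):
        dm = assemble(panel, "o3", LagStructure("unconstrained"))
        assert not dm.X.isna().any().any()

    def test_missing_cell_named_in_error(self, panel):
        bad = panel.copy()
        bad.loc[100, "so2"] = np.nan
        with pytest.raises(ValueError, match="so2"):
            assemble(bad, "so2", LagStructure("single", lag=0))

    def test_date_translation_leaves_fit_invariant(self):
        cfg = SimConfig(n_days=400, seed=19)
        panel, _ = airdlm.simulate_panel(cfg)
        shifted = panel.copy()
        shifted["date"] = shifted["date"] + pd.Timedelta(days=7)  # same weekday
        dm1 = assemble(panel, "pm10", LagStructure("single", lag=0))
        dm2 = assemble(shifted, "pm10", LagStructure("single", lag=0))
        y = panel.set_index("date")["all"].loc[dm1.dates].to_numpy()
        np.testing.assert_allclose(fit(y, dm1).fitted, fit(y, dm2).fitted, rtol=1e-8)

    def test_rank_deficiency_warned(self, panel):
        flat = panel.copy()
        flat["co"] = 2.5
        with pytest.warns(UserWarning, match="rank"):
            assemble(flat, "co", LagStructure("single", lag=0))

    def test_complete_case_gaps_respect_calendar_lags(self, panel):
        # removing one day invalidates the 7 following days for an 8-lag model
        gappy = panel.drop(index=500).reset_index(drop=True)
        dm = assemble(gappy, "pm10", LagStructure("unconstrained"))
        lost = set(pd.date_range(panel.loc[500, "date"],
                                 periods=8, freq="D"))
        assert lost.isdisjoint(set(dm.dates))
        assert len(dm.X) == 2191 - 7 - 8
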