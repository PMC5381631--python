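"""Log-log slopes, common-age restriction, pair ratios and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cohortaccel as ca
from cohortaccel.cohorts import STANDARD_BANDS

from conftest import (
    PRINTED_GB_RATIOS,
    PRINTED_GB_SUMMARY,
    grid_refine_slope,
    make_ratios,
    two_point_slope,
)

BANDS3 = [ca.AgeBand(25, 29), ca.AgeBand(30, 34), ca.AgeBand(35, 39)]


def power_law(bands, c, m):
    return [c * b.representative_age**m for b in bands]


class TestLoglogSlope:
    @pytest.mark.parametrize("m", [-2.0, 0.0, 1.5, 4.0, 9.0])
    @pytest.mark.parametrize("c", [1e-6, 1.0, 250.0])
    def test_power_law_recovers_exponent(self, c, m):
        fit = ca.loglog_slope(BANDS3, power_law(BANDS3, c, m))
        assert fit.slope == pytest.approx(m, abs=1e-12)
        assert fit.n_points == 3

    @given(
        m=st.floats(-5, 10),
        c=st.floats(1e-4, 1e4),
        n=st.integers(2, len(STANDARD_BANDS)),
    )
    def test_power_law_property(self, m, c, n):
        bands = STANDARD_BANDS[:n]
        fit = ca.loglog_slope(bands, power_law(bands, c, m))
        assert fit.slope == pytest.approx(m, abs=1e-8)

    def test_youngest_gb_cohort_slope(self, table1):
        # cohort 1975-79: rates 4.7, 7.4, 10.1 at ages 27.5, 32.5, 37.5
        fit = ca.loglog_slope(BANDS3, [4.7, 7.4, 10.1], 1975)
        oracle = grid_refine_slope([27.5, 32.5, 37.5], [4.7, 7.4, 10.1])
        assert fit.slope == pytest.approx(2.4733622584121746, abs=1e-12)
        assert fit.slope == pytest.approx(oracle, abs=1e-6)
        assert fit.slope == pytest.approx(2.47, abs=0.01)

    def test_two_points_equal_closed_form(self):
        # cohort 1895-99: two observed cells only
        bands = [ca.AgeBand(80, 84), ca.AgeBand(85)]
        fit = ca.loglog_slope(bands, [9.5, 17.0], 1895)
        assert fit.slope == pytest.approx(two_point_slope(82.5, 9.5, 87.5, 17.0))
        assert fit.slope == pytest.approx(9.90, abs=0.02)

    def test_zero_rate_band_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fit = ca.loglog_slope(BANDS3, [4.7, 0.0, 10.1])
        assert fit.n_points == 2
        assert ca.AgeBand(30, 34) not in fit.bands_used
        assert "30-34" in caplog.text

    def test_fewer_than_two_usable_points_is_missing(self):
        assert ca.loglog_slope(BANDS3, [4.7, 0.0, np.nan]) is None

    def test_scale_invariance(self):
        rates = [4.7, 7.4, 10.1]
        base = ca.loglog_slope(BANDS3, rates).slope
        scaled = ca.loglog_slope(BANDS3, [r * 73000.0 for r in rates]).slope
        assert scaled == pytest.approx(base, rel=1e-14)

    def test_log_base_invariance(self):
        # base-10 OLS done independently must match the natural-log slope
        rates = np.array([4.7, 7.4, 10.1])
        ages = np.array([b.representative_age for b in BANDS3])
        x10, y10 = np.log10(ages), np.log10(rates)
        slope10 = np.polyfit(x10, y10, 1)[0]
        assert ca.loglog_slope(BANDS3, rates).slope == pytest.approx(
            slope10, rel=1e-13
        )


class TestCommonBands:
    def test_oldest_pair(self, table1):
        assert ca.common_bands(table1, 1895, 1900) == [
            ca.AgeBand(80, 84), ca.AgeBand(85)
        ]

    def test_youngest_pair(self, table1):
        assert ca.common_bands(table1, 1970, 1975) == BANDS3

    def test_disjoint_rows_empty(self, table1):
        assert ca.common_bands(table1, 1895, 1975) == []


class TestPairRatio:
    def test_youngest_gb_pair(self, table1):
        pr = ca.pair_ratio(table1, 1975)
        assert pr.common_bands == tuple(BANDS3)
        assert pr.log2_ratio == pytest.approx(-0.29374889932967196, abs=1e-12)
        assert pr.log2_ratio == pytest.approx(-0.28, abs=0.02)

    def test_1920_pair(self, table1):
        pr = ca.pair_ratio(table1, 1920)
        assert len(pr.common_bands) == 6  # 60-64 ... 85+
        assert pr.log2_ratio == pytest.approx(-0.03784046481170663, abs=1e-12)
        assert pr.log2_ratio == pytest.approx(-0.04, abs=0.02)

    def test_identical_rows_give_zero(self):
        rate = np.array([[3.0, 6.0, 11.0], [3.0, 6.0, 11.0]])
        table = ca.CohortTable(cohort_starts=[1970, 1975], bands=BANDS3, rate=rate)
        assert ca.pair_ratio(table, 1975).log2_ratio == 0.0

    def test_missing_prior_cohort_is_hard_error(self, table1):
        with pytest.raises(ValueError, match="prior cohort"):
            ca.pair_ratio(table1, 1895)

    def test_restriction_to_common_bands_is_effective(self):
        # adding a band observed in only one cohort must not move the ratio
        rate = np.array(
            [[3.0, 6.0, 11.0, np.nan], [4.0, 7.0, 13.0, 20.0]]
        )
        bands = BANDS3 + [ca.AgeBand(40, 44)]
        table = ca.CohortTable(cohort_starts=[1970, 1975], bands=bands, rate=rate)
        trimmed = ca.CohortTable(
            cohort_starts=[1970, 1975], bands=BANDS3, rate=rate[:, :3]
        )
        assert ca.pair_ratio(table, 1975).log2_ratio == pytest.approx(
            ca.pair_ratio(trimmed, 1975).log2_ratio, rel=1e-14
        )

    def test_fewer_than_two_common_bands_is_missing(self):
        rate = np.array([[3.0, np.nan, np.nan], [np.nan, np.nan, 13.0]])
        table = ca.CohortTable(cohort_starts=[1970, 1975], bands=BANDS3, rate=rate)
        assert ca.pair_ratio(table, 1975).is_missing

    def test_sign_matches_slope_difference(self, table1):
        for pr in ca.all_pair_ratios(table1):
            if not pr.is_missing:
                assert np.sign(pr.log2_ratio) == np.sign(
                    pr.slope_recent - pr.slope_prior
                ) or pr.log2_ratio == 0


class TestScaleInvariance:
    def test_whole_pipeline_invariant_to_rate_rescaling(self, table1):
        scaled = ca.CohortTable(
            cohort_starts=list(table1.cohort_starts),
            bands=list(table1.bands),
            rate=table1.rate * 7.3,
        )
        base = ca.summarize(ca.all_pair_ratios(table1))
        other = ca.summarize(ca.all_pair_ratios(scaled))
        assert other.mean == pytest.approx(base.mean, rel=1e-12)
        assert other.se == pytest.approx(base.se, rel=1e-12)
        assert other.z == pytest.approx(base.z, rel=1e-12)


class TestSummarize:
    def test_printed_gb_ratios_reproduce_printed_summary(self):
        s = ca.summarize(make_ratios(PRINTED_GB_RATIOS))
        assert round(s.mean, 2) == PRINTED_GB_SUMMARY["mean"]
        assert round(s.se, 2) == PRINTED_GB_SUMMARY["se"]
        assert round(s.z, 2) == PRINTED_GB_SUMMARY["z"]
        assert s.n == 16

    def test_symmetric_ratios_average_to_zero(self):
        s = ca.summarize(make_ratios([-1.0, 1.0]))
        assert s.mean == 0.0 and s.z == 0.0

    def test_mean_is_log2_of_geometric_mean_of_slope_ratios(self, table1):
        ratios = ca.all_pair_ratios(table1)
        s = ca.summarize(ratios)
        gm = np.prod(
            [r.slope_recent / r.slope_prior for r in ratios]
        ) ** (1.0 / len(ratios))
        assert s.mean == pytest.approx(np.log2(gm), rel=1e-10)

    def test_missing_ratios_excluded_from_n(self):
        s = ca.summarize(make_ratios([None, -0.1, -0.3]))
        assert s.n == 2
        assert s.mean == pytest.approx(-0.2)

    def test_degenerate_inputs_are_hard_errors(self):
        with pytest.raises(ValueError, match="zero standard error"):
            ca.summarize(make_ratios([-0.1, -0.1, -0.1]))
        with pytest.raises(ValueError, match="at least 2"):
            ca.summarize(make_ratios([-0.1]))

    def test_z_times_se_equals_mean(self, table1):
        s = ca.summarize(ca.all_pair_ratios(table1))
        assert s.z * s.se == pytest.approx(s.mean, rel=1e-12)


class TestPointwiseAcceleration:
    def test_power_law_is_flat_at_exponent(self, gb_spec):
        bands = STANDARD_BANDS
        rate = np.array([power_law(bands, 2.0, 5.0)] * 2)
        table = ca.CohortTable(cohort_starts=[1970, 1975], bands=bands, rate=rate)
        curve = ca.pointwise_acceleration(table, 1975)
        assert len(curve.points) == len(bands) - 1
        for _, acc in curve.points:
            assert acc == pytest.approx(5.0, abs=1e-10)

    def test_two_cell_cohort_single_point(self, table1):
        curve = ca.pointwise_acceleration(table1, 1895)
        assert len(curve.points) == 1
        age, acc = curve.points[0]
        assert age == pytest.approx(np.sqrt(82.5 * 87.5))
        assert acc == pytest.approx(two_point_slope(82.5, 9.5, 87.5, 17.0))

    def test_monotone_rates_give_positive_acceleration(self, table1):
        for c in table1.cohort_starts:
            row = table1.row(c)
            if np.isfinite(row).sum() >= 2:
                curve = ca.pointwise_acceleration(table1, c)
                assert all(acc > 0 for _, acc in curve.points)

    def test_single_cell_cohort_rejected(self):
        rate = np.array([[np.nan, 5.0, np.nan], [1.0, 2.0, 4.0]])
        table = ca.CohortTable(cohort_starts=[1970, 1975], bands=BANDS3, rate=rate)
        with pytest.raises(ValueError, match="at least 2"):
            ca.pointwise_acceleration(table, 1970)
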