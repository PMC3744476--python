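"""Soil/growth statistics: depth totals, summary t tests, fold ratios,
OLS recovery, interior moisture-carbon correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fairycircles.fieldstats import (
    SummaryStat,
    depth_weighted_sum,
    fold_ratio,
    interior_correlation,
    ols_fit,
    t_test_summary,
)
from fairycircles.soil import SoilSample, gen_soil_transect


def _layer(top, bottom, moisture, soc=0.05):
    return SoilSample(
        site_id=0,
        zone="circle_center",
        distance_from_center=0.0,
        depth_top=top,
        depth_bottom=bottom,
        moisture_pct=moisture,
        soc_pct=soc,
    )


class TestDepthWeightedSum:
    def test_single_layer_arithmetic(self):
        # 2.2% over 0.3 m at 1738 kg/m^3 -> 0.022 * 1738 * 0.3 = 11.47 kg/m^2
        total = depth_weighted_sum([_layer(0.0, 0.3, 2.2)])
        assert total == pytest.approx(0.022 * 1738 * 0.3, rel=1e-12)

    def test_zero_concentration_gives_zero(self):
        assert depth_weighted_sum([_layer(0.0, 0.3, 0.0)]) == 0.0

    def test_doubling_thickness_doubles_total(self):
        one = depth_weighted_sum([_layer(0.0, 0.3, 2.2)])
        two = depth_weighted_sum([_layer(0.0, 0.6, 2.2)])
        assert two == pytest.approx(2 * one)

    @given(
        split=st.floats(min_value=0.05, max_value=0.45),
        conc=st.floats(min_value=0.1, max_value=30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_reslicing_invariance(self, split, conc):
        whole = depth_weighted_sum([_layer(0.0, 0.5, conc)])
        sliced = depth_weighted_sum([_layer(0.0, split, conc), _layer(split, 0.5, conc)])
        assert sliced == pytest.approx(whole, rel=1e-12)

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            depth_weighted_sum([_layer(0.0, 0.3, 2.0), _layer(0.2, 0.5, 2.0)])


class TestTTestSummary:
    def test_field_moisture_contrast_is_highly_significant(self):
        res = t_test_summary(SummaryStat(2.2, 0.2, 11), SummaryStat(0.95, 0.18, 11))
        assert res.p_two_sided < 0.001
        assert res.t > 0

    def test_biomass_totals_significant(self):
        res = t_test_summary(SummaryStat(0.73, 0.05, 5), SummaryStat(1.04, 0.09, 5))
        assert res.p_two_sided < 0.05

    def test_identical_groups_give_null_result(self):
        res = t_test_summary(SummaryStat(1.0, 0.1, 10), SummaryStat(1.0, 0.1, 10))
        assert res.t == 0.0
        assert res.p_two_sided == 1.0

    def test_matches_raw_welch_test(self, rng):
        """Summary-based Welch t equals scipy's raw-data Welch t when raw
        samples are constructed to have exactly the summarized moments."""

        def forced(mean, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        a = forced(2.2, 0.2 * np.sqrt(11), 11)
        b = forced(0.95, 0.18 * np.sqrt(11), 11)
        raw = sps.ttest_ind(a, b, equal_var=False)
        summ = t_test_summary(SummaryStat(2.2, 0.2, 11), SummaryStat(0.95, 0.18, 11))
        assert summ.t == pytest.approx(raw.statistic, abs=1e-9)
        assert summ.p_two_sided == pytest.approx(raw.pvalue, abs=1e-9)

    def test_paired_from_summaries_rejected(self):
        with pytest.raises(ValueError):
            t_test_summary(
                SummaryStat(1.0, 0.1, 5), SummaryStat(2.0, 0.1, 5), flavor="paired"
            )


class TestFoldRatio:
    def test_moisture_fold(self):
        assert fold_ratio(2.2, 0.95) == 2.3

    def test_biomass_fold(self):
        assert fold_ratio(1.04, 0.73) == 1.4

    def test_identity(self):
        assert fold_ratio(3.14, 3.14) == 1.0

    @given(
        a=st.floats(min_value=0.1, max_value=100),
        b=st.floats(min_value=0.1, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_product_before_rounding(self, a, b):
        assert fold_ratio(a, b, decimals=12) * fold_ratio(b, a, decimals=12) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio(1.0, 0.0)


class TestOlsFit:
    def test_exact_linear_data_recovered(self):
        x = np.linspace(0, 10, 20)
        y = 3.0 + 2.0 * x
        res = ols_fit(x, y)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["coefficients"]["intercept"] == pytest.approx(3.0)
        assert res["coefficients"]["x0"] == pytest.approx(2.0)

    def test_orthogonal_response_near_zero_r2(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert ols_fit(x, y)["r_squared"] < 0.05

    def test_rainfall_regression_coefficients_recovered(self, rng):
        """Simulated sites from MAP = -63 lat + 266 lon - 2501 plus noise:
        the coefficients come back within two standard errors."""
        n = 60
        lat = rng.uniform(-26, -24, n)
        lon = rng.uniform(15.5, 16.5, n)
        map_mm = -63 * lat + 266 * lon - 2501 + rng.normal(0, 20, n)
        X = pd.DataFrame({"lat": lat, "lon": lon})
        res = ols_fit(X, map_mm)
        for name, true in [("lat", -63.0), ("lon", 266.0)]:
            est = res["coefficients"][name]
            se = res["coef_se"][name]
            assert abs(est - true) < 2 * se + 1e-9

    def test_rank_deficient_design_rejected(self):
        x = np.ones(10)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError):
            ols_fit(X, np.arange(10.0))


class TestInteriorCorrelation:
    def test_generator_construction_yields_negative_correlation(self):
        samples = gen_soil_transect(n_sites=5, noise_sd=0.1, seed=0)
        res = interior_correlation(samples)
        assert res["slope_sign"] == -1
        assert res["p_two_sided"] < 0.05

    def test_perfect_anticorrelation(self):
        rows = []
        for d, (sm, soc) in enumerate([(4.0, 0.01), (3.0, 0.02), (2.0, 0.03), (1.0, 0.04)]):
            rows.append(
                SoilSample(0, "circle_center" if d == 0 else "periphery",
                           float(d) * 0.5, 0.0, 0.3, sm, soc)
            )
        res = interior_correlation(rows, interior_radius=2.4)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope_sign"] == -1

    def test_constant_soc_rejected(self):
        rows = [
            SoilSample(0, "periphery", float(d) * 0.5, 0.0, 0.3, 4.0 - d, 0.05)
            for d in range(5)
        ]
        with pytest.raises(ValueError):
            interior_correlation(rows, interior_radius=2.4)

    def test_too_few_interior_points_rejected(self):
        rows = [
            SoilSample(0, "periphery", 0.5, 0.0, 0.3, 2.0, 0.05),
            SoilSample(0, "periphery", 1.0, 0.0, 0.3, 1.8, 0.06),
        ]
        with pytest.raises(ValueError):
            interior_correlation(rows, interior_radius=2.4)
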