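import math

import numpy as np
import pytest

from tunefree import features, fitting, models
from tunefree.dataset import GRID
from tunefree.features import SampledCurve, extract, sample_fit, zscore_agreement
from tunefree.fitting import FitConfig

from _oracles import feature_scan
from conftest import make_curve

COMPARED = [
    "GlobalMinimum", "GlobalMaximum", "GlobalMinimumAngle", "GlobalMaximumAngle",
    "Maximum_left", "Maximum_right", "MaximumAngle_left", "MaximumAngle_right",
    "PeakToPeak_left", "PeakToPeak_right", "DeltaPeakToPeak",
    "InnerMinimum", "InnerMinimumAngle", "OuterMinimumAngle",
    "InnerWidth_left", "InnerWidth_right", "DeltaInnerWidth",
    "OuterWidth_left", "OuterWidth_right", "DeltaOuterWidth",
    "Bandwidth25_left", "Bandwidth25_right", "Bandwidth50_left", "Bandwidth50_right",
    "Bandwidth75_left", "Bandwidth75_right",
    "Skewness_right", "minusSkewness_left", "DeltaSkewness",
    "CircularVariance",
]


def assert_rows_match(got, expected, names=COMPARED):
    for name in names:
        if name not in expected:
            continue
        e = expected[name]
        g = got[name]
        if isinstance(e, float) and math.isnan(e):
            assert math.isnan(g), name
        else:
            assert g == pytest.approx(e, rel=1e-9, abs=1e-9), name


class TestWorkedExample:
    def test_direct_bimodal_row(self, example_curve_values):
        """Hand-checkable worked example on the 12-point grid."""
        got = extract(SampledCurve(GRID, example_curve_values), "bimodal", uni_max=28.0)
        assert got["GlobalMaximum"] == 28.0
        assert got["GlobalMaximumAngle"] == 300.0
        assert got["GlobalMinimum"] == 4.0
        assert got["GlobalMinimumAngle"] == 210.0
        assert got["Maximum_left"] == 22.0
        assert got["MaximumAngle_left"] == 120.0
        assert got["Maximum_right"] == 28.0
        assert got["MaximumAngle_right"] == 300.0
        assert got["PeakToPeak_right"] == 24.0
        # inner arc (120, 300): min over {14, 8, 4, 10, 21} is 4 at 210
        assert got["InnerMinimum"] == 4.0
        assert got["InnerMinimumAngle"] == 210.0
        assert got["InnerWidth_left"] == 90.0
        assert got["InnerWidth_right"] == 90.0
        assert got["DeltaInnerWidth"] == 0.0
        # outer arc (300..360, 0..120): min over {12, 5, 6, 9} is 5 at 0
        assert got["OuterMinimumAngle"] == 0.0
        assert got["OuterWidth_left"] == 120.0
        assert got["OuterWidth_right"] == 60.0
        assert got["normalizedPeakToPeak_right"] == pytest.approx(24.0 / 28.0)
        # the full row against the exhaustive-scan oracle
        assert_rows_match(got, feature_scan(GRID, example_curve_values, "bimodal", 28.0))

    def test_direct_unimodal_row(self, example_curve_values):
        got = extract(SampledCurve(GRID, example_curve_values), "unimodal")
        assert got["Maximum_right"] == 28.0
        assert got["MaximumAngle_right"] == 300.0
        assert math.isnan(got["Maximum_left"])
        assert math.isnan(got["InnerMinimum"])
        assert math.isnan(got["DeltaSkewness"])
        assert not math.isnan(got["CircularVariance"])
        assert_rows_match(got, feature_scan(GRID, example_curve_values, "unimodal"))


class TestOracleAgreement:
    @pytest.mark.parametrize("modality", ["unimodal", "bimodal"])
    def test_random_curves_match_exhaustive_scan(self, modality):
        rng = np.random.default_rng(321)
        for _ in range(300):
            vals = rng.uniform(0.0, 40.0, 12)
            got = extract(SampledCurve(GRID, vals), modality, uni_max=40.0)
            expected = feature_scan(GRID, vals, modality, 40.0)
            assert_rows_match(got, expected)

    def test_fine_grid_matches_scan(self):
        p = [12.0, 35.0, 115.0, 18.0, 30.0, 245.0, 6.0]
        thetas = np.arange(0.0, 360.0, 5.0)
        vals = models.evaluate_bimodal("wG", p, thetas)
        got = extract(SampledCurve(thetas, vals, source="fitted"), "bimodal")
        assert_rows_match(got, feature_scan(thetas, vals, "bimodal"))


class TestDegenerateAndSymmetry:
    def test_constant_curve(self):
        got = extract(SampledCurve(GRID, np.full(12, 7.0)), "bimodal")
        assert got["PeakToPeak_left"] == 0.0
        assert got["PeakToPeak_right"] == 0.0
        # every sample survives the walk: full support at grid resolution
        assert got["Bandwidth50_right"] == 330.0
        assert math.isnan(got["Skewness_right"])

    def test_symmetric_bimodal_zeros(self):
        p = [10.0, 30.0, 120.0, 10.0, 30.0, 240.0, 4.0]
        vals = models.evaluate_bimodal("wG", p, GRID)
        got = extract(SampledCurve(GRID, vals), "bimodal")
        assert got["MaximumAngle_left"] == 120.0
        assert got["MaximumAngle_right"] == 240.0
        assert got["InnerMinimumAngle"] == 180.0
        assert got["DeltaInnerWidth"] == 0.0
        assert got["DeltaSkewness"] == pytest.approx(0.0, abs=1e-9)

    def test_additive_shift_moves_rates_not_angles(self, example_curve_values):
        base = extract(SampledCurve(GRID, example_curve_values), "bimodal")
        shifted = extract(SampledCurve(GRID, example_curve_values + 5.0), "bimodal")
        for name in ["GlobalMinimum", "GlobalMaximum", "Maximum_left", "Maximum_right",
                     "InnerMinimum"]:
            assert shifted[name] == pytest.approx(base[name] + 5.0)
        for name in ["PeakToPeak_left", "PeakToPeak_right", "MaximumAngle_left",
                     "MaximumAngle_right", "InnerMinimumAngle", "DeltaInnerWidth",
                     "Bandwidth50_right", "Skewness_right"]:
            assert shifted[name] == pytest.approx(base[name])

    def test_mirror_symmetry_swaps_left_right(self):
        rng = np.random.default_rng(99)
        vals = rng.uniform(2.0, 30.0, 12)
        vals[4] += 25.0   # left peak at 120
        vals[8] += 22.0   # right peak at 240
        reflected = np.empty(12)
        for i, t in enumerate(GRID):
            reflected[i] = vals[int(((360.0 - t) % 360.0) / 30.0)]
        a = extract(SampledCurve(GRID, vals), "bimodal")
        b = extract(SampledCurve(GRID, reflected), "bimodal")
        assert b["Maximum_left"] == a["Maximum_right"]
        assert b["Maximum_right"] == a["Maximum_left"]
        assert b["MaximumAngle_left"] == (360.0 - a["MaximumAngle_right"]) % 360.0
        assert b["InnerWidth_left"] == a["InnerWidth_right"]
        assert b["DeltaInnerWidth"] == -a["DeltaInnerWidth"]
        assert b["DeltaOuterWidth"] == -a["DeltaOuterWidth"]
        assert b["Skewness_right"] == pytest.approx(a["minusSkewness_left"])
        assert b["DeltaSkewness"] == pytest.approx(-a["DeltaSkewness"])

    def test_direct_angle_features_quantized_to_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            got = extract(SampledCurve(GRID, rng.uniform(0, 30, 12)), "bimodal")
            for name in ["MaximumAngle_left", "MaximumAngle_right", "InnerMinimumAngle",
                         "InnerWidth_left", "DeltaInnerWidth", "Bandwidth50_right"]:
                assert got[name] % 30.0 == 0.0


class TestSampleFit:
    def _wg_fit(self, c=250.0):
        y = models.evaluate("wG", [20.0, 40.0, c, 5.0], GRID)
        return fitting.fit(make_curve(y), FitConfig(family="wG"))

    def test_grid_resolution_reproduces_fitted_values(self):
        res = self._wg_fit()
        sc = sample_fit(res, resolution=30.0)
        np.testing.assert_allclose(sc.values, res.fitted, atol=1e-8)

    def test_one_degree_gives_360_samples(self):
        assert len(sample_fit(self._wg_fit(), 1.0).thetas) == 360

    def test_fine_max_near_parameter_c(self):
        res = self._wg_fit(c=247.0)
        sc = sample_fit(res, 1.0)
        assert abs(sc.thetas[np.argmax(sc.values)] - 247.0) <= 0.5

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            sample_fit(self._wg_fit(), 7.0)

    def test_nonconverged_rejected(self):
        res = self._wg_fit()
        res.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            sample_fit(res)


class TestZScore:
    def test_identical_populations_zero(self):
        vals = {"PeakToPeak_right": np.array([10.0, 12.0, 14.0])}
        z = zscore_agreement(vals, vals)
        assert z["PeakToPeak_right"] == 0.0

    def test_hand_arithmetic(self):
        model = {"f": np.array([12.0, 12.0, 12.0])}
        direct = {"f": np.array([6.0, 10.0, 14.0])}  # mean 10, sd 4
        assert zscore_agreement(model, direct)["f"] == pytest.approx(0.5)

    def test_zero_spread_gives_nan(self):
        z = zscore_agreement({"f": np.array([1.0, 2.0])}, {"f": np.array([3.0, 3.0])})
        assert math.isnan(z["f"])
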