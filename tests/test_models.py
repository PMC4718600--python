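import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tunefree import models

from _oracles import wrapped_bell_sum, wrapped_gaussian_sum

GRID = np.arange(0, 360, 30.0)

UNIMODAL_PARAMS = {
    "wG": [10.0, 30.0, 240.0, 5.0],
    "wC": [10.0, 1.0, 240.0, 5.0],
    "vM": [10.0, 2.3, 240.0, 5.0],
    "sbeta": [10.0, 10.74, 240.0, 5.0],
    "wB": [10.0, 40.0, 240.0, 5.0, 1.5],
    "F2": [5.0, 1.0, -0.5, 0.25, 2.0],
    "F3": [5.0, 1.0, -0.5, 0.25, 2.0, -1.0, 0.1],
    "F4": [5.0, 1.0, -0.5, 0.25, 2.0, -1.0, 0.1, 0.3, -0.2],
}


class TestArity:
    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown model family"):
            models.evaluate("gauss", [1, 2, 3, 4], GRID)

    @pytest.mark.parametrize("name", models.FAMILY_NAMES)
    def test_wrong_parameter_count(self, name):
        with pytest.raises(ValueError, match="parameters"):
            models.evaluate(name, [1.0, 2.0], GRID)

    def test_param_counts(self):
        assert models.n_params("wG") == 4
        assert models.n_params("wB") == 5
        assert models.n_params("wG", "bimodal") == 7
        assert models.n_params("wB", "bimodal") == 9
        assert [models.n_params(f) for f in ("F2", "F3", "F4")] == [5, 7, 9]
        assert models.n_params("F3", "bimodal") == 7  # shared functional form


class TestUnimodalShapes:
    @pytest.mark.parametrize("name", models.NONLINEAR_FAMILIES)
    def test_zero_amplitude_gives_constant_baseline(self, name):
        p = list(UNIMODAL_PARAMS[name])
        p[0] = 0.0
        vals = models.evaluate(name, p, GRID)
        np.testing.assert_allclose(vals, p[3], atol=1e-12)

    def test_von_mises_peak_value(self):
        # at theta = c the numerator equals the denominator: value a + d
        assert models.evaluate("vM", [7.0, 3.1, 123.0, 2.0], [123.0])[0] == pytest.approx(9.0)

    def test_symmetric_beta_peak_value(self):
        # x = 0.5 at theta = c, so 4x(1-x) = 1 and the value is a + d
        assert models.evaluate("sbeta", [7.0, 8.0, 77.0, 2.0], [77.0])[0] == pytest.approx(9.0)

    def test_wrapped_gaussian_matches_term_by_term_sum(self):
        thetas = np.arange(0.0, 360.0, 7.5)
        vals = models.evaluate("wG", [10.0, 30.0, 240.0, 5.0], thetas)
        expected = [wrapped_gaussian_sum(t, 10.0, 30.0, 240.0, 5.0) for t in thetas]
        np.testing.assert_allclose(vals, expected, rtol=1e-12)
        # the worked peak value: d + a * sum of the 9 wrap terms at theta = c
        peak = models.evaluate("wG", [10.0, 30.0, 240.0, 5.0], [240.0])[0]
        assert peak == pytest.approx(5.0 + 10.0 * sum(
            np.exp(-0.5 * (360.0 * i / 30.0) ** 2) for i in range(-4, 5)))

    def test_wrapped_bell_matches_term_by_term_sum(self):
        thetas = np.arange(0.0, 360.0, 15.0)
        vals = models.evaluate("wB", [10.0, 40.0, 240.0, 5.0, 1.5], thetas)
        expected = [wrapped_bell_sum(t, 10.0, 40.0, 240.0, 5.0, 1.5) for t in thetas]
        np.testing.assert_allclose(vals, expected, rtol=1e-12)

    def test_wrapped_bell_peak_and_antipode(self):
        # normalization puts the peak at a + d and the antipode at d
        vals = models.evaluate("wB", [10.0, 40.0, 240.0, 5.0, 1.5], [240.0, 60.0])
        np.testing.assert_allclose(vals, [15.0, 5.0], atol=1e-12)

    def test_wrap_truncation_converged_gaussian(self):
        # N = 4 image terms suffice for Gaussian widths up to 120 degrees
        p = [10.0, 120.0, 240.0, 5.0]
        v4 = models.evaluate("wG", p, GRID)
        v8 = [wrapped_gaussian_sum(t, *p, n_wrap=8) for t in GRID]
        np.testing.assert_allclose(v4, v8, atol=1e-9)

    def test_wrap_truncation_bell_power_law_tails(self):
        # the bell's power-law tails converge much more slowly; the N = 4
        # truncation is the model definition, but doubling N must stay small
        p = [10.0, 120.0, 240.0, 5.0, 1.5]
        v4 = models.evaluate("wB", p, GRID)
        v8 = [wrapped_bell_sum(t, *p, n_wrap=8) for t in GRID]
        np.testing.assert_allclose(v4, v8, atol=5e-3)


class TestBimodal:
    def test_zero_second_amplitude_reduces_to_unimodal(self):
        p_bi = [10.0, 30.0, 120.0, 0.0, 30.0, 240.0, 6.0]
        bi = models.evaluate_bimodal("wG", p_bi, GRID)
        uni = models.evaluate("wG", [10.0, 30.0, 120.0, 6.0], GRID)
        np.testing.assert_allclose(bi, uni, atol=1e-12)

    def test_midpoint_value_by_direct_summation(self):
        p = [10.0, 30.0, 120.0, 10.0, 30.0, 240.0, 4.0]
        val = models.evaluate_bimodal("wG", p, [180.0])[0]
        expected = (wrapped_gaussian_sum(180.0, 10.0, 30.0, 120.0, 2.0)
                    + wrapped_gaussian_sum(180.0, 10.0, 30.0, 240.0, 2.0))
        assert val == pytest.approx(expected, rel=1e-12)

    def test_mirror_symmetric_params_give_symmetric_curve(self):
        p = [8.0, 25.0, 120.0, 8.0, 25.0, 240.0, 3.0]
        thetas = np.arange(0.0, 360.0, 5.0)
        vals = models.evaluate_bimodal("wC", p, thetas)
        reflected = models.evaluate_bimodal("wC", p, 360.0 - thetas)
        np.testing.assert_allclose(vals, reflected, rtol=1e-10)

    def test_fourier_rejected(self):
        with pytest.raises(ValueError, match="functional form"):
            models.evaluate_bimodal("F3", UNIMODAL_PARAMS["F3"], GRID)

    def test_wb_bimodal_component_exponents(self):
        p = [10.0, 40.0, 120.0, 5.0, 20.0, 240.0, 4.0, 1.0, 3.0]
        val = models.evaluate_bimodal("wB", p, [90.0])[0]
        expected = (wrapped_bell_sum(90.0, 10.0, 40.0, 120.0, 2.0, 1.0)
                    + wrapped_bell_sum(90.0, 5.0, 20.0, 240.0, 2.0, 3.0))
        assert val == pytest.approx(expected, rel=1e-12)


class TestFourier:
    def test_design_row_at_zero(self):
        np.testing.assert_allclose(models.fourier_design_row(3, 0.0),
                                   [1, 1, 0, 1, 0, 1, 0], atol=1e-12)

    def test_design_row_at_ninety(self):
        np.testing.assert_allclose(models.fourier_design_row(2, 90.0),
                                   [1, 0, 1, -1, 0], atol=1e-12)

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_row_length(self, order):
        assert len(models.fourier_design_row(order, 17.0)) == 2 * order + 1

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_grid_evaluation_equals_design_times_coefficients(self, order):
        p = UNIMODAL_PARAMS[f"F{order}"]
        direct = models.evaluate(f"F{order}", p, GRID)
        via_matrix = models.fourier_design_matrix(GRID, order) @ np.asarray(p)
        np.testing.assert_allclose(direct, via_matrix, rtol=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError, match="order"):
            models.fourier_design_row(5, 0.0)


@settings(deadline=None, max_examples=60)
@given(
    name=st.sampled_from(models.FAMILY_NAMES),
    theta=st.floats(min_value=-720.0, max_value=720.0, allow_nan=False),
)
def test_periodicity(name, theta):
    """Every model family is 360-degree periodic."""
    p = UNIMODAL_PARAMS[name]
    a = models.evaluate(name, p, [theta])[0]
    b = models.evaluate(name, p, [theta + 360.0])[0]
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)
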