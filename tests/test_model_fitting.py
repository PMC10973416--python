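import dataclasses
import math

import numpy as np
import pytest

from n2oph import model_fitting as mf

# published hump-shaped quadratics (curvature, slope, intercept) -> peak pH
PUBLISHED_QUADRATICS = [
    ((-0.0913, 1.030, -1.826), 5.6),  # coarse EF vs pH
    ((-0.1000, 1.198, -2.537), 6.0),  # bin-averaged EF vs pH
    ((-0.072, 0.871, -2.204), 6.0),   # field (nirK+nirS)/nosZI vs pH
    ((-0.357, 4.273, -9.560), 6.0),   # field N2O flux vs pH
    ((-0.0334, 0.446, -1.304), 6.7),  # potential denitrification vs pH
    ((-0.129, 1.546, 2.782), 6.0),    # log nirK, coarse
    ((-0.276, 3.481, -1.956), 6.3),   # log nirK, averaged
    ((-0.114, 1.429, 2.833), 6.3),    # log nirS, coarse
    ((-0.281, 3.816, -4.026), 6.8),   # log nirS, averaged
    ((-0.115, 1.398, -3.442), 6.1),   # log ratio, coarse
    ((-0.220, 2.627, -5.838), 6.0),   # log ratio, averaged
]


def normal_equations_polyfit(x, y, degree, weights=None):
    """Independent oracle: accumulate the moment sums and solve X'WX b = X'Wy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    p = degree + 1
    A = np.empty((p, p))
    b = np.empty(p)
    for i in range(p):
        b[i] = float(np.sum(w * y * x**i))
        for j in range(p):
            A[i, j] = float(np.sum(w * x ** (i + j)))
    return np.linalg.solve(A, b)


class TestFitPolynomial:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = mf.fit_polynomial(x, 2 * x + 1, degree=1)
        assert fit.c0 == pytest.approx(1.0, abs=1e-10)
        assert fit.c1 == pytest.approx(2.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_exact_quadratic_recovered_to_1e9(self):
        x = np.linspace(3, 9, 25)
        y = -0.1 * x**2 + 1.198 * x - 2.537
        fit = mf.fit_polynomial(x, y, degree=2)
        assert fit.c2 == pytest.approx(-0.1, abs=1e-9)
        assert fit.c1 == pytest.approx(1.198, abs=1e-9)
        assert fit.c0 == pytest.approx(-2.537, abs=1e-9)

    @pytest.mark.parametrize("degree", [1, 2])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_normal_equations_oracle(self, degree, weighted):
        rng = np.random.default_rng(42)
        x = rng.uniform(3, 9, 10)
        y = -0.1 * x**2 + 1.2 * x - 2.5 + rng.normal(0, 0.3, 10)
        w = rng.uniform(0.5, 3.0, 10) if weighted else None
        fit = mf.fit_polynomial(x, y, degree=degree, weights=w)
        expected = normal_equations_polyfit(x, y, degree, w)
        assert np.allclose(fit.coefficients, expected, rtol=1e-8, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 50)
        y = rng.normal(0, 1, 50)
        w = rng.uniform(0.5, 2.0, 50)
        fit = mf.fit_polynomial(x, y, degree=2, weights=w)
        resid = y - fit.predict(x)
        scale = float(np.sum(np.abs(w * y)))
        for col in (np.ones_like(x), x, x**2):
            assert abs(np.sum(w * resid * col)) / scale < 1e-8

    def test_rank_deficient_design_errors(self):
        with pytest.raises(ValueError, match="rank"):
            mf.fit_polynomial([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0], degree=1)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            mf.fit_polynomial([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], degree=2)

    def test_zero_curvature_zero_noise_adj_r2_equal(self):
        x = np.linspace(0, 10, 30)
        y = 0.5 * x + 1.0
        lin = mf.fit_polynomial(x, y, degree=1)
        quad = mf.fit_polynomial(x, y, degree=2)
        assert lin.adj_r2 == pytest.approx(quad.adj_r2) == pytest.approx(1.0)


class TestAicc:
    def test_hand_evaluation(self):
        # n=20, rss=10, k=3 (linear + error variance):
        # 20*ln(0.5) + 6 + 24/16
        expected = 20 * math.log(0.5) + 6 + 24 / 16
        assert mf.aicc(10.0, 20, 2) == pytest.approx(expected, rel=1e-12)

    def test_monotone_penalty_in_k(self):
        assert mf.aicc(10.0, 20, 3) > mf.aicc(10.0, 20, 2)

    def test_halving_rss_lowers_aicc_by_n_ln2(self):
        n = 50
        delta = mf.aicc(8.0, n, 2) - mf.aicc(4.0, n, 2)
        assert delta == pytest.approx(n * math.log(2), rel=1e-12)

    def test_small_sample_correction_vanishes_for_large_n(self):
        n, k = 5000, 4  # quadratic mean model + error variance
        aic = n * math.log(10.0 / n) + 2 * k
        assert abs(mf.aicc(10.0, n, k - 1) - aic) < 0.01

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            mf.aicc(1.0, 4, 2)
        with pytest.raises(ValueError):
            mf.aicc(0.0, 20, 2)


class TestSelectModel:
    def _pair(self, delta):
        x = np.linspace(0, 10, 20)
        lin = mf.fit_polynomial(x, x + np.sin(x), degree=1)
        quad = mf.fit_polynomial(x, x + np.sin(x), degree=2)
        # rebuild with controlled aicc values
        lin = dataclasses.replace(lin, aicc=100.0)
        quad = dataclasses.replace(quad, aicc=100.0 - delta)
        return lin, quad

    def test_large_delta_prefers_quadratic(self):
        lin, quad = self._pair(5.0)
        sel = mf.select_model(lin, quad)
        assert sel.chosen.model_kind == "quadratic" and not sel.tie

    def test_small_delta_prefers_linear_with_tie_flag(self):
        lin, quad = self._pair(1.0)
        sel = mf.select_model(lin, quad)
        assert sel.chosen.model_kind == "linear" and sel.tie

    def test_identical_aicc_prefers_linear(self):
        lin, quad = self._pair(0.0)
        assert mf.select_model(lin, quad).chosen.model_kind == "linear"

    def test_mismatched_n_obs_errors(self):
        x = np.linspace(0, 10, 20)
        lin = mf.fit_polynomial(x, x + np.sin(x), degree=1)
        quad = mf.fit_polynomial(x[:-1], (x + np.sin(x))[:-1], degree=2)
        with pytest.raises(ValueError, match="same data"):
            mf.select_model(lin, quad)


class TestVertex:
    @pytest.mark.parametrize("coeffs,peak", PUBLISHED_QUADRATICS)
    def test_published_fits_reproduce_printed_peaks(self, coeffs, peak):
        c2, c1, c0 = coeffs
        fit = mf.quadratic_fit_result(c2, c1, c0)
        px, py = mf.vertex(fit)
        assert round(px, 1) == pytest.approx(peak)
        assert py == pytest.approx(c0 + c1 * px + c2 * px**2)

    def test_convex_quadratic_has_no_peak(self):
        fit = mf.quadratic_fit_result(0.1, 1.0, 0.0)
        assert mf.vertex(fit) is None

    def test_linear_fit_errors(self):
        x = np.linspace(0, 10, 10)
        lin = mf.fit_polynomial(x, 2 * x, degree=1)
        with pytest.raises(ValueError):
            mf.vertex(lin)

    def test_out_of_range_peak_flagged(self):
        x = np.linspace(0, 1, 10)
        y = -0.1 * x**2 + 10 * x  # vertex at x=50, far right of data
        fit = mf.fit_polynomial(x, y, degree=2)
        assert fit.peak_in_range is False


class TestConfidenceBand:
    def test_zero_rss_band_collapses_to_line(self):
        x = np.linspace(0, 10, 12)
        fit = mf.fit_polynomial(x, 3 * x + 2, degree=1)
        lo, hi = mf.confidence_band(fit, x)
        assert np.allclose(lo, fit.predict(x), atol=1e-10)
        assert np.allclose(hi, fit.predict(x), atol=1e-10)

    def test_band_narrowest_at_mean_of_symmetric_x(self):
        rng = np.random.default_rng(2)
        x = np.linspace(-5, 5, 41)
        y = x + rng.normal(0, 1, x.size)
        fit = mf.fit_polynomial(x, y, degree=1)
        grid = np.linspace(-5, 5, 101)
        lo, hi = mf.confidence_band(fit, grid)
        widths = hi - lo
        assert np.argmin(widths) == 50  # grid midpoint = mean of x

    def test_bad_level_errors(self):
        x = np.linspace(0, 10, 12)
        fit = mf.fit_polynomial(x, 3 * x + 2, degree=1)
        with pytest.raises(ValueError):
            mf.confidence_band(fit, x, level=1.5)

    def test_monte_carlo_coverage_near_nominal(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 25)
        truth = 1.0 + 0.5 * x
        x0 = np.array([4.0])
        hits = 0
        reps = 500
        for _ in range(reps):
            y = truth + rng.normal(0, 1.0, x.size)
            fit = mf.fit_polynomial(x, y, degree=1)
            lo, hi = mf.confidence_band(fit, x0)
            hits += lo[0] <= 1.0 + 0.5 * x0[0] <= hi[0]
        assert abs(hits / reps - 0.95) < 0.03
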