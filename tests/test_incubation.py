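import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from n2oph import incubation as inc
from n2oph import synthetic
from n2oph.model_fitting import fit_polynomial
from n2oph.study_io import IncubationSeries


def flux_dimensional_oracle(delta_c, volume_l, temp_c, soil_kg, hours,
                            rho=1.964, n_fraction=28.0 / 44.0):
    """Step-by-step unit-conversion oracle, kept independent of the module.

    ppm -> volume fraction -> N2O volume in the bottle -> volume at standard
    state (ideal gas) -> N2O mass via the standard-state density -> N mass ->
    micrograms, normalized per kg dry soil and hour.
    """
    frac = delta_c * 1e-6                    # volume fraction of headspace
    v_n2o_m3 = frac * volume_l * 1e-3        # m^3 of N2O at incubation T
    v_std_m3 = v_n2o_m3 * 273.0 / (273.0 + temp_c)   # m^3 at 0 degC
    mass_n2o_kg = v_std_m3 * rho
    mass_n_kg = mass_n2o_kg * n_fraction
    mass_n_ug = mass_n_kg * 1e9
    return mass_n_ug / soil_kg / hours


def _series(ppm, times=(2.0, 4.0, 6.0), acetylene=False, mass=0.02, vol=0.125, temp=20.0):
    return IncubationSeries(
        sample_id="b", soil_dry_mass=mass, bottle_volume=vol,
        temperature_c=temp, acetylene=acetylene,
        timepoints=list(times), headspace_ppm=list(ppm),
    )


class TestFluxEquation:
    def test_matches_dimensional_oracle(self):
        got = inc.flux_eq(delta_c=1.0, volume=0.125, temperature_c=20.0,
                          soil_mass=0.020, interval_h=6.0)
        want = flux_dimensional_oracle(1.0, 0.125, 20.0, 0.020, 6.0)
        assert got == pytest.approx(want, rel=1e-9)

    @given(
        dc=st.floats(0.01, 100), v=st.floats(0.05, 1.0), t=st.floats(0, 40),
        w=st.floats(0.001, 0.5), h=st.floats(0.5, 24),
    )
    def test_oracle_equivalence_over_parameter_space(self, dc, v, t, w, h):
        assert inc.flux_eq(dc, v, t, w, h) == pytest.approx(
            flux_dimensional_oracle(dc, v, t, w, h), rel=1e-9
        )

    def test_zero_delta_c_zero_rate(self):
        assert inc.flux_eq(0.0, 0.125, 20.0, 0.02, 6.0) == 0.0

    def test_linear_in_delta_c_and_inverse_in_mass(self):
        base = inc.flux_eq(1.0, 0.125, 20.0, 0.02, 6.0)
        assert inc.flux_eq(2.0, 0.125, 20.0, 0.02, 6.0) == pytest.approx(2 * base)
        assert inc.flux_eq(1.0, 0.125, 20.0, 0.04, 6.0) == pytest.approx(base / 2)

    def test_temperature_factor_strictly_decreasing(self):
        rates = [inc.flux_eq(1.0, 0.125, t, 0.02, 6.0) for t in (0, 10, 20, 30)]
        assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_negative_delta_c_gives_negative_rate(self):
        assert inc.flux_eq(-1.0, 0.125, 20.0, 0.02, 6.0) < 0

    def test_nonpositive_interval_errors(self):
        with pytest.raises(ValueError):
            inc.flux_eq(1.0, 0.125, 20.0, 0.02, 0.0)


class TestSlopeRate:
    def test_exact_line_slope(self):
        est = inc.slope_rate(_series([1.0, 2.0, 3.0]))
        # slope 0.5 ppm/h through flux_eq with 1 h interval
        want = inc.flux_eq(0.5, 0.125, 20.0, 0.02, 1.0)
        assert est.rate == pytest.approx(want, rel=1e-12)
        assert est.method == "regression" and est.r2_of_slope == pytest.approx(1.0)

    def test_two_point_series_labelled(self):
        est = inc.slope_rate(_series([1.0, 2.0], times=(0.0, 6.0)))
        assert est.method == "two_point" and est.r2_of_slope is None

    def test_duplicate_timepoints_error(self):
        s = _series([1.0, 2.0, 3.0])
        s.timepoints = [2.0, 2.0, 6.0]
        with pytest.raises(ValueError):
            inc.slope_rate(s)

    def test_noiseless_synthetic_rate_recovered(self, default_config):
        series, truth = synthetic.generate_incubation_pairs(default_config)
        gas = inc.GasParams(
            gas_density=default_config.gas_density,
            n_fraction=default_config.n_fraction,
        )
        for i, s in enumerate(series):
            if not s.acetylene:
                continue
            est = inc.slope_rate(s, gas)
            assert est.rate == pytest.approx(truth["total_rate"][i // 2], rel=1e-9)

    def test_noisy_rate_median_relative_error_below_5pct(self, default_config):
        cfg = dataclasses.replace(default_config, ppm_noise_sd=0.02, n_incubation_samples=100)
        series, truth = synthetic.generate_incubation_pairs(cfg)
        rel_err = []
        for i, s in enumerate(series):
            if not s.acetylene:
                continue
            est = inc.slope_rate(s)
            true_rate = truth["total_rate"][i // 2]
            rel_err.append(abs(est.rate - true_rate) / true_rate)
        assert np.median(rel_err) < 0.05

    @given(c=st.floats(0.1, 10))
    def test_ppm_scaling_scales_rate(self, c):
        base = inc.slope_rate(_series([1.0, 2.0, 3.0])).rate
        scaled = inc.slope_rate(_series([c * 1.0, c * 2.0, c * 3.0])).rate
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestProductRatio:
    def test_half(self):
        pr = inc.product_ratio(5.0, 10.0)
        assert pr.ratio == pytest.approx(0.5) and not pr.clamped

    def test_above_one_clamped_with_flag(self):
        pr = inc.product_ratio(12.0, 10.0)
        assert pr.ratio == 1.0 and pr.clamped
        assert pr.raw_ratio == pytest.approx(1.2)

    def test_negative_net_rate_clamped_to_zero(self):
        pr = inc.product_ratio(-1.0, 10.0)
        assert pr.ratio == 0.0 and pr.clamped

    def test_no_denitrification_signal_errors(self):
        with pytest.raises(ValueError):
            inc.product_ratio(5.0, 0.0)

    def test_zero_noise_ph_series_refits_published_slope(self, default_config):
        """Paired bottles generated from ratio = -0.082 pH + 1.265 refit to that law."""
        series, truth = synthetic.generate_incubation_pairs(default_config)
        ratios = []
        for k in range(0, len(series), 2):
            with_c2h2, without = series[k], series[k + 1]
            r_tot = inc.slope_rate(with_c2h2).rate
            r_net = inc.slope_rate(without).rate
            ratios.append(inc.product_ratio(r_net, r_tot).ratio)
        fit = fit_polynomial(truth["ph"], ratios, degree=1)
        assert fit.c1 == pytest.approx(-0.082, abs=0.005)
        assert fit.c0 == pytest.approx(1.265, abs=0.02)

    def test_noisy_ratio_median_error_below_003(self, default_config):
        cfg = dataclasses.replace(default_config, ppm_noise_sd=0.02, n_incubation_samples=200)
        series, truth = synthetic.generate_incubation_pairs(cfg)
        err = []
        for k in range(0, len(series), 2):
            r_tot = inc.slope_rate(series[k]).rate
            r_net = inc.slope_rate(series[k + 1]).rate
            err.append(abs(inc.product_ratio(r_net, r_tot).ratio - truth["ratio"][k // 2]))
        assert np.median(err) < 0.03


class TestPda:
    def test_known_rate_exactly_recovered_in_mg(self):
        s = _series([1.0, 2.0, 3.0], acetylene=True)
        ug = inc.slope_rate(s).rate
        est = inc.pda(s)
        assert est.unit == "mg N kg-1 h-1"
        assert est.rate == pytest.approx(ug * 1e-3, rel=1e-12)

    def test_non_acetylene_series_rejected(self):
        with pytest.raises(ValueError, match="acetylene"):
            inc.pda(_series([1.0, 2.0, 3.0], acetylene=False))

    def test_unit_round_trip(self):
        s = _series([1.0, 2.0, 3.0], acetylene=True)
        assert inc.pda(s).rate * 1e3 == pytest.approx(inc.slope_rate(s).rate, rel=1e-12)
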