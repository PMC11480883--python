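"""τ_eff estimators: linear, fitted, one-timescale, bounds, exchange."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taueff import (
    FITTED_LINES,
    TABULATED_FIELDS,
    SpectralDensityModel,
    effective_correlation_time,
    feasible_tau_bounds,
    k_constant,
    linear_coefficients,
    make_field,
    relaxation_rates,
    tau_eff_fitted,
    tau_eff_linear,
    tau_eff_one_timescale,
    tau_eff_rex_corrected,
)
from taueff.relaxation_theory import _r2_single_tau

from conftest import random_mixture

# Proportionality constants k (×10⁻⁹ s²) of the linear approximation at
# the commonly used magnetic fields.
K_TABLE = {300: 0.84, 360: 0.81, 400: 0.80, 500: 0.75, 600: 0.69,
           700: 0.64, 720: 0.63, 750: 0.61, 800: 0.59, 850: 0.56,
           900: 0.54, 950: 0.51, 1000: 0.49, 1200: 0.41, 1500: 0.31}


class TestLinearCoefficients:
    @pytest.mark.parametrize("mhz,expected", sorted(K_TABLE.items()))
    def test_k_reproduces_tabulated_values(self, mhz, expected):
        assert k_constant(mhz) * 1e9 == pytest.approx(expected, abs=0.01)

    def test_k_is_inverse_of_coefficient_sum(self):
        for mhz in (300.0, 850.0, 1500.0):
            c = linear_coefficients(make_field(mhz))
            assert c.k * (4 * c.k1 + 4 * c.k2) == pytest.approx(1.0,
                                                                rel=1e-12)
            assert c.k1 > 0 and c.k2 > 0

    def test_frequency_combinations(self):
        f = make_field(700.0)
        c = linear_coefficients(f)
        assert c.a == pytest.approx((f.omega_h - f.omega_n) ** 2)
        assert c.b == pytest.approx(f.omega_n ** 2)
        assert c.c == pytest.approx(f.omega_h ** 2)
        assert c.d == pytest.approx((f.omega_h + f.omega_n) ** 2)

    def test_k_equals_long_tau_slope_of_r2(self):
        """(4K1+4K2) is ∂R₂°/∂τ in the long-τ limit where the
        Lorentzian terms vanish."""
        f = make_field(600.0)
        c = linear_coefficients(f)
        t1, t2 = 4e-7, 8e-7
        slope = (float(_r2_single_tau(t2, f)) - float(_r2_single_tau(t1, f))) \
            / (t2 - t1)
        assert slope == pytest.approx(4 * c.k1 + 4 * c.k2, rel=1e-4)


class TestLinearEstimator:
    def test_examples(self):
        est = tau_eff_linear(10.0, make_field(300.0))
        assert est.tau_eff * 1e9 == pytest.approx(8.4, abs=0.05)
        assert est.upper == est.tau_eff
        assert est.estimator == "linear"
        assert tau_eff_linear(0.0, make_field(600.0)).tau_eff == 0.0
        est15 = tau_eff_linear(10.0, make_field(1500.0))
        assert est15.tau_eff * 1e9 == pytest.approx(3.1, abs=0.05)

    def test_error_propagation(self):
        f = make_field(600.0)
        est = tau_eff_linear(10.0, f, r2_err=0.5)
        assert est.tau_err == pytest.approx(
            linear_coefficients(f).k * 0.5, rel=1e-12)

    def test_negative_r2_rejected(self):
        with pytest.raises(ValueError):
            tau_eff_linear(-1.0, make_field(600.0))


class TestFittedEstimator:
    def test_examples(self):
        assert tau_eff_fitted(10.0, 600.0).tau_eff * 1e9 == pytest.approx(
            0.71 * 10 - 0.64, rel=1e-12)
        assert tau_eff_fitted(10.0, 300.0).tau_eff * 1e9 == pytest.approx(
            0.85 * 10 - 1.52, rel=1e-12)

    def test_non_physical_result_flagged_not_clamped(self):
        est = tau_eff_fitted(0.1, 600.0)
        assert est.flag == "non-physical"
        assert est.tau_eff < 0          # value preserved

    def test_untabulated_field_names_supported_fields(self):
        with pytest.raises(KeyError, match="300"):
            tau_eff_fitted(10.0, 650.0)

    def test_intercepts_negative_slopes_positive(self):
        for line in FITTED_LINES.values():
            assert line.m > 0
            assert line.c < 0


class TestOneTimescale:
    @pytest.mark.parametrize("mhz", TABULATED_FIELDS)
    def test_forward_inverse_round_trip(self, mhz):
        field = make_field(mhz)
        for tau in np.logspace(math.log10(1e-11), math.log10(5e-7), 9):
            r2 = relaxation_rates(SpectralDensityModel.single(tau),
                                  field).r2
            est = tau_eff_one_timescale(r2, field)
            assert est.tau_eff == pytest.approx(tau, rel=1e-6)

    def test_never_exceeds_linear_estimate(self, field600):
        for r2 in (0.5, 2.0, 10.0, 50.0, 200.0):
            one = tau_eff_one_timescale(r2, field600).tau_eff
            lin = tau_eff_linear(r2, field600).tau_eff
            assert one <= lin * (1 + 1e-12)

    def test_approaches_linear_for_slow_dynamics(self, field600):
        r2 = relaxation_rates(SpectralDensityModel.single(50e-9),
                              field600).r2
        one = tau_eff_one_timescale(r2, field600).tau_eff
        lin = tau_eff_linear(r2, field600).tau_eff
        assert abs(one - lin) / lin < 0.02

    def test_material_deviation_for_fast_dynamics(self, field600):
        """Below ~3 ns the Lorentzian terms matter: the two estimators
        must disagree by more than 5%."""
        r2 = relaxation_rates(SpectralDensityModel.single(3e-9),
                              field600).r2
        one = tau_eff_one_timescale(r2, field600).tau_eff
        lin = tau_eff_linear(r2, field600).tau_eff
        assert (lin - one) / one > 0.05

    def test_out_of_range_reports_achievable_interval(self, field600):
        with pytest.raises(ValueError, match="achievable range"):
            tau_eff_one_timescale(1e9, field600)

    def test_field_invariance_of_exchange_free_estimates(self):
        """Exchange-free single-timescale data give the same τ_eff
        when inverted from R₂ at 500 vs 850 MHz."""
        tau = 7e-9
        ests = []
        for mhz in (500.0, 850.0):
            f = make_field(mhz)
            r2 = relaxation_rates(SpectralDensityModel.single(tau), f).r2
            ests.append(tau_eff_one_timescale(r2, f).tau_eff)
        assert ests[0] == pytest.approx(ests[1], rel=1e-6)

    def test_monotone_in_r2(self, field600):
        grid = np.linspace(0.5, 100.0, 40)
        taus = [tau_eff_one_timescale(r2, field600).tau_eff for r2 in grid]
        assert np.all(np.diff(taus) > 0)


class TestFeasibleBounds:
    def test_brackets_one_timescale_estimate(self, field600):
        # 1e-4 slack covers the hull's grid discretization (~1e-5)
        for r2 in (1.0, 5.0, 20.0, 100.0):
            lower, upper = feasible_tau_bounds(r2, field600)
            one = tau_eff_one_timescale(r2, field600).tau_eff
            lin = tau_eff_linear(r2, field600).tau_eff
            assert lower <= one * (1 + 1e-4)
            assert one <= upper * (1 + 1e-9)
            assert upper == pytest.approx(lin, rel=1e-12)

    def test_monte_carlo_mixture_containment(self, field600):
        """1000 random 5-component mixtures: every (R₂°, τ_eff) pair
        falls inside the numerically solved feasible band."""
        rng = np.random.default_rng(20240602)
        for _ in range(1000):
            model = random_mixture(rng, max_components=5)
            tau = effective_correlation_time(model)
            r2 = relaxation_rates(model, field600).r2
            lower, upper = feasible_tau_bounds(r2, field600)
            assert lower * (1 - 1e-4) <= tau <= upper * (1 + 1e-9)

    def test_out_of_range_rejected(self, field600):
        with pytest.raises(ValueError):
            feasible_tau_bounds(1e9, field600)


class TestRexCorrected:
    @staticmethod
    def synthetic_records(tau, rex500, fields_mhz, rng=None, noise=0.0):
        f500 = make_field(500.0)
        phi = rex500 / f500.omega_n ** 2
        records = []
        for mhz in fields_mhz:
            f = make_field(mhz)
            r2 = float(_r2_single_tau(tau, f)) + phi * f.omega_n ** 2
            if noise:
                r2 *= 1.0 + noise * rng.standard_normal()
            records.append((r2, f))
        return records

    def test_noiseless_recovery(self):
        records = self.synthetic_records(5e-9, 2.0, (500, 600, 700))
        est = tau_eff_rex_corrected(records)
        assert est.tau_eff == pytest.approx(5e-9, rel=1e-4)
        assert est.rex_by_field[500.0] == pytest.approx(2.0, rel=1e-4)
        assert est.flag is None
        assert est.phi >= 0

    def test_zero_exchange_matches_single_field_inversion(self):
        records = self.synthetic_records(5e-9, 0.0, (500, 700))
        est = tau_eff_rex_corrected(records)
        single = tau_eff_one_timescale(records[0][0], make_field(500.0))
        assert est.tau_eff == pytest.approx(single.tau_eff, rel=1e-6)

    def test_negative_apparent_exchange_pinned_and_flagged(self):
        # R2 decreasing with field cannot be fit with Φ ≥ 0
        records = [(10.0, make_field(500.0)), (8.0, make_field(800.0))]
        est = tau_eff_rex_corrected(records)
        assert est.flag == "phi-pinned-to-zero"
        assert est.phi == 0.0

    def test_single_field_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            tau_eff_rex_corrected([(10.0, make_field(600.0)),
                                   (10.2, make_field(600.2))])

    def test_recovery_under_noise(self):
        """2% Gaussian noise on R₂, 200 replicates: median relative
        τ error below 5%.

        Uses the four-field 400–700 MHz experimental setting; the
        wider field range separates the τ-driven and ωN²-scaled parts
        of R₂ much better than adjacent high fields alone.
        """
        rng = np.random.default_rng(20240603)
        errors = []
        for _ in range(200):
            records = self.synthetic_records(5e-9, 2.0,
                                             (400, 500, 600, 700),
                                             rng=rng, noise=0.02)
            est = tau_eff_rex_corrected(records)
            errors.append(abs(est.tau_eff - 5e-9) / 5e-9)
        assert float(np.median(errors)) < 0.05


class TestUpperBoundProperty:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_tau_eff_never_exceeds_k_r2(self, seed):
        """τ_eff ≤ k·R₂° for any timescale mixture — the Lorentzian
        terms of the R₂° decomposition are non-negative."""
        rng = np.random.default_rng(seed)
        model = random_mixture(rng)
        field = make_field(float(rng.uniform(300, 1500)))
        tau = effective_correlation_time(model)
        r2 = relaxation_rates(model, field).r2
        assert tau <= linear_coefficients(field).k * r2
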