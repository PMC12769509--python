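"""Rate parameterization families, interpolation, and priors."""

import numpy as np
import pytest

from strdyn.rates import (
    FAMILIES,
    ParamGrid,
    ParamSpec,
    RateCurve,
    build_rate_table,
    default_empirical_curve,
    default_grid,
    default_substitution_rates,
    fit_informative_prior,
    fitted_loglog_params,
    interpolate_rates,
    uniform_prior,
)


@pytest.fixture(scope="module")
def emp():
    return default_empirical_curve()


class TestFamilies:
    def test_multiplier_jump(self):
        """epsilon(9) = m * epsilon(8): the multiplier is a discrete jump
        immediately above the empirical range."""
        L = np.arange(9, dtype=float)
        emp = RateCurve(np.r_[0, np.full(8, 1e-8)], np.r_[0, np.full(8, 5e-9)],
                        np.r_[0, np.full(8, 1e-10)])
        spec = ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0))
        curve = build_rate_table(spec, emp, 20)
        assert curve.eps[9] == pytest.approx(4e-8)
        assert curve.kap[9] == pytest.approx(2e-8)

    def test_symmetric_equal_rates_above_8(self, emp):
        spec = ParamSpec("symmetric_power", (3e-8, 1.5))
        curve = build_rate_table(spec, emp, 50)
        assert np.allclose(curve.eps[9:], curve.kap[9:])
        assert curve.eps[9] == pytest.approx(3e-8)
        assert curve.eps[18] == pytest.approx(3e-8 * 2**1.5)

    def test_pure_power_anchored_at_substitution_rate(self):
        subst = default_substitution_rates()
        spec = ParamSpec("pure_power", (9.0, 13.0, 3.6, 4.0))
        curve = build_rate_table(spec, None, 30, subst)
        assert curve.eps[9] == pytest.approx(subst.mu)
        assert curve.kap[13] == pytest.approx(subst.nu)
        assert np.allclose(curve.iot[1:], curve.eps[1:] / 100)

    def test_iota_is_one_percent_of_epsilon_where_parameterized(self, emp):
        spec = ParamSpec("decoupled_power", (3e-8, 2e-8, 1.5, 2.0))
        curve = build_rate_table(spec, emp, 40)
        assert np.allclose(curve.iot[9:], curve.eps[9:] / 100)
        # below 9 the empirical values are kept
        assert np.allclose(curve.iot[1:9], emp.iot[1:9])

    def test_nesting_decoupled_reduces_to_symmetric(self, emp):
        sym = build_rate_table(ParamSpec("symmetric_power", (2e-8, 1.7)), emp, 60)
        dec = build_rate_table(
            ParamSpec("decoupled_power", (2e-8, 2e-8, 1.7, 1.7)), emp, 60
        )
        assert np.array_equal(sym.eps, dec.eps)
        assert np.array_equal(sym.kap, dec.kap)

    def test_log_family_anchor(self, emp):
        # log(9-7)/log 2 = 1, so c parameterizes the L = 9 value here too
        spec = ParamSpec("symmetric_log", (5e-8, 1.3))
        curve = build_rate_table(spec, emp, 30)
        assert curve.eps[9] == pytest.approx(5e-8)

    def test_delta_tau(self):
        spec = ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0))
        assert spec.delta_tau == pytest.approx(0.4)

    def test_dimensionality_enforced(self):
        for fam, names in FAMILIES.items():
            with pytest.raises(ValueError):
                ParamSpec(fam, tuple([1.0] * (len(names) + 1)))

    def test_rates_nonnegative_finite_across_grid(self, emp):
        grid = ParamGrid(
            "multiplier_coupled_power",
            {"m": np.array([1.0, 10.0]), "tau_eps": np.array([0.0, 4.0]),
             "tau_kap": np.array([0.0, 4.0])},
        )
        for spec in grid.points():
            c = build_rate_table(spec, emp, 200)
            for arr in (c.eps, c.kap, c.iot):
                assert np.all(arr[1:] >= 0) and np.all(np.isfinite(arr[1:]))

    def test_empirical_required(self):
        with pytest.raises(ValueError):
            build_rate_table(ParamSpec("symmetric_power", (1e-8, 1.0)), None, 20)


class TestInterpolation:
    def test_no_jump_curve_unchanged(self, emp):
        # m = 1: epsilon(9)/epsilon(8) = 1, the log-linear bridge passes
        # through the original points
        spec = ParamSpec("multiplier_coupled_power", (1.0, 1.0, 1.0))
        curve = build_rate_table(spec, emp, 30)
        sm = interpolate_rates(curve, (8, 10))
        assert np.allclose(sm.eps, curve.eps, rtol=1e-12)

    def test_monotone_across_window(self, emp):
        spec = ParamSpec("multiplier_coupled_power", (10.0, 1.6, 2.0))
        curve = build_rate_table(spec, emp, 30)
        sm = interpolate_rates(curve, (8, 12))
        assert np.all(np.diff(sm.eps[8:13]) > 0)
        # endpoints preserved
        assert sm.eps[8] == curve.eps[8] and sm.eps[12] == curve.eps[12]

    def test_zero_width_window_identity(self, emp):
        spec = ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0))
        curve = build_rate_table(spec, emp, 30)
        sm = interpolate_rates(curve, (9, 10))
        assert np.array_equal(sm.eps, curve.eps)


class TestPriors:
    def test_uniform_prior_mass(self):
        grid = default_grid("multiplier_coupled_power")
        p = uniform_prior(grid)
        assert len(p) == grid.n
        assert np.isclose(p.sum(), 1.0)
        assert np.allclose(p, 1.0 / grid.n)

    def test_informative_prior_sums_to_one(self, emp):
        lengths = np.arange(11, 30)
        eps = 2.7e-8 * (lengths / 9.0) ** 1.8
        kap = 1.7e-8 * (lengths / 9.0) ** 2.2
        grid = ParamGrid(
            "decoupled_power",
            {
                "c_eps": np.geomspace(1e-8, 1e-7, 6),
                "c_kap": np.geomspace(1e-8, 1e-7, 6),
                "tau_eps": np.arange(1.0, 3.01, 0.25),
                "tau_kap": np.arange(1.0, 3.01, 0.25),
            },
        )
        prior = fit_informative_prior(lengths, eps, kap, grid, inflation=100,
                                      empirical=emp)
        assert np.isclose(prior.sum(), 1.0)
        assert np.all(prior >= 0)

    def test_noiseless_power_law_recovered(self):
        """Fitting rates generated exactly on a power law recovers the
        generating constant and exponent within 1%."""
        lengths = np.arange(11, 30)
        c_true, tau_true = 3.1e-8, 1.9
        rates = c_true * (lengths / 9.0) ** tau_true
        c_fit, tau_fit = fitted_loglog_params(lengths, rates)
        assert abs(c_fit / c_true - 1) < 0.01
        assert abs(tau_fit / tau_true - 1) < 0.01

    def test_restrictive_sharper_than_permissive(self, emp):
        lengths = np.arange(11, 30)
        eps = 2.7e-8 * (lengths / 9.0) ** 1.8
        kap = 1.7e-8 * (lengths / 9.0) ** 2.2
        grid = ParamGrid(
            "decoupled_power",
            {
                "c_eps": np.geomspace(1e-9, 1e-6, 8),
                "c_kap": np.geomspace(1e-9, 1e-6, 8),
                "tau_eps": np.arange(0.5, 3.51, 0.5),
                "tau_kap": np.arange(0.5, 3.51, 0.5),
            },
        )
        restrictive = fit_informative_prior(lengths, eps, kap, grid, 100, emp)
        permissive = fit_informative_prior(lengths, eps, kap, grid, 1000, emp)

        def entropy(p):
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        assert entropy(restrictive) < entropy(permissive)

    def test_too_few_lengths_raises(self, emp):
        grid = default_grid("multiplier_coupled_power")
        with pytest.raises(ValueError):
            fit_informative_prior([11, 12], [1e-8, 1e-8], [1e-8, 1e-8], grid,
                                  empirical=emp)
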