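"""Closed-form relations among f, g and h and the moment identities."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import trapezoid

import interdiv as iv
from interdiv.analytics import (LN2, TAU_AGE_COEF, AgePDF, MomentSummary,
                                lambda_diagnostic)

D = 0.15


def _grid(rate=D, n=20001):
    return np.linspace(0.0, 6 * LN2 / rate, n)


def _consistent_gamma_h(shape=8, rate=D, n=20001):
    """Gamma h whose Laplace transform at rate is exactly 1/2, so that
    g = 2 e^{-rate a} h carries unit mass (a steady-state-consistent pair)."""
    scale = (2 ** (1.0 / shape) - 1.0) / rate
    grid = _grid(rate, n)
    from scipy.stats import gamma
    h = AgePDF(grid, gamma.pdf(grid, a=shape, scale=scale), kind="h", rate=rate)
    return h


class TestFfromG:
    def test_boundary_value_is_twice_the_rate(self):
        g = _exponential_g(rate_g=0.6)
        f = iv.f_from_g(g, D)
        assert f.density[0] == pytest.approx(2 * D)   # 0.3/hr at D = 0.15

    def test_exponential_g_matches_closed_form(self):
        # g = r e^{-ra}: f(a) = 2D e^{-Da} - D e^{-Da} r/(r-D) (1 - e^{-(r-D)a})
        r = 0.6
        g = _exponential_g(rate_g=r)
        f = iv.f_from_g(g, D)
        a = g.grid
        expected = (2 * D * np.exp(-D * a)
                    - D * np.exp(-D * a) * r / (r - D) * (1 - np.exp(-(r - D) * a)))
        assert np.max(np.abs(f.density - expected)) < 1e-8

    def test_dirac_g_gives_truncated_exponential(self):
        grid = _grid(n=40001)
        spec = iv.DistributionSpec("dirac", {"loc": LN2 / D})
        g = AgePDF(grid, spec.pdf_on_grid(grid), kind="g", rate=D)
        f = iv.f_from_g(g, D)
        before = grid < LN2 / D - 0.01
        after = grid > LN2 / D + 0.01
        assert np.allclose(f.density[before], 2 * D * np.exp(-D * grid[before]),
                           rtol=1e-6)
        # the discretized atom leaves O(bin width) residue past the cutoff
        assert np.max(np.abs(f.density[after])) < 2e-5

    def test_inconsistent_pair_flagged_not_raised(self):
        # exponential g with r/(r-D) > 2, i.e. r < 2D: f goes negative
        g = _exponential_g(rate_g=0.25)
        f = iv.f_from_g(g, D)
        assert f.meta["steady_state_consistent"] is False
        assert f.density.min() < 0

    def test_unnormalized_g_rejected(self):
        grid = _grid()
        g = AgePDF(grid, np.full_like(grid, 0.01), kind="g")
        with pytest.raises(ValueError, match="normalized"):
            iv.f_from_g(g, D)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            iv.f_from_g(_exponential_g(0.6), 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shape=st.floats(1.5, 30.0), mean_factor=st.floats(0.5, 1.0))
    def test_normalization_theorem(self, shape, mean_factor):
        """f from any normalized g with int e^{Da} g <= 2 has unit mass.

        On the truncated grid [0, A] the identity reads
        int_0^A f + f(A)/D = 1: beyond the support of g the density decays
        as a pure exponential, whose tail mass is f(A)/D.
        """
        from scipy.stats import gamma
        mean = mean_factor * LN2 / D      # keep the exponential moment <= 2
        grid = _grid()
        dens = gamma.pdf(grid, a=shape, scale=mean / shape)
        g = AgePDF(grid, dens / trapezoid(dens, grid), kind="g", rate=D)
        if trapezoid(np.exp(D * grid) * g.density, grid) > 2:
            return
        f = iv.f_from_g(g, D)
        total = f.integral + f.density[-1] / D
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalization_exact_for_consistent_pair(self):
        """When int e^{Da} g = 2 exactly, the grid integral itself is 1."""
        h = _consistent_gamma_h()
        g = AgePDF(h.grid, 2 * np.exp(-D * h.grid) * h.density, kind="g",
                   rate=D)
        f = iv.f_from_g(g, D)
        assert f.integral == pytest.approx(1.0, abs=1e-6)

    def test_exp_weighted_f_nonincreasing_and_bounded(self):
        g = _exponential_g(0.6)
        f = iv.f_from_g(g, D)
        w = np.exp(D * f.grid) * f.density
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all(f.density <= 2 * D * np.exp(-D * f.grid) + 1e-12)

    def test_lambda_diagnostic_nonnegative(self):
        f = iv.f_from_g(_exponential_g(0.6), D)
        assert lambda_diagnostic(f, D) >= 0


def _exponential_g(rate_g, rate=D, n=20001):
    grid = _grid(rate, n)
    dens = rate_g * np.exp(-rate_g * grid)
    return AgePDF(grid, dens / trapezoid(dens, grid), kind="g", rate=rate)


class TestHtoG:
    def test_powell_integrals_for_consistent_pair(self):
        h = _consistent_gamma_h()
        ehw = np.exp(-D * h.grid) * h.density
        assert trapezoid(ehw, h.grid) == pytest.approx(0.5, abs=1e-6)
        g = iv.g_from_h(h, D)
        tau_obs = g.moment(1)
        assert trapezoid(h.grid * ehw, h.grid) == pytest.approx(tau_obs / 2,
                                                                rel=1e-6)

    def test_round_trip_is_identity(self):
        g = _exponential_g(0.6)
        g2 = iv.g_from_h(iv.h_from_g(g, D), D)
        assert np.max(np.abs(g2.density - g.density)) < 1e-10

    def test_g_h_cross_at_ln2_over_D(self):
        h = _consistent_gamma_h()
        g = iv.g_from_h(h, D)
        a_star = LN2 / D
        before = g.grid < a_star
        after = (g.grid > a_star) & (h.density > 1e-12)
        assert np.all(g.density[before] >= h.density[before])
        assert np.all(g.density[after] <= h.density[after])

    def test_consistency_residual_reported(self):
        h = _consistent_gamma_h()
        g = iv.g_from_h(h, D)
        assert g.meta["consistency_residual"] < 1e-6
        # an arbitrary (inconsistent) h reports a visible residual
        from scipy.stats import gamma
        grid = _grid()
        h_bad = AgePDF(grid, gamma.pdf(grid, a=8, scale=3.0 / 8), kind="h",
                       rate=D)
        g_bad = iv.g_from_h(h_bad, D)
        assert g_bad.meta["consistency_residual"] > 0.01


class TestPowellForm:
    def test_boundary_value(self):
        h = _consistent_gamma_h()
        f = iv.f_from_h_powell(h, D)
        assert f.density[0] == pytest.approx(2 * D)

    def test_equivalent_to_route_via_g(self):
        """f via g = 2 e^{-Da} h equals Powell's direct form to < 1e-8."""
        h = _consistent_gamma_h(shape=8)
        g = AgePDF(h.grid, 2 * np.exp(-D * h.grid) * h.density,
                   kind="g", rate=D)
        f1 = iv.f_from_g(g, D)
        f2 = iv.f_from_h_powell(h, D)
        assert np.max(np.abs(f1.density - f2.density)) < 1e-8

    def test_dirac_h_matches_dirac_g_route(self):
        grid = _grid(n=40001)
        spec = iv.DistributionSpec("dirac", {"loc": LN2 / D})
        dens = spec.pdf_on_grid(grid)
        f_h = iv.f_from_h_powell(AgePDF(grid, dens, kind="h"), D)
        f_g = iv.f_from_g(AgePDF(grid, dens, kind="g"), D)
        assert np.max(np.abs(f_h.density - f_g.density)) < 1e-4


class TestBatchForm:
    def test_boundary_is_twice_nu(self):
        nu = 0.276
        g = _exponential_g(1.0, rate=nu)
        f = iv.batch_f_from_g(g, nu)
        assert f.density[0] == pytest.approx(2 * nu)

    def test_identical_to_chemostat_formula(self):
        nu = 0.276
        g = _exponential_g(1.0, rate=nu)
        f1 = iv.batch_f_from_g(g, nu)
        f2 = iv.f_from_g(g, nu)
        assert np.array_equal(f1.density, f2.density)


class TestMomentChecks:
    def test_tau_bound_reference_value(self):
        chk = iv.check_tau_bound_D(4.314, D)
        assert chk.rhs == pytest.approx(4.620981, rel=1e-6)  # ln2/0.15
        assert chk.passed

    def test_dirac_case_zero_slack(self):
        chk = iv.check_tau_bound_D(LN2 / D, D)
        assert chk.passed and chk.residual == pytest.approx(0.0, abs=1e-12)

    def test_sum_identity_reference_values(self):
        chk = iv.check_sum_identity(2.360, 4.314, D, tolerance=2e-3)
        assert chk.lhs == pytest.approx(6.674)
        assert chk.rhs == pytest.approx(1 / 0.15)
        assert abs(chk.relative_residual) < 1.2e-3 and chk.passed

    def test_sum_identity_batch_reference(self):
        chk = iv.check_sum_identity(1.302, 2.327, 0.276, tolerance=2e-3)
        assert abs(chk.relative_residual) < 2e-3 and chk.passed

    def test_sum_identity_exact_for_dirac(self):
        mean_age = (1 - LN2) / D
        chk = iv.check_sum_identity(mean_age, LN2 / D, D)
        assert chk.residual == pytest.approx(0.0, abs=1e-12)

    def test_age_bound_coefficient_and_reference(self):
        assert TAU_AGE_COEF == pytest.approx(2.2589, abs=5e-5)
        chk = iv.check_tau_bound_age(4.314, 2.360)
        assert chk.rhs == pytest.approx(5.331, abs=5e-4)
        assert chk.passed

    def test_age_bound_zero_slack_for_dirac(self):
        chk = iv.check_tau_bound_age(LN2 / D, (1 - LN2) / D)
        assert chk.residual == pytest.approx(0.0, abs=1e-12)

    def test_second_moment_identity_dirac(self):
        # f = 2D e^{-Da} truncated at ln2/D; <a^2> = (2 - 2ln2 - ln2^2)/D^2
        t0 = LN2 / D
        ms = MomentSummary(
            mean_age=(1 - LN2) / D,
            mean_age_sq=(2 - 2 * LN2 - LN2**2) / D**2,
            tau_obs=t0, tau_sq=t0**2, rate=D)
        chk = iv.check_second_moment_identity(ms, D)
        assert chk.passed and abs(chk.relative_residual) < 1e-12

    def test_second_moment_contradiction_fails(self):
        ms = MomentSummary(mean_age=2.0, mean_age_sq=10.0, tau_obs=1.0,
                           tau_sq=0.0, rate=D)
        chk = iv.check_second_moment_identity(ms, D)
        assert not chk.passed


class TestSynchrony:
    def test_root_of_polynomial_is_infeasible(self):
        x = 1 - math.sqrt(2) / 2
        implied, feasible = iv.synchrony_feasibility(x / D, D)
        assert implied == pytest.approx(0.0, abs=1e-10)
        assert feasible is False
        # the implied tau_obs at the root exceeds the hard bound ln2/D
        tau_implied = 1 / D - x / D
        assert tau_implied > LN2 / D

    def test_reference_point_has_positive_variance(self):
        implied, feasible = iv.synchrony_feasibility(2.360, D)
        assert implied > 0 and feasible is False

    def test_domain_error_beyond_unit_product(self):
        with pytest.raises(ValueError):
            iv.synchrony_feasibility((1 + math.sqrt(2) / 2) / D, D)


class TestAgePDFContainer:
    def test_rejects_mismatched_arrays(self):
        with pytest.raises(ValueError):
            AgePDF(np.arange(5.0), np.arange(4.0))

    def test_rejects_nonincreasing_grid(self):
        with pytest.raises(ValueError):
            AgePDF(np.array([0.0, 1.0, 1.0]), np.zeros(3))

    def test_normalized_and_moment(self):
        grid = np.linspace(0, 10, 1001)
        p = AgePDF(grid, np.exp(-grid)).normalized()
        assert p.is_normalized()
        assert p.moment(1) == pytest.approx(1.0, rel=1e-3)

    def test_report_serialization(self):
        rep = iv.RelationReport([iv.check_tau_bound_D(4.0, D)])
        d = rep.to_dict()
        assert d["passed"] and d["checks"][0]["name"]
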