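"""Tests for the saddle-node normal form and its first-passage theory."""

import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from g1crit.normal_form import (
    AIRY_SWITCH,
    NormalFormParams,
    log_mfpt_exact,
    log_mfpt_kramers,
    mfpt_empirical,
    mfpt_exact,
    mfpt_kramers,
    predict_exit_time,
    reduce_to_normal_form,
    scaling_exponent,
    simulate_normal_form,
)
from g1crit.rb_switch import RbParams, first_passage_ensemble


class TestExactDelay:
    def test_critical_point_value_from_airy_closed_forms(self):
        """At mu=0, xi=1: T = 2^{1/3} pi^2 (Ai(0)^2 + Bi(0)^2).

        Ai(0) = 3^{-2/3}/Gamma(2/3) and Bi(0) = 3^{-1/6}/Gamma(2/3) give an
        oracle independent of the Airy evaluation path.
        """
        g23 = gamma_fn(2.0 / 3.0)
        ai0 = 3.0 ** (-2.0 / 3.0) / g23
        bi0 = 3.0 ** (-1.0 / 6.0) / g23
        expected = 2.0 ** (1.0 / 3.0) * math.pi**2 * (ai0**2 + bi0**2)
        assert mfpt_exact(0.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.27, abs=0.01)

    def test_strictly_decreasing_in_mu(self):
        T = mfpt_exact(np.linspace(-0.5, 0.5, 41), 0.1)
        assert np.all(np.diff(T) < 0)
        assert mfpt_exact(0.5, 0.1) < mfpt_exact(0.0, 0.1) < mfpt_exact(-0.5, 0.1)

    def test_scaling_collapse_single_dimensionless_combination(self):
        """xi^{2/3} T depends on mu xi^{-4/3} only."""
        combos = np.linspace(-3.0, 3.0, 13)
        ref = None
        for xi in (0.05, 0.1, 0.4):
            mu = combos * xi ** (4.0 / 3.0)
            scaled = mfpt_exact(mu, xi) * xi ** (2.0 / 3.0)
            if ref is None:
                ref = scaled
            else:
                np.testing.assert_allclose(scaled, ref, rtol=1e-10)

    def test_log_evaluation_continuous_across_switch_over(self):
        # pick mu so the Airy argument straddles the switch-over at fixed xi
        xi = 0.1
        z_lo, z_hi = AIRY_SWITCH - 1e-7, AIRY_SWITCH + 1e-7
        mu = lambda z: -z / (2.0 ** (2.0 / 3.0) * xi ** (-4.0 / 3.0))
        a, b = log_mfpt_exact(mu(z_lo), xi), log_mfpt_exact(mu(z_hi), xi)
        # the genuine slope d(log T)/dz is ~(4/3) sqrt(z); over a 2e-7 gap
        # any jump beyond 1e-5 would be a code-path discontinuity
        assert abs(a - b) < 1e-5

    def test_deep_subcritical_log_value_is_finite(self):
        val = log_mfpt_exact(-0.6, 0.02)
        assert np.isfinite(val) and val > 100.0

    def test_xi_must_be_positive(self):
        with pytest.raises(ValueError):
            mfpt_exact(0.0, 0.0)
        with pytest.raises(ValueError):
            NormalFormParams(mu=0.0, xi=-0.1)


class TestKramers:
    def test_domain_error_for_supercritical_mu(self):
        with pytest.raises(ValueError):
            mfpt_kramers(0.1, 0.1)

    def test_log_ratio_to_exact_approaches_one_monotonically(self):
        """Kramers/exact agreement improves as the barrier deepens."""
        xi = 0.1
        mus = np.array([-0.1, -0.2, -0.3, -0.4, -0.5])
        ratios = log_mfpt_kramers(mus, xi) / log_mfpt_exact(mus, xi)
        errs = np.abs(ratios - 1.0)
        assert np.all(np.diff(errs) < 0)

    def test_deep_barrier_log_agreement_within_two_percent(self):
        lk = log_mfpt_kramers(-0.5, 0.05)
        le = log_mfpt_exact(-0.5, 0.05)
        assert lk == pytest.approx(le, rel=0.02)

    def test_shallow_barrier_deviation_is_visible(self):
        # recorded, not asserted small: the approximation degrades here
        ratio = mfpt_kramers(-0.1, 0.3) / mfpt_exact(-0.1, 0.3)
        assert not math.isclose(ratio, 1.0, rel_tol=0.05)


class TestScalingExponent:
    def test_reference_grid_recovers_three_halves(self):
        fit = scaling_exponent(0.05, np.linspace(-0.6, -0.2, 20))
        assert fit.regime_ok
        assert fit.exponent == pytest.approx(1.5, abs=0.05)

    def test_smaller_noise_approaches_asymptote(self):
        grid = np.linspace(-0.6, -0.2, 20)
        e1 = scaling_exponent(0.05, grid).exponent
        e2 = scaling_exponent(0.02, grid).exponent
        assert abs(e2 - 1.5) < abs(e1 - 1.5)

    def test_kramers_slope_matches_up_to_prefactor_correction(self):
        grid = np.linspace(-0.6, -0.2, 20)
        y = np.log(log_mfpt_kramers(grid, 0.05))
        slope = np.polyfit(np.log(np.abs(grid)), y, 1)[0]
        assert slope == pytest.approx(1.5, abs=0.02)

    def test_regime_violation_warns(self):
        with pytest.warns(UserWarning):
            fit = scaling_exponent(0.5, np.linspace(-0.3, -0.1, 5))
        assert not fit.regime_ok


def _tail_time(mu: float, b: float) -> float:
    """Deterministic time of dx/dt = x^2 + mu spent outside (-b, b)."""
    if mu > 0:
        s = math.sqrt(mu)
        return 2.0 * (math.pi / 2.0 - math.atan(b / s)) / s
    if mu == 0:
        return 2.0 / b
    s = math.sqrt(-mu)
    return (1.0 / s) * math.log((b + s) / (b - s))


class TestEmpirical:
    def test_deterministic_limit_matches_quadrature(self):
        """Weak noise, mu=1: passage time -> int dx/(x^2+1) between bounds."""
        emp = mfpt_empirical(1.0, 1e-4, n=8, seed=0, dt=1e-3, x0=-3.0, x_absorb=3.0)
        expected = 2.0 * math.atan(3.0)  # = int_{-3}^{3} dx/(x^2+1)
        assert emp.mean == pytest.approx(expected, rel=0.01)

    def test_matches_exact_formula_on_grid(self):
        """Monte-Carlo first passage vs the Airy formula, 3x3 grid, 3 SE.

        The closed form integrates the full line; the simulation runs
        between +-12, so the deterministic tail time spent outside the
        boundaries (closed form below) is subtracted before comparing.
        """
        for i, mu in enumerate((-0.1, 0.0, 0.1)):
            for j, xi in enumerate((0.15, 0.25, 0.35)):
                emp = mfpt_empirical(
                    mu, xi, n=1200, seed=7000 + 3 * i + j, dt=0.002,
                    x0=-12.0, x_absorb=12.0,
                )
                expected = mfpt_exact(mu, xi) - _tail_time(mu, 12.0)
                assert emp.n_censored == 0
                assert abs(emp.mean - expected) < 3.0 * emp.se, (mu, xi)

    def test_censored_paths_are_counted_not_dropped(self):
        emp = mfpt_empirical(-0.3, 0.12, n=50, seed=3, dt=0.01, t_cap=5.0)
        assert emp.n_censored > 0
        assert emp.n_censored + emp.exit_times.size == 50

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            mfpt_empirical(0.0, 0.1, x0=2.0, x_absorb=1.0)


class TestTimeDependentMu:
    def test_zero_noise_constant_mu_paths_identical(self):
        et, cen = simulate_normal_form(0.5, 0.0, dt=0.01, t_max=50.0, n=16, seed=0)
        assert not cen.any()
        assert np.all(et == et[0])

    def test_fast_ramp_clusters_exit_times(self):
        """Strong time-dependence of mu suppresses exit-time dispersion,
        while holding mu near the fold makes G1 lengths diverge."""
        cv = lambda x: np.std(x) / np.mean(x)
        const_et, const_cen = simulate_normal_form(
            0.01, 0.1, dt=0.01, t_max=400.0, n=400, seed=1
        )
        ramp = lambda t: -1.0 + 0.5 * t  # crosses the fold at t=2
        ramp_et, ramp_cen = simulate_normal_form(
            ramp, 0.1, dt=0.01, t_max=400.0, n=400, seed=2
        )
        const_ok, ramp_ok = const_et[~const_cen], ramp_et[~ramp_cen]
        assert cv(ramp_ok) < 0.25 * cv(const_ok)
        # sub-critical holding: escape-dominated, CV approaching 1
        sub_et, sub_cen = simulate_normal_form(
            -0.05, 0.1, dt=0.01, t_max=1500.0, n=400, seed=3
        )
        assert cv(sub_et[~sub_cen]) > 0.7


class TestReduction:
    def test_fold_orientation_gives_positive_mu_above_crit(self, reduction):
        nf = reduction.map_params(reduction.C_crit + 0.01, 0.3)
        assert nf.mu > 0
        nf = reduction.map_params(reduction.C_crit - 0.01, 0.3)
        assert nf.mu < 0

    def test_quadratic_coefficient_finite_and_h_stable(self, rb, reduction):
        assert reduction.b != 0 and np.isfinite(reduction.b)
        # second difference at a coarser step agrees (the expansion is smooth)
        from g1crit.rb_switch import drift

        h = 1e-3
        b2 = 0.5 * (
            drift(reduction.r_fold + h, reduction.C_crit, rb)
            - 2 * drift(reduction.r_fold, reduction.C_crit, rb)
            + drift(reduction.r_fold - h, reduction.C_crit, rb)
        ) / h**2
        assert reduction.b == pytest.approx(b2, rel=1e-3)

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError):
            reduce_to_normal_form(RbParams(V=1.0))  # no fold at all

    def test_predicts_full_switch_exit_times_at_weak_noise(self, reduction):
        """Cross-module oracle: Airy delay + deterministic approach matches
        the simulated switch ensemble near the fold (weak-noise regime)."""
        rb = RbParams(sigma=0.05)
        C = reduction.C_crit + 0.005
        predicted = predict_exit_time(rb, C, red=reduction)
        et, cen = first_passage_ensemble(rb, C, dt=0.01, t_max=2000.0, n=1000, seed=5)
        ok = et[~cen]
        se = ok.std(ddof=1) / math.sqrt(ok.size)
        assert abs(predicted - ok.mean()) < 3.0 * se
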