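"""Core Greenspan model: parameter reduction, internal-radius solvers,
growth rate and trajectory integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import internal_radii_fd
from spheroidfit import (DimensionalParameters, ReducedParameters,
                         classify_phase, growth_rate, inhibited_radius,
                         necrotic_radius, nutrient_deficit,
                         reduce_parameters, simulate)


class TestReduceParameters:
    def test_direct_formula(self):
        dim = DimensionalParameters(s=0.1, lam=0.2, alpha=1.0, k=1e4,
                                    c_inf=1.0, c_i=0.85, c_n=0.4, Ro0=100.0)
        red = reduce_parameters(dim)
        assert red.Rc == pytest.approx(np.sqrt(6e4 * 0.6), rel=1e-12)
        assert red.Q == pytest.approx(0.5, rel=1e-12)
        assert red.gamma == pytest.approx(2.0, rel=1e-12)
        assert red.Ro0 == 100.0

    def test_equal_thresholds_give_Q_one(self):
        dim = DimensionalParameters(s=0.1, lam=0.0, alpha=1.0, k=1e4,
                                    c_inf=1.0, c_i=0.4, c_n=0.4, Ro0=100.0)
        red = reduce_parameters(dim)
        assert red.Q == pytest.approx(1.0)
        assert red.gamma == 0.0  # no necrotic volume loss

    @pytest.mark.parametrize("kw", [
        {"s": -0.1}, {"alpha": 0.0}, {"k": -1.0},
        {"c_n": 1.5},               # necrosis threshold above c_inf
        {"c_i": 0.3},               # inhibition below necrosis threshold
    ])
    def test_domain_errors(self, kw):
        base = dict(s=0.1, lam=0.2, alpha=1.0, k=1e4, c_inf=1.0,
                    c_i=0.85, c_n=0.4, Ro0=100.0)
        base.update(kw)
        with pytest.raises(ValueError):
            reduce_parameters(DimensionalParameters(**base))


class TestPhaseAndRadii:
    @pytest.mark.parametrize("Ro,expected", [
        (100.0, 1), (160.0, 1),    # at the boundary: lower phase
        (180.0, 2), (200.0, 2),
        (250.0, 3),
    ])
    def test_classify_phase(self, Ro, expected):
        p = ReducedParameters(Ro0=50, Rc=200.0, s=0.1, gamma=0.0, Q=0.8)
        assert classify_phase(Ro, p) == expected

    def test_necrotic_radius_onset_and_value(self):
        p = ReducedParameters(Ro0=50, Rc=200.0, s=0.1, gamma=0.0, Q=0.8)
        assert necrotic_radius(200.0, p) == 0.0
        # root of 2n^3 - 3n^2 + 1 = 0.64 (frozen from scipy.brentq)
        assert necrotic_radius(250.0, p) == pytest.approx(
            101.38574752954581, rel=1e-10)

    def test_necrotic_fraction_limit(self):
        p = ReducedParameters(Ro0=50, Rc=1.0, s=0.1, gamma=0.0, Q=0.8)
        assert necrotic_radius(1e6, p) / 1e6 == pytest.approx(1.0, abs=1e-2)

    def test_inhibited_phase2_closed_form(self):
        p = ReducedParameters(Ro0=50, Rc=250.0, s=0.1, gamma=0.0, Q=0.8)
        ri = inhibited_radius(220.0, 0.0, p)
        assert ri == pytest.approx(np.sqrt(220 ** 2 - 200 ** 2), rel=1e-12)

    def test_inhibited_zero_at_phase_boundary(self):
        p = ReducedParameters(Ro0=50, Rc=250.0, s=0.1, gamma=0.0, Q=0.8)
        assert inhibited_radius(200.0, 0.0, p) == 0.0

    def test_Q_one_collapses_inhibited_onto_necrotic(self):
        p = ReducedParameters(Ro0=50, Rc=150.0, s=0.1, gamma=0.5, Q=1.0)
        rn = necrotic_radius(300.0, p)
        assert rn > 0
        assert inhibited_radius(300.0, rn, p) == rn

    def test_inconsistent_Rn_rejected(self):
        p = ReducedParameters(Ro0=50, Rc=150.0, s=0.1, gamma=0.5, Q=0.8)
        with pytest.raises(ValueError):
            inhibited_radius(300.0, 310.0, p)
        with pytest.raises(ValueError):
            inhibited_radius(300.0, 5.0, p)  # far from the true root

    def test_continuity_at_onset(self):
        p = ReducedParameters(Ro0=50, Rc=200.0, s=0.1, gamma=0.0, Q=0.8)
        rn = necrotic_radius(200.0 * (1 + 1e-6), p)
        assert 0 < rn < 0.5
        ri = inhibited_radius(160.0 * (1 + 1e-6), 0.0, p)
        assert 0 < ri < 0.5

    def test_necrotic_fraction_monotone_in_size(self):
        p = ReducedParameters(Ro0=50, Rc=100.0, s=0.1, gamma=0.0, Q=0.8)
        ratios = np.linspace(1.05, 4.0, 40)
        frac = np.array([necrotic_radius(r * 100.0, p) / (r * 100.0)
                         for r in ratios])
        assert np.all(np.diff(frac) > 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(ro_frac=st.floats(0.2, 2.4), rc=st.floats(20.0, 249.0),
           q=st.floats(0.05, 1.0))
    def test_radius_ordering(self, ro_frac, rc, q):
        """0 <= Rn <= Ri <= Ro for any state within the calibration box."""
        p = ReducedParameters(Ro0=50, Rc=rc, s=0.1, gamma=1.0, Q=q)
        ro = max(ro_frac * rc, 1.0)
        rn = necrotic_radius(ro, p)
        ri = inhibited_radius(ro, rn, p)
        assert 0.0 <= rn <= ri <= ro


class TestOracleEquivalence:
    def test_fd_free_boundary_agreement_sample(self):
        """Algebraic solvers match the finite-volume nutrient solution
        (small sample; the full 100-configuration sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            rc = rng.uniform(80.0, 220.0)
            ro = rc * rng.uniform(1.01, 2.5)
            q = rng.uniform(0.2, 1.0)
            p = ReducedParameters(Ro0=50, Rc=rc, s=0.1, gamma=0.0, Q=q)
            rn = necrotic_radius(ro, p)
            ri = inhibited_radius(ro, rn, p)
            ri_fd, rn_fd = internal_radii_fd(ro, rc, q)
            assert rn == pytest.approx(rn_fd, rel=1e-6)
            assert ri == pytest.approx(ri_fd, rel=1e-6)


class TestGrowthRate:
    def test_phase1_linear_in_Ro(self):
        p = ReducedParameters(Ro0=50, Rc=400.0, s=0.3, gamma=0.0, Q=1.0)
        assert growth_rate(100.0, p) == pytest.approx(10.0, rel=1e-12)

    def test_balance_point_is_stationary(self):
        # choose gamma so that proliferation exactly balances loss
        p0 = ReducedParameters(Ro0=50, Rc=150.0, s=0.2, gamma=1.0, Q=0.8)
        ro = 400.0
        rn = necrotic_radius(ro, p0)
        ri = inhibited_radius(ro, rn, p0)
        gamma_star = (ro ** 3 - ri ** 3) / (3 * rn ** 3)
        p = ReducedParameters(Ro0=50, Rc=150.0, s=0.2, gamma=gamma_star,
                              Q=0.8)
        assert growth_rate(ro, p) == pytest.approx(0.0, abs=1e-9)

    def test_phase3_rate_against_fd_radii(self):
        p = ReducedParameters(Ro0=50, Rc=200.0, s=0.14, gamma=1.0, Q=0.8)
        ro = 250.0
        ri_fd, rn_fd = internal_radii_fd(ro, 200.0, 0.8)
        expected = (p.s / 3 * (ro ** 3 - ri_fd ** 3)
                    - p.gamma * p.s * rn_fd ** 3) / ro ** 2
        assert growth_rate(ro, p) == pytest.approx(expected, rel=1e-6)


class TestNutrientDeficit:
    def test_surface_and_no_core_profile(self):
        assert nutrient_deficit(300.0, 300.0, 50.0) == 0.0
        r = np.linspace(0, 200, 9)
        np.testing.assert_allclose(nutrient_deficit(r, 200.0, 0.0),
                                   200.0 ** 2 - r ** 2, rtol=1e-12)

    def test_constant_inside_core(self):
        u_core = nutrient_deficit(10.0, 300.0, 80.0)
        assert u_core == pytest.approx(nutrient_deficit(80.0, 300.0, 80.0))
        assert u_core == pytest.approx(nutrient_deficit(0.0, 300.0, 80.0))

    def test_against_fd_profile(self):
        """Shell profile agrees with the finite-volume solve of the
        diffusion-consumption balance."""
        from oracles import solve_deficit_fd
        ro, rn = 300.0, 90.0
        x, v = solve_deficit_fd(rn / ro)
        r = np.linspace(rn, ro, 23)
        u = nutrient_deficit(r, ro, rn)
        u_fd = np.interp(r / ro, x, v) * ro ** 2
        np.testing.assert_allclose(u, u_fd, rtol=2e-6, atol=1e-4 * ro ** 2 * 1e-2)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            nutrient_deficit(-1.0, 200.0, 0.0)
        with pytest.raises(ValueError):
            nutrient_deficit(250.0, 200.0, 0.0)


class TestSimulate:
    def test_phase1_exponential(self):
        p = ReducedParameters(Ro0=100.0, Rc=400.0, s=0.3, gamma=0.0, Q=1.0)
        t = np.linspace(0.0, 10.0, 11)
        traj = simulate(p, t)
        np.testing.assert_allclose(traj.Ro, 100.0 * np.exp(0.3 * t / 3.0),
                                   rtol=1e-8)
        assert all(st.phase == 1 for st in traj.states)

    def test_single_time_zero(self):
        # Ro0 = 120 sits between Q*Rc = 105 and Rc = 150: starts in phase 2
        p = ReducedParameters(Ro0=120.0, Rc=150.0, s=0.3, gamma=1.0, Q=0.7)
        traj = simulate(p, [0.0])
        st0 = traj.states[0]
        assert st0.Ro == pytest.approx(120.0, rel=1e-12)
        assert st0.phase == 2 and st0.Ri > 0 and st0.Rn == 0.0

    def test_states_respect_ordering_and_continuity(self, theta_star):
        t = np.linspace(0.0, 25.0, 101)
        traj = simulate(theta_star, t)
        assert np.all(traj.Rn <= traj.Ri + 1e-9)
        assert np.all(traj.Ri <= traj.Ro + 1e-9)
        # outer radius evolves continuously (no jumps across transitions)
        assert np.max(np.abs(np.diff(traj.Ro))) < 10.0

    def test_long_horizon_reaches_growth_loss_balance(self):
        p = ReducedParameters(Ro0=100.0, Rc=150.0, s=0.3, gamma=1.5, Q=0.8)
        traj = simulate(p, [200.0])
        from spheroidfit import growth_rate as gr
        ro = traj.Ro[0]
        assert abs(gr(ro, p)) < 1e-4 * p.s * ro

    def test_Q_above_one_matches_Q_one_for_outer_and_necrotic(self):
        t = np.linspace(0.0, 20.0, 21)
        base = dict(Ro0=120.0, Rc=150.0, s=0.3, gamma=1.0)
        tr1 = simulate(ReducedParameters(**base, Q=1.0), t)
        tr2 = simulate(ReducedParameters(**base, Q=1.3), t)
        np.testing.assert_allclose(tr1.Ro, tr2.Ro, rtol=1e-9)
        np.testing.assert_allclose(tr1.Rn, tr2.Rn, rtol=1e-9, atol=1e-9)
        assert np.all(tr2.Ri == 0.0)  # no inhibited region above Q = 1

    def test_against_scipy_reference_integrator(self, theta_star):
        """Cross-check the in-package adaptive RK against scipy's."""
        from scipy.integrate import solve_ivp
        from spheroidfit import growth_rate as gr
        t = np.array([0.0, 5.0, 10.0, 17.0])
        sol = solve_ivp(lambda _, y: [gr(y[0], theta_star)], (0, 17.0),
                        [theta_star.Ro0], t_eval=t, rtol=1e-10, atol=1e-10)
        traj = simulate(theta_star, t)
        np.testing.assert_allclose(traj.Ro, sol.y[0], rtol=1e-7)

    def test_invalid_times(self, theta_star):
        with pytest.raises(ValueError):
            simulate(theta_star, [])
        with pytest.raises(ValueError):
            simulate(theta_star, [1.0, 1.0])
        with pytest.raises(ValueError):
            simulate(theta_star, [-1.0, 2.0])
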