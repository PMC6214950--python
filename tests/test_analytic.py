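import numpy as np
import pytest
from scipy.optimize import minimize

from hettasep.analytic import (
    WeightVector,
    balance_matrix,
    balance_residual,
    density_weights,
    delta_total_current,
    lane_currents,
    lane_currents_z_form,
    lane_densities,
    langmuir_map,
    optimal_current,
    particle_moments,
    solve_fugacity,
    solve_stationary,
    total_current,
)
from hettasep.model import RateSet, build_homogeneous, build_random


class TestDensityWeights:
    @pytest.mark.parametrize("omega, expected", [(0.5, 2.0), (1.0, 1.0)])
    def test_homogeneous_closed_form(self, omega, expected):
        w = density_weights(build_homogeneous(6, omega, 1.0))
        assert np.allclose(w.f, expected, rtol=1e-14)

    def test_ring_balance_satisfied(self, asym_k3):
        w = density_weights(asym_k3)
        res = balance_residual(asym_k3, w)
        assert np.abs(res).max() < 1e-12

    def test_matches_balance_matrix_nullspace(self, asym_k3):
        w = density_weights(asym_k3)
        W = balance_matrix(asym_k3)
        _, _, vt = np.linalg.svd(W)
        null = np.abs(vt[-1])
        ratio = w.f / null
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    def test_residual_scale_over_seeds(self, random_ratesets):
        for rates in random_ratesets:
            w = density_weights(rates)
            res = balance_residual(rates, w)
            scale = np.max(w.f * (rates.omega_up + rates.omega_down))
            assert np.abs(res).max() < 1e-10 * scale

    def test_perturbed_weights_detected(self, asym_k3):
        w = density_weights(asym_k3)
        f = w.f.copy()
        f[1] *= 1.1
        res = balance_residual(asym_k3, WeightVector(f))
        assert np.abs(res).max() > 1e-3

    def test_extreme_ratio_overflow_named(self):
        # compounding ratio ~1e4 per lane over many lanes overflows float64
        K = 100
        rates = RateSet(K, np.full(K, 1e2), np.full(K, 1e-2), np.ones(K))
        with pytest.raises(OverflowError, match="lane"):
            density_weights(rates)

    def test_large_k_heterogeneous_finite(self):
        # across 2000 lanes the cumulative log-ratio walk spans hundreds of
        # orders of magnitude in the partial products; log-space sums keep
        # the weights themselves finite
        rates = build_random(2000, seed=0)
        w = density_weights(rates)
        assert np.all(np.isfinite(w.f)) and np.all(w.f > 0)
        res = balance_residual(rates, w)
        scale = np.max(w.f * (rates.omega_up + rates.omega_down))
        assert np.abs(res).max() < 1e-10 * scale


class TestBalanceMatrix:
    def test_structure_and_nullvector_homogeneous(self):
        W = balance_matrix(build_homogeneous(3, 1.0, 1.0))
        assert np.allclose(W @ np.ones(3), 0.0)
        assert np.allclose(np.diag(W), -2.0)

    def test_rank_deficiency_is_exactly_one(self):
        rates = build_random(5, seed=17)
        W = balance_matrix(rates)
        sv = np.linalg.svd(W, compute_uv=False)
        assert sv[-1] < 1e-12 * sv[0]
        assert sv[-2] > 1e-6 * sv[0]

    def test_annihilates_density_weights(self, random_ratesets):
        for rates in random_ratesets[:20]:
            w = density_weights(rates)
            W = balance_matrix(rates)
            assert np.abs(W @ w.f).max() < 1e-10 * np.abs(W).max() * w.f.max()


class TestFugacity:
    def test_homogeneous_closed_form(self):
        for omega in (0.5, 1.0, 2.0):
            w = density_weights(build_homogeneous(5, omega, 1.0))
            assert solve_fugacity(w, 0.5) == pytest.approx(omega, rel=1e-10)
            for rho in (0.1, 0.3, 0.8):
                assert solve_fugacity(w, rho) == pytest.approx(
                    omega * rho / (1 - rho), rel=1e-10
                )

    def test_fig4_equation_residual(self, fig4):
        rates, _ = fig4
        w = density_weights(rates)
        z = solve_fugacity(w, 0.5)
        assert abs(np.sum(z * w.f / (1 + z * w.f)) - 5.0) < 1e-10

    def test_boundary_density_rejected(self):
        w = density_weights(build_homogeneous(4, 1.0, 1.0))
        with pytest.raises(ValueError):
            solve_fugacity(w, 0.0)


class TestLaneObservables:
    def test_density_limits_and_midpoint(self):
        w = WeightVector(np.array([0.5, 2.0, 4.0]))
        assert np.all(lane_densities(w, 0.0) == 0.0)
        assert lane_densities(w, 2.0)[0] == pytest.approx(0.5)

    def test_current_values(self, asym_k3):
        assert np.allclose(lane_currents(asym_k3, [0.5] * 3), 0.25)
        assert np.all(lane_currents(asym_k3, [0.0] * 3) == 0.0)
        assert np.all(lane_currents(asym_k3, [1.0] * 3) == 0.0)

    def test_current_linear_in_forward_rate(self, asym_k3):
        doubled = asym_k3.with_p(2 * asym_k3.p)
        rho = [0.3, 0.6, 0.9]
        assert np.allclose(lane_currents(doubled, rho), 2 * lane_currents(asym_k3, rho))

    def test_z_form_equivalence_on_grid(self, asym_k3):
        w = density_weights(asym_k3)
        for z in np.logspace(-3, 3, 25):
            a = lane_currents(asym_k3, lane_densities(w, z))
            b = lane_currents_z_form(asym_k3, w, z)
            assert np.allclose(a, b, rtol=1e-12)

    def test_particle_moments(self):
        mean, var = particle_moments([0.3, 0.0, 1.0], L=1000)
        assert np.allclose(mean, [300.0, 0.0, 1000.0])
        assert np.allclose(var, [210.0, 0.0, 0.0])


class TestSolveStationary:
    def test_conservation_and_totals(self, random_ratesets):
        for rates in random_ratesets[:20]:
            for rho_bar in (0.2, 0.5, 0.8):
                sol = solve_stationary(rates, rho_bar)
                assert abs(sol.rho.sum() - rates.K * rho_bar) < 1e-10
                assert sol.J_total == pytest.approx(sol.J.sum())

    def test_homogeneous_exact(self):
        rates = build_homogeneous(7, 0.4, 1.0)
        sol = solve_stationary(rates, 0.3)
        assert np.allclose(sol.rho, 0.3, rtol=1e-12)
        assert np.allclose(sol.J, 0.3 * 0.7, rtol=1e-12)
        assert total_current(rates, 0.5) == pytest.approx(0.25 * 7)

    def test_boundaries(self, asym_k3):
        assert np.all(solve_stationary(asym_k3, 0.0).rho == 0.0)
        assert np.all(solve_stationary(asym_k3, 1.0).rho == 1.0)
        assert total_current(asym_k3, 0.0) == 0.0
        assert total_current(asym_k3, 1.0) == 0.0

    def test_scale_invariance_of_observables(self, asym_k3):
        w = density_weights(asym_k3)
        for c in (1e-3, 0.1, 7.0, 1e4):
            z1 = solve_fugacity(w, 0.37)
            z2 = solve_fugacity(w.scaled(c), 0.37)
            assert z2 == pytest.approx(z1 / c, rel=1e-9)
            assert np.allclose(
                lane_densities(w, z1), lane_densities(w.scaled(c), z2), rtol=1e-9
            )

    def test_density_monotone_in_filling(self, asym_k3):
        grid = np.linspace(0.01, 0.99, 99)
        rho = np.array([solve_stationary(asym_k3, rb).rho for rb in grid])
        assert np.all(np.diff(rho, axis=0) > 0)

    def test_current_unimodal_with_quarter_peak(self, asym_k3):
        grid = np.linspace(0.001, 0.999, 999)
        J = np.array([solve_stationary(asym_k3, rb).J for rb in grid])
        for lane in range(3):
            peak = int(np.argmax(J[:, lane]))
            assert np.all(np.diff(J[: peak + 1, lane]) > 0)
            assert np.all(np.diff(J[peak:, lane]) < 0)
            assert J[:, lane].max() == pytest.approx(0.25, abs=1e-6)


class TestOptimalCurrent:
    def test_half_filling_closed_form(self):
        p = np.array([0.3, 1.0, 2.5])
        res = optimal_current(p, 0.5)
        assert res.lam == 0.0
        assert np.allclose(res.rho_star, 0.5)
        assert res.J_max == pytest.approx(0.25 * p.sum())
        assert res.interior

    def test_symmetric_forward_rates(self):
        res = optimal_current([1.0, 1.0, 1.0], 0.3)
        assert np.allclose(res.rho_star, 0.3)
        assert res.J_max == pytest.approx(3 * 0.3 * 0.7)

    def test_against_constrained_optimizer(self):
        p = np.array([1.0, 2.0, 4.0])
        rho_bar = 0.4
        res = optimal_current(p, rho_bar)

        def neg_current(x):
            return -np.sum(p * x * (1 - x))

        opt = minimize(
            neg_current,
            x0=np.full(3, rho_bar),
            bounds=[(0, 1)] * 3,
            constraints={"type": "eq", "fun": lambda x: x.sum() - 3 * rho_bar},
            method="SLSQP",
            tol=1e-12,
        )
        assert res.J_max == pytest.approx(-opt.fun, rel=1e-8)
        assert np.allclose(res.rho_star, opt.x, atol=1e-6)

    def test_non_interior_flagged_not_raised(self):
        # widely spread forward rates push some optimal density out of [0,1]
        with pytest.warns(RuntimeWarning, match="interior"):
            res = optimal_current([0.01, 1.0, 1.0], 0.05)
        assert not res.interior

    def test_dominates_actual_currents(self, random_ratesets):
        for rho_bar in (0.3, 0.5, 0.7):
            for rates in random_ratesets:
                env = optimal_current(rates.p, rho_bar, rates.K)
                assert total_current(rates, rho_bar) <= env.J_max + 1e-9


class TestDeltaCurrent:
    def test_identical_rates_give_exact_zero(self):
        base = RateSet(10, [0.15] * 10, [0.35] * 10, [1.0] * 10)
        assert delta_total_current(base, base, 0.5) == 0.0

    def test_mismatched_K_rejected(self, asym_k3):
        with pytest.raises(ValueError):
            delta_total_current(asym_k3, build_homogeneous(4, 0.5, 1.0), 0.5)

    def test_heterogeneity_cannot_help_at_equal_p(self):
        # sum rho_i is fixed, so sum rho_i(1-rho_i) peaks at equal densities
        base = build_homogeneous(5, 0.3, 1.0)
        for seed in range(50):
            r = build_random(5, seed=seed)
            het = RateSet(5, r.omega_up, r.omega_down, np.ones(5))
            assert delta_total_current(het, base, 0.5) <= 1e-12

    def test_perturbation_sweep_zero_at_baseline(self):
        base = RateSet(10, [0.15] * 10, [0.35] * 10, [1.0] * 10)
        pert = base.with_omega_up(0, 0.15)
        assert delta_total_current(pert, base, 0.5) == 0.0
        assert abs(delta_total_current(base.with_omega_up(0, 0.6), base, 0.5)) > 1e-5


class TestLangmuirMap:
    @pytest.mark.parametrize(
        "z, f, expected",
        [(1.0, 1.0, (1.0, 1.0, 0.5)), (2.0, 3.0, (2.0, 1.0 / 3.0, 6.0 / 7.0))],
    )
    def test_examples(self, z, f, expected):
        assert langmuir_map(z, f) == pytest.approx(expected)

    def test_consistent_with_lane_density_on_grid(self):
        w = WeightVector(np.array([0.2, 1.0, 5.0]))
        for z in np.logspace(-2, 2, 9):
            rho = lane_densities(w, z)
            for i, f in enumerate(w.f):
                _, _, rho_eq = langmuir_map(z, f)
                assert rho_eq == pytest.approx(rho[i], rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            langmuir_map(0.0, 1.0)
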