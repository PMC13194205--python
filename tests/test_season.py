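import numpy as np
import pytest
from scipy.integrate import solve_ivp

import streampop as sp
from streampop.errors import InvalidParameterError
from streampop.season import LinearField, linear_propagate

from conftest import interior


class TestGreensPropagate:
    def test_constants_are_invariant(self, small_grid):
        phi = sp.constant_field(small_grid, 3.2)
        out = sp.greens_propagate(phi, D=1.0, q=0.0, t=1.0)
        mask = interior(small_grid, 6.0 * np.sqrt(2.0))
        assert np.max(np.abs(out.values[mask] - 3.2)) < 1e-8

    def test_point_mass_peak_advects(self, small_grid):
        vals = np.zeros(small_grid.n_nodes)
        vals[small_grid.n_nodes // 2] = 1.0 / small_grid.spacing
        out = sp.greens_propagate(sp.DensityField(small_grid, vals),
                                  D=1.0, q=2.0, t=1.0)
        peak = small_grid.nodes[np.argmax(out.values)]
        assert abs(peak - 2.0) <= small_grid.spacing + 1e-12

    def test_gaussian_convolution_closed_form(self, small_grid):
        # Gaussian(sd s0) propagated for time t under pure diffusion is a
        # Gaussian of variance s0^2 + 2 D t (amplitude rescaled)
        x = small_grid.nodes
        s0 = 1.5
        phi = sp.DensityField(small_grid, np.exp(-x**2 / (2 * s0**2)))
        out = sp.greens_propagate(phi, D=1.0, q=0.0, t=1.0)
        s2 = s0**2 + 2.0
        exact = s0 / np.sqrt(s2) * np.exp(-x**2 / (2 * s2))
        assert np.max(np.abs(out.values - exact)) / exact.max() < 1e-8

    def test_mu_shift_scales_exponentially(self, small_grid):
        phi = sp.constant_field(small_grid, 1.0)
        out = sp.greens_propagate(phi, D=1.0, q=0.0, t=2.0, mu_shift=0.3)
        mask = interior(small_grid, 16.0)
        assert np.allclose(out.values[mask], np.exp(-0.6), atol=1e-10)

    def test_zero_time_is_identity_and_negative_rejected(self, small_grid):
        phi = sp.constant_field(small_grid, 2.0)
        assert np.array_equal(
            sp.greens_propagate(phi, 1.0, 0.0, 0.0).values, phi.values)
        with pytest.raises(InvalidParameterError):
            sp.greens_propagate(phi, 1.0, 0.0, -0.1)


class TestReactionStepExact:
    def test_pure_quadratic_decay(self):
        assert sp.reaction_step_exact(1.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_zero_dt_identity(self):
        assert sp.reaction_step_exact(1.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_closed_form_against_ode_integrator(self):
        # du/dt = -alpha u - u^2; high-accuracy integration is the oracle
        expected = np.exp(-1.0) / (2.0 - np.exp(-1.0))  # = 0.2253996736
        got = sp.reaction_step_exact(1.0, 1.0, 1.0)
        assert got == pytest.approx(expected, abs=1e-12)
        ode = solve_ivp(lambda t, u: -1.0 * u - u**2, (0, 1), [1.0],
                        rtol=1e-12, atol=1e-14)
        assert got == pytest.approx(ode.y[0, -1], abs=1e-9)

    def test_vectorized_with_mixed_alpha(self):
        alpha = np.array([0.0, 0.5, 1.0])
        out = sp.reaction_step_exact(np.full(3, 2.0), alpha, 0.7)
        for a, o in zip(alpha, out):
            ode = solve_ivp(lambda t, u, a=a: -a * u - u**2, (0, 0.7), [2.0],
                            rtol=1e-12, atol=1e-14)
            assert o == pytest.approx(ode.y[0, -1], abs=1e-9)

    def test_negative_initial_rejected(self):
        with pytest.raises(InvalidParameterError):
            sp.reaction_step_exact(-0.5, 1.0, 1.0)


class TestSolveSeason:
    def test_zero_stays_zero(self, baseline_model, small_grid):
        sol = sp.solve_season(baseline_model, sp.constant_field(small_grid, 0.0))
        assert all(f.sup_norm == 0.0 for f in sol.fields)

    def test_uniform_mortality_matches_bernoulli(self, small_grid):
        # constant alpha, no drift: transport leaves constants invariant,
        # so interior values follow the scalar closed form
        m = sp.ModelSpec(
            1.0, 0.0, 1.0,
            sp.logistic_mortality(sp.constant_profile(0.7)),
            sp.beverton_holt(sp.constant_profile(2.0)),
            sp.KernelSpec("gaussian", 0, 2))
        sol = sp.solve_season(m, sp.constant_field(small_grid, 1.3))
        expected = sp.reaction_step_exact(1.3, 0.7, 1.0)
        mask = interior(small_grid, 10.0)
        assert np.max(np.abs(sol.final.values[mask] - expected)) < 1e-6

    def test_linear_reaction_matches_advected_heat_solution(self, small_grid):
        th0 = -0.5
        m = sp.ModelSpec(1.0, 1.0, 1.0, sp.linear_reaction(th0),
                         sp.linear_birth(1.0), sp.KernelSpec("gaussian", 0, 2))
        x = small_grid.nodes
        u0 = sp.DensityField(small_grid, np.exp(-x**2 / 2))
        sol = sp.solve_season(m, u0, dt=1.0 / 64)
        s2 = 1.0 + 2.0
        exact = np.exp(th0) / np.sqrt(s2) * np.exp(-(x - 1.0)**2 / (2 * s2))
        assert np.max(np.abs(sol.final.values - exact)) / exact.max() < 1e-3

    def test_mass_conserved_without_reaction_or_drift(self, small_grid):
        m = sp.ModelSpec(1.0, 0.0, 1.0, sp.linear_reaction(0.0),
                         sp.linear_birth(1.0), sp.KernelSpec("gaussian", 0, 2))
        x = small_grid.nodes
        u0 = sp.DensityField(small_grid, np.exp(-x**2 / 8))
        sol = sp.solve_season(m, u0)
        assert sol.final.mass == pytest.approx(u0.mass, rel=1e-6)

    def test_comparison_principle_on_seeded_pairs(self, baseline_model,
                                                  seeded_payload):
        for phi, psi in seeded_payload["pairs"][:5]:
            lo = sp.solve_season(baseline_model, phi).final.values
            hi = sp.solve_season(baseline_model, psi).final.values
            assert np.all(lo <= hi + 1e-8)

    def test_nonnegativity_and_negligible_clipping(self, baseline_model,
                                                   seeded_payload):
        for phi in seeded_payload["fields"]:
            sol = sp.solve_season(baseline_model, phi)
            assert np.min(sol.final.values) >= 0.0
            assert sol.scheme_metadata["clipped_mass"] < 1e-10

    def test_non_divisible_dt_rejected(self, baseline_model, small_grid):
        with pytest.raises(InvalidParameterError):
            sp.solve_season(baseline_model, sp.constant_field(small_grid, 1.0),
                            dt=0.3)

    def test_recorded_times_bracket_the_season(self, baseline_model,
                                               small_grid):
        sol = sp.solve_season(baseline_model, sp.constant_field(small_grid, 1.0),
                              dt=0.25, record=[0.0, 0.5, 1.0])
        assert sol.times[0] == 0.0 and sol.times[-1] == 1.0
        assert len(sol.fields) == 3


class TestLinearPropagate:
    def test_zero_coefficient_preserves_constants(self, small_grid):
        lf = LinearField(xi=lambda x: np.zeros_like(x), D=1.0, q=0.0)
        out = linear_propagate(lf, sp.constant_field(small_grid, 2.0), 1.0,
                               1.0 / 16)
        mask = interior(small_grid, 10.0)
        assert np.allclose(out.values[mask], 2.0, atol=1e-10)

    def test_constant_coefficient_exact_growth(self, small_grid):
        th0 = -0.8
        lf = LinearField(xi=lambda x, t=th0: np.full_like(x, t), D=1.0, q=0.0)
        out = linear_propagate(lf, sp.constant_field(small_grid, 1.0), 2.0,
                               2.0 / 32)
        mask = interior(small_grid, 18.0)
        assert np.allclose(out.values[mask], np.exp(th0 * 2.0), atol=1e-10)

    def test_plateau_coefficient_between_envelopes(self, small_grid):
        # xi = -alpha(x) in [-1, 0]: solution of the linear equation from
        # phi = 1 must sit between the constant-coefficient envelopes
        alpha = sp.plateau_profile("mortality", 5.0)
        lf = LinearField(xi=lambda x: -alpha(x), D=1.0, q=0.0)
        out = linear_propagate(lf, sp.constant_field(small_grid, 1.0), 1.0,
                               1.0 / 32)
        mask = interior(small_grid, 10.0)
        assert np.all(out.values[mask] >= np.exp(-1.0) - 1e-8)
        assert np.all(out.values[mask] <= 1.0 + 1e-8)

    def test_linearity_in_the_initial_state(self, small_grid, seeded_payload):
        alpha = sp.plateau_profile("mortality", 5.0)
        lf = LinearField(xi=lambda x: -alpha(x), D=1.0, q=0.5)
        phi = seeded_payload["fields"][0]
        psi = seeded_payload["fields"][1]
        comb = sp.DensityField(small_grid, 2.0 * phi.values + 0.5 * psi.values)
        out_comb = linear_propagate(lf, comb, 1.0, 1.0 / 16).values
        out_sep = (2.0 * linear_propagate(lf, phi, 1.0, 1.0 / 16).values
                   + 0.5 * linear_propagate(lf, psi, 1.0, 1.0 / 16).values)
        assert np.max(np.abs(out_comb - out_sep)) < 1e-10

    def test_strang_splitting_second_order_for_smooth_coefficient(self):
        grid = sp.SpatialGrid(30.0, 1201)
        x = grid.nodes
        xi = lambda x: -1.0 / (1.0 + np.exp(-(np.abs(x) - 7.5)))  # noqa: E731
        lf = LinearField(xi=xi, D=1.0, q=1.0)
        phi = sp.DensityField(grid, np.exp(-x**2 / 8))
        ref = linear_propagate(lf, phi, 1.0, 1.0 / 512).values
        errs = [np.max(np.abs(linear_propagate(lf, phi, 1.0, 1.0 / K).values
                              - ref))
                for K in (16, 32, 64)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.8)
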