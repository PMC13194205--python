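import numpy as np
import pytest

import streampop as sp
from streampop.errors import InvalidParameterError, MemoryGuardError
from streampop.spectral import _LinearApplier, auto_substep

from conftest import interior


def homogeneous_lin(eta0, theta0, D=1.0, q=0.0, tau=1.0, sd=2.0):
    return sp.LinearizedModel(
        eta=lambda x, e=eta0: np.full_like(x, e),
        theta=lambda x, t=theta0: np.full_like(x, t),
        D=D, q=q, tau=tau, kernel=sp.KernelSpec("gaussian", 0.0, sd))


@pytest.fixture(scope="module")
def op_grid():
    return sp.SpatialGrid(50.0, 501)


@pytest.fixture(scope="module")
def baseline_lin(baseline_model):
    return sp.LinearizedModel.from_model(baseline_model)


@pytest.fixture(scope="module")
def baseline_matrix(baseline_lin, op_grid):
    return sp.assemble_operator(baseline_lin, op_grid, 1.0 / 16)


class TestZetaCutoff:
    @pytest.mark.parametrize("x, expected", [(0.0, 1.0), (2.5, 0.5), (4.0, 0.0),
                                             (-2.5, 0.5), (2.0, 1.0)])
    def test_tent_values(self, x, expected):
        assert sp.zeta_cutoff(3.0, x) == pytest.approx(expected)

    def test_positive_radius_required(self):
        with pytest.raises(InvalidParameterError):
            sp.zeta_cutoff(0.0, 1.0)


class TestAssembleOperator:
    def test_zero_fecundity_gives_zero_operator(self, op_grid):
        lin = homogeneous_lin(0.0, -0.5)
        M = sp.assemble_operator(lin, op_grid, 1.0 / 16)
        assert np.max(np.abs(M.entries)) == 0.0

    def test_action_on_constants_homogeneous(self, op_grid):
        # with eta = eta0 and theta = 0 the operator maps 1 to eta0
        # (interior; the propagator and kernel both preserve constants)
        lin = homogeneous_lin(2.0, 0.0)
        M = sp.assemble_operator(lin, op_grid, 1.0 / 16)
        ones = np.ones(op_grid.n_nodes)
        out = M.entries @ ones
        mask = interior(op_grid, 25.0)
        assert np.max(np.abs(out[mask] - 2.0)) < 1e-8

    def test_matrix_agrees_with_composed_application(self, baseline_lin,
                                                     baseline_matrix, op_grid,
                                                     seeded_payload):
        for phi in seeded_payload["fields"]:
            v = np.interp(op_grid.nodes, phi.grid.nodes, phi.values)
            direct = sp.apply_linearized(baseline_lin, op_grid, 1.0 / 16, v)
            via_matrix = baseline_matrix.entries @ v
            assert np.max(np.abs(direct - via_matrix)) < 1e-10

    def test_linearity_and_positivity(self, baseline_matrix, op_grid,
                                      seeded_payload):
        A = baseline_matrix.entries
        assert np.min(A) >= -1e-12
        f0 = np.interp(op_grid.nodes, seeded_payload["fields"][0].grid.nodes,
                       seeded_payload["fields"][0].values)
        f1 = np.interp(op_grid.nodes, seeded_payload["fields"][1].grid.nodes,
                       seeded_payload["fields"][1].values)
        lhs = A @ (1.7 * f0 + 0.3 * f1)
        rhs = 1.7 * (A @ f0) + 0.3 * (A @ f1)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_memory_guard(self, baseline_lin):
        big = sp.SpatialGrid(150.0, 8193)
        with pytest.raises(MemoryGuardError):
            sp.assemble_operator(baseline_lin, big, 1.0 / 16)


class TestTruncatedOperator:
    def test_truncation_restricts_and_weights(self, baseline_matrix, op_grid):
        M = sp.truncated_operator(baseline_matrix, 30.0)
        assert M.entries.shape[0] == np.sum(np.abs(op_grid.nodes) <= 30.0)

    def test_truncation_cannot_increase_radius(self, baseline_matrix):
        r_small = sp.spectral_radius(sp.truncated_operator(baseline_matrix,
                                                           25.0))
        r_big = sp.spectral_radius(sp.truncated_operator(baseline_matrix,
                                                         45.0))
        assert r_small <= r_big + 1e-10

    def test_radius_beyond_domain_rejected(self, baseline_matrix):
        with pytest.raises(InvalidParameterError):
            sp.truncated_operator(baseline_matrix, 51.0)


class TestSpectralRadius:
    def test_diagonal(self):
        assert sp.spectral_radius(np.diag([0.2, 0.7, 0.3])) == pytest.approx(0.7)

    def test_rank_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 1.0, 40)
        b = rng.uniform(0.1, 1.0, 40)
        assert sp.spectral_radius(np.outer(a, b)) == pytest.approx(
            float(b @ a), rel=1e-10)

    def test_power_matches_dense(self, baseline_matrix):
        M = sp.truncated_operator(baseline_matrix, 40.0)
        dense = sp.spectral_radius(M, method="dense_eig")
        power = sp.spectral_radius(M, method="power")
        assert power == pytest.approx(dense, rel=1e-6)


class TestEstimateRhoL:
    @pytest.mark.parametrize("eta0, theta0", [(2.0, 0.0), (1.0, -1.0)])
    def test_homogeneous_closed_form(self, eta0, theta0):
        grid = sp.SpatialGrid(80.0, 801)
        sweep = sp.estimate_rho_L(homogeneous_lin(eta0, theta0), grid)
        exact = eta0 * np.exp(theta0)
        assert sweep.rho_L_estimate == pytest.approx(exact, rel=0.02)
        assert np.all(np.diff(sweep.rho_values) >= -1e-8)

    def test_zero_fecundity_gives_zero(self):
        grid = sp.SpatialGrid(80.0, 401)
        sweep = sp.estimate_rho_L(homogeneous_lin(0.0, 0.0), grid)
        assert np.all(sweep.rho_values == 0.0)
        assert sweep.plateaued

    def test_matrix_free_power_agrees_with_dense(self, baseline_lin):
        grid = sp.SpatialGrid(50.0, 501)
        radii = [20.0, 30.0, 40.0]
        dense = sp.estimate_rho_L(baseline_lin, grid, radii=radii,
                                  method="dense")
        power = sp.estimate_rho_L(baseline_lin, grid, radii=radii,
                                  method="power")
        assert power.rho_L_estimate == pytest.approx(dense.rho_L_estimate,
                                                     rel=1e-6)

    def test_too_few_radii_rejected(self, baseline_lin):
        grid = sp.SpatialGrid(50.0, 501)
        with pytest.raises(InvalidParameterError):
            sp.estimate_rho_L(baseline_lin, grid, radii=[10.0, 20.0])

    def test_linearization_consistency_of_generation_map(self, baseline_model,
                                                         seeded_payload):
        # Q[eps*phi] = eps*L[phi] + O(eps^2): the nonlinear map and its
        # linearization agree to second order at the extinction state
        grid = sp.SpatialGrid(50.0, 1001)
        lin = sp.LinearizedModel.from_model(baseline_model)
        for phi in seeded_payload["fields"][:3]:
            Lphi = sp.apply_linearized(lin, grid, 1.0 / 64, phi.values)
            diffs = []
            for eps in (1e-2, 1e-3, 1e-4):
                scaled = sp.DensityField(grid, eps * phi.values)
                Q = sp.generation_step(baseline_model, scaled,
                                       dt=1.0 / 64).values
                diffs.append(np.max(np.abs(Q - eps * Lphi)))
            orders = np.log10(np.array(diffs[:-1]) / np.array(diffs[1:]))
            assert np.all(orders >= 1.8)


class TestPeriodicSpectralRadius:
    def test_homogeneous_constant_is_exact_eigenfunction(self):
        # on the circular domain constants are exact eigenfunctions, so the
        # homogeneous threshold is recovered to roundoff
        grid = sp.SpatialGrid(40.0, 401)
        lin = homogeneous_lin(2.0, 0.0)
        assert sp.periodic_spectral_radius(lin, grid) == pytest.approx(
            2.0, rel=1e-10)

    def test_dense_and_power_agree(self):
        sc_model = sp.build_scenario("fig5", m=10.0).model
        lin = sp.LinearizedModel.from_model(sc_model)
        grid = sp.SpatialGrid(75.0, 751)
        dense = sp.periodic_spectral_radius(lin, grid, method="dense")
        power = sp.periodic_spectral_radius(lin, grid, method="power")
        assert power == pytest.approx(dense, rel=1e-4)


class TestAutoSubstep:
    def test_coarse_grid_gets_fewer_substeps(self):
        lin = homogeneous_lin(1.0, 0.0)
        fine = sp.SpatialGrid(50.0, 1001)
        coarse = sp.SpatialGrid(50.0, 201)  # spacing 0.5
        assert auto_substep(lin, fine) <= auto_substep(lin, coarse)
        # the chosen substep always resolves the transport kernel
        for g in (fine, coarse):
            dt = auto_substep(lin, g)
            assert np.sqrt(2 * dt) >= 0.8 * g.spacing


class TestLinearApplierPositivity:
    def test_nonnegative_inputs_stay_nonnegative(self, baseline_lin,
                                                 seeded_payload):
        grid = sp.SpatialGrid(50.0, 501)
        ap = _LinearApplier(baseline_lin, grid, 1.0 / 16)
        for phi in seeded_payload["fields"]:
            v = np.interp(grid.nodes, phi.grid.nodes, phi.values)
            assert np.min(ap.apply(v)) >= -1e-12
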