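"""Unit tests for the continuum solver: quadrature, the three transport
operators against closed-form oracles, and the integrator's invariants."""

import numpy as np
import pytest

import phenomig as pm
from phenomig import pde
from phenomig.coefficients import ContinuumCoefficients, EnvironmentDynamics

from conftest import diffusion_coeffs


def uniform_fields(grid, value=1.0, e_value=0.0):
    return pm.Fields(n=np.full(grid.shape, value),
                     e=np.full(grid.n_x + 1, e_value))


class TestTotalDensity:
    def test_zero_and_constant(self, small_grid):
        assert (pm.total_density(np.zeros(small_grid.shape), small_grid) == 0).all()
        rho = pm.total_density(np.ones(small_grid.shape), small_grid)
        np.testing.assert_allclose(rho, 1.0)  # y spans [0, 1]

    def test_linear_integrand_is_exact(self, small_grid):
        """Midpoint quadrature over cell centres integrates n = y exactly."""
        n = np.tile(small_grid.y, (small_grid.n_x + 1, 1))
        np.testing.assert_allclose(pm.total_density(n, small_grid), 0.5,
                                   rtol=1e-14)


class TestSpatialRhs:
    def test_zero_density_gives_zero(self, small_grid):
        out = pm.spatial_rhs(np.zeros(small_grid.shape),
                             np.zeros(small_grid.n_x + 1),
                             diffusion_coeffs(), small_grid)
        assert (out == 0).all()

    def test_uniform_state_is_a_fixed_point(self, small_grid):
        """With uniform n, rho and e, both dn/dx and dD_m/dx vanish, so the
        transport term is exactly zero even for density-dependent D_m."""
        coeffs = ContinuumCoefficients(
            D_m=lambda y, rho, e: (1.0 - rho - e) * np.ones_like(y))
        out = pm.spatial_rhs(np.full(small_grid.shape, 0.3),
                             np.full(small_grid.n_x + 1, 0.2), coeffs, small_grid)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    @pytest.mark.parametrize("n_x", [100, 200, 400])
    def test_heat_equation_oracle(self, n_x):
        """Pure diffusion of a Gaussian matches the analytic heat-equation
        time derivative to O(dx^2)."""
        grid = pm.Grid(x_min=-10, x_max=10, y_min=0, y_max=1, n_x=n_x, n_y=0)
        t0 = 1.0
        x = grid.x
        n = np.exp(-x**2 / (4 * t0))[:, None]
        exact = (n.ravel() * (x**2 - 2 * t0) / (4 * t0**2))[:, None]
        out = pm.spatial_rhs(n, np.zeros(n_x + 1), diffusion_coeffs(), grid)
        interior = slice(5, -5)
        err = np.abs(out - exact)[interior].max()
        assert err < 5.0 * grid.dx**2

    def test_second_order_convergence_in_dx(self):
        errs = []
        for n_x in (100, 200, 400):
            grid = pm.Grid(x_min=-10, x_max=10, y_min=0, y_max=1, n_x=n_x, n_y=0)
            x = grid.x
            n = np.exp(-x**2 / 4.0)[:, None]
            exact = (n.ravel() * (x**2 - 2.0) / 4.0)[:, None]
            out = pm.spatial_rhs(n, np.zeros(n_x + 1), diffusion_coeffs(), grid)
            errs.append(np.abs(out - exact)[5:-5].max())
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert (orders > 1.5).all() and (orders < 2.5).all()


class TestPhenotypeRhs:
    def test_no_transport_short_circuits(self, small_grid):
        n = np.random.default_rng(0).uniform(size=small_grid.shape)
        out = pm.phenotype_rhs(n, np.zeros(small_grid.n_x + 1),
                               ContinuumCoefficients(), small_grid)
        assert (out == 0).all()

    def test_advection_conserves_mass_per_evaluation(self):
        """Interface fluxes telescope: the y-sum of the advective update is
        zero to machine precision (zero-flux boundaries)."""
        grid = pm.Grid(x_min=0, x_max=10, y_min=0, y_max=1, n_x=10, n_y=39)
        n = np.zeros(grid.shape)
        n[:, 10:20] = 1.0  # square pulse
        coeffs = ContinuumCoefficients(
            v_p=lambda y, rho, e: 0.7 * np.ones(np.broadcast(y, rho, e).shape))
        out = pm.phenotype_rhs(n, np.zeros(grid.n_x + 1), coeffs, grid)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-13)

    def test_diffusion_eigenfunction_oracle(self):
        """cos(pi y) is the first zero-flux eigenfunction on [0, 1]:
        d2/dy2 (eps n) = -eps pi^2 n, matched to O(dy^2)."""
        eps = 0.05
        errs = []
        for n_y in (24, 49, 99):
            grid = pm.Grid(x_min=0, x_max=10, y_min=0, y_max=1, n_x=4, n_y=n_y)
            n = np.tile(np.cos(np.pi * grid.y), (5, 1))
            coeffs = ContinuumCoefficients(
                D_p=lambda y, rho, e: eps * np.ones(np.broadcast(y, rho, e).shape))
            out = pm.phenotype_rhs(n, np.zeros(5), coeffs, grid)
            errs.append(np.abs(out + eps * np.pi**2 * n).max())
        assert errs[0] < eps * np.pi**2 * 0.05
        orders = np.log(np.array(errs[:-1]) / np.array(errs[1:])) / \
            np.log(np.array([49 / 24, 99 / 49]))
        assert (orders > 1.5).all()

    def test_koren_limiter_profile(self):
        """The limiter function: phi(theta) = max(0, min(2 theta,
        (1 + 2 theta)/3, 2))."""
        theta = np.array([-1.0, 0.0, 0.25, 1.0, 4.0, 100.0])
        expected = np.array([0.0, 0.0, 0.5, 1.0, 2.0, 2.0])
        np.testing.assert_allclose(pde._koren_phi(theta), expected)


class TestReactionRhs:
    def test_pointwise_product(self, small_grid):
        n = np.full(small_grid.shape, 3.0)
        out = pm.reaction_rhs(n, np.zeros(small_grid.n_x + 1),
                              ContinuumCoefficients(
                                  r=lambda y, rho, e: np.ones_like(y)),
                              small_grid)
        np.testing.assert_allclose(out, 3.0)

    def test_logistic_rate(self, small_grid):
        """Uniform n with rho = 0.25 under r = 1 - rho gives 0.75 n."""
        n = np.full(small_grid.shape, 0.25)  # y-span 1 => rho = 0.25
        coeffs = ContinuumCoefficients(
            r=lambda y, rho, e: (1.0 - rho) * np.ones_like(y))
        out = pm.reaction_rhs(n, np.zeros(small_grid.n_x + 1), coeffs, small_grid)
        np.testing.assert_allclose(out, 0.75 * n, rtol=1e-12)


class TestEnvironmentRhs:
    def test_inert_environment(self, small_grid):
        out = pm.environment_rhs(np.ones(small_grid.shape),
                                 np.full(small_grid.n_x + 1, 0.5),
                                 ContinuumCoefficients(),
                                 EnvironmentDynamics.static(), small_grid)
        assert (out == 0).all()

    def test_exponential_decay_closed_form(self, small_grid):
        """With nu = n and static uniform cells (rho fixed), the environment
        decays as e0 exp(-rho t)."""
        rho0 = 0.4
        n0 = np.full(small_grid.shape, rho0)  # y-span 1
        coeffs = ContinuumCoefficients(nu=lambda y, n: n)
        fields0 = pm.Fields(n=n0, e=np.full(small_grid.n_x + 1, 0.8))
        cfg = pm.SolverConfig(save_times=np.linspace(0, 2, 5), rtol=1e-9,
                              atol=1e-12)
        traj = pm.solve(fields0, coeffs, EnvironmentDynamics.static(),
                        small_grid, cfg)
        expected = 0.8 * np.exp(-rho0 * traj.times[-1])
        np.testing.assert_allclose(traj.final.e, expected, rtol=1e-6)

    def test_logistic_growth_closed_form(self, small_grid):
        """With no cells and g = r_C (1 - e/kappa), e follows the logistic
        solution toward kappa."""
        r_C, kappa, e0 = 0.5, 1.0, 0.1
        env = EnvironmentDynamics(
            D_e=lambda rho, e: 1.0 - (rho + e) / kappa,
            g=lambda rho, e: r_C * (1.0 - (rho + e) / kappa),
        )
        fields0 = pm.Fields(n=np.zeros(small_grid.shape),
                            e=np.full(small_grid.n_x + 1, e0))
        cfg = pm.SolverConfig(save_times=np.linspace(0, 5, 6), rtol=1e-9,
                              atol=1e-12)
        traj = pm.solve(fields0, ContinuumCoefficients(), env, small_grid, cfg)
        t = traj.times[-1]
        expected = e0 * np.exp(r_C * t) / (1 - e0 + e0 * np.exp(r_C * t))
        np.testing.assert_allclose(traj.final.e, expected, rtol=1e-6)


class TestSolve:
    def test_zero_coefficients_keep_fields_constant(self, small_grid):
        fields0 = uniform_fields(small_grid, 0.3, 0.2)
        cfg = pm.SolverConfig(save_times=np.linspace(0, 5, 6))
        traj = pm.solve(fields0, ContinuumCoefficients(),
                        EnvironmentDynamics.static(), small_grid, cfg)
        for f in traj.fields:
            np.testing.assert_allclose(f.n, fields0.n, atol=1e-12)
            np.testing.assert_allclose(f.e, fields0.e, atol=1e-12)

    def test_logistic_growth_closed_form(self, small_grid):
        """Spatially uniform logistic growth from rho0 = 0.1 matches
        rho0 e^t / (1 - rho0 + rho0 e^t) to 1e-6 at t = 5."""
        rho0 = 0.1
        fields0 = uniform_fields(small_grid, rho0)
        coeffs = ContinuumCoefficients(
            r=lambda y, rho, e: (1.0 - rho) * np.ones_like(y))
        cfg = pm.SolverConfig(save_times=np.linspace(0, 5, 11), rtol=1e-10,
                              atol=1e-13)
        traj = pm.solve(fields0, coeffs, EnvironmentDynamics.static(),
                        small_grid, cfg)
        rho = pm.total_density(traj.final.n, small_grid)
        expected = rho0 * np.e**5 / (1 - rho0 + rho0 * np.e**5)
        np.testing.assert_allclose(rho, expected, atol=1e-6)

    def test_mass_conserved_without_reaction(self):
        """With r = 0 and zero-flux boundaries in both axes, the discrete
        mass is invariant to near machine precision."""
        pre = pm.go_or_grow("cell")
        coeffs = ContinuumCoefficients(
            D_m=pre.coeffs.D_m, v_p=pre.coeffs.v_p, D_p=pre.coeffs.D_p,
            nu=pre.coeffs.nu)  # r dropped
        grid = pm.Grid(x_min=0, x_max=20, y_min=0, y_max=1, n_x=100, n_y=9)
        fields0 = pre.initial_fields(grid)
        cfg = pm.SolverConfig(save_times=np.linspace(0, 10, 5))
        traj = pm.solve(fields0, coeffs, pre.env, grid, cfg)
        mass = [f.n.sum() * grid.dx * grid.dy for f in traj.fields]
        assert abs(mass[-1] - mass[0]) / mass[0] < 1e-8

    def test_capacity_barrier_for_volume_filling(self):
        """Volume-filling coefficients never push rho + e above kappa."""
        pre = pm.go_or_grow("cell")
        grid = pm.Grid(x_min=0, x_max=10, y_min=0, y_max=1, n_x=50, n_y=9)
        fields0 = pre.initial_fields(grid)
        cfg = pm.SolverConfig(save_times=np.linspace(0, 5, 6))
        traj = pm.solve(fields0, pre.coeffs, pre.env, grid, cfg)
        for f in traj.fields:
            occ = pm.total_density(f.n, grid) + f.e
            assert occ.max() <= pre.params.kappa + 1e-6

    def test_blow_up_detection(self, small_grid):
        fields0 = uniform_fields(small_grid, 0.5)
        coeffs = ContinuumCoefficients(
            r=lambda y, rho, e: 10.0 * np.ones_like(y))  # unbounded growth
        cfg = pm.SolverConfig(save_times=np.linspace(0, 10, 11))
        with pytest.raises(pde.SolverError):
            pm.solve(fields0, coeffs, EnvironmentDynamics.static(),
                     small_grid, cfg)


class TestConfigValidation:
    def test_save_times_must_increase(self):
        with pytest.raises(ValueError):
            pm.SolverConfig(save_times=np.array([0.0, 1.0, 0.5]))

    def test_unknown_limiter_rejected(self):
        with pytest.raises(ValueError, match="limiter"):
            pm.SolverConfig(limiter="superbee",
                            save_times=np.array([0.0, 1.0]))
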