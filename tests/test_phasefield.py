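"""Cahn--Hilliard dynamics: conservation, dissipation, interface calibration."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from airprint.phasefield import (
    GridSpec,
    PhaseFieldParams,
    PhaseFieldState,
    advective_dt_limit,
    cahn_hilliard_step,
    chemical_potential,
    equilibrium_profile,
    free_energy,
    load_snapshot,
    save_snapshot,
    spinodal_state,
    volume_fractions,
)


def small_grid(bc="no-flux", n=64, dx=1e-5):
    return GridSpec(nx=n, ny=n, dx=dx, dy=dx, bc_x=bc, bc_y=bc)


class TestChemicalPotential:
    def test_uniform_phases_have_zero_potential(self):
        grid = small_grid()
        for val in (1.0, -1.0, 0.0):
            psi = chemical_potential(np.full(grid.shape, val), grid, 2e-5)
            assert np.abs(psi).max() < 1e-14

    @pytest.mark.parametrize("bc", ["no-flux", "periodic"])
    def test_tanh_profile_residual_second_order(self, bc):
        """psi on the analytic interface decays ~dx^2 under refinement."""
        eps = 0.05
        residuals = []
        for n in (64, 128, 256):
            grid = GridSpec(nx=n, ny=16, dx=1.0 / n, dy=1.0 / n, bc_x="no-flux",
                            bc_y=bc)
            x, _ = grid.cell_centers()
            phi = equilibrium_profile(x - 0.5, eps)
            residuals.append(np.abs(chemical_potential(phi, grid, eps)).max())
        rate = np.log2(residuals[0] / residuals[1])
        assert rate > 1.8
        assert np.log2(residuals[1] / residuals[2]) > 1.8


class TestEquilibriumProfile:
    def test_odd_and_saturating(self):
        eps = 1e-4
        assert equilibrium_profile(0.0, eps) == 0.0
        assert equilibrium_profile(50 * eps, eps) == pytest.approx(1.0)
        x = np.linspace(-5, 5, 11) * eps
        assert np.allclose(
            equilibrium_profile(x, eps), -equilibrium_profile(-x, eps)
        )

    def test_tanh_minimizes_discrete_energy(self):
        """Random perturbations of the equilibrium profile only raise F."""
        grid = GridSpec(nx=128, ny=16, dx=1e-5, dy=1e-5, bc_x="no-flux",
                        bc_y="periodic")
        eps = 2e-5
        params = PhaseFieldParams(sigma=0.025, eps_pf=eps)
        x, _ = grid.cell_centers()
        phi0 = equilibrium_profile(x - grid.lx / 2, eps)
        base = free_energy(
            PhaseFieldState(phi0, chemical_potential(phi0, grid, eps), 0.0, grid),
            params,
        )
        rng = np.random.default_rng(11)
        for _ in range(20):
            bump = 0.02 * rng.standard_normal(grid.shape)
            bump -= bump.mean()  # compare at equal mean composition
            phi = np.clip(phi0 + bump, -1.04, 1.04)
            f = free_energy(
                PhaseFieldState(phi, np.zeros(grid.shape), 0.0, grid), params
            )
            assert f >= base


class TestVolumeFractions:
    def test_pure_phases_and_midpoint(self):
        f_air, f_gel = volume_fractions(np.array([1.0, 0.0, -1.0]))
        assert np.allclose(f_air, [1.0, 0.5, 0.0])
        assert np.allclose(f_gel, [0.0, 0.5, 1.0])

    def test_pointwise_partition_of_unity_with_overshoot(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-1.05, 1.05, size=100)
        f_air, f_gel = volume_fractions(phi)
        assert np.allclose(f_air + f_gel, 1.0)
        assert (f_air >= 0).all() and (f_air <= 1).all()


class TestFreeEnergy:
    def test_zero_iff_pure_phase(self):
        grid = small_grid()
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        for val in (1.0, -1.0):
            st = PhaseFieldState(
                np.full(grid.shape, val), np.zeros(grid.shape), 0.0, grid
            )
            assert free_energy(st, params) == 0.0
        st = PhaseFieldState(
            np.full(grid.shape, 0.5), np.zeros(grid.shape), 0.0, grid
        )
        assert free_energy(st, params) > 0.0

    def test_line_tension_matches_sigma(self):
        """F/L of a relaxed flat interface reproduces the physical surface
        tension, validating lambda = (3/sqrt 8) sigma eps."""
        grid = GridSpec(nx=256, ny=16, dx=1e-5, dy=1e-5, bc_x="no-flux",
                        bc_y="periodic")
        eps = 2e-5
        params = PhaseFieldParams(sigma=0.025, eps_pf=eps)
        x, _ = grid.cell_centers()
        phi = equilibrium_profile(x - grid.lx / 2, eps)
        st = PhaseFieldState(phi, chemical_potential(phi, grid, eps), 0.0, grid)
        for _ in range(500):
            st = cahn_hilliard_step(st, None, params, 2e-6)
        assert free_energy(st, params) / grid.ly == pytest.approx(0.025, rel=0.05)


class TestCahnHilliardStep:
    def test_uniform_state_is_fixed_point(self):
        grid = small_grid("periodic")
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        phi = np.full(grid.shape, -1.0)
        st = PhaseFieldState(phi, np.zeros(grid.shape), 0.0, grid)
        zero = np.zeros(grid.shape)
        st2 = cahn_hilliard_step(st, (zero, zero), params, 1e-6)
        assert np.abs(st2.phi - phi).max() < 1e-13

    @pytest.mark.parametrize("bc", ["no-flux", "periodic"])
    def test_mass_conservation_1000_steps(self, bc):
        grid = small_grid(bc)
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        st = spinodal_state(grid, params, np.random.default_rng(1))
        m0 = st.phi.sum()
        for _ in range(1000):
            st = cahn_hilliard_step(st, None, params, 1e-6)
        drift = abs(st.phi.sum() - m0) / np.abs(st.phi).sum()
        assert drift < 1e-10

    def test_energy_dissipation_spinodal(self):
        grid = small_grid("periodic")
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        st = spinodal_state(grid, params, np.random.default_rng(5))
        f_prev = free_energy(st, params)
        for _ in range(400):
            st = cahn_hilliard_step(st, None, params, 2e-6)
            f = free_energy(st, params)
            assert f <= f_prev + 1e-12
            f_prev = f

    def test_interface_width_calibration(self):
        """A relaxed 1D interface has tanh width within 5% of sqrt(2) eps."""
        grid = GridSpec(nx=256, ny=16, dx=1e-5, dy=1e-5, bc_x="no-flux",
                        bc_y="periodic")
        eps = 2e-5
        params = PhaseFieldParams(sigma=0.025, eps_pf=eps)
        x, _ = grid.cell_centers()
        phi = np.tanh((x - grid.lx / 2) / (0.5 * eps))  # deliberately too sharp
        st = PhaseFieldState(phi, chemical_potential(phi, grid, eps), 0.0, grid)
        for _ in range(2500):
            st = cahn_hilliard_step(st, None, params, 1e-5)
        xc = x[:, 8]
        popt, _ = curve_fit(
            lambda xx, x0, w: np.tanh((xx - x0) / w), xc, st.phi[:, 8],
            p0=[grid.lx / 2, eps],
        )
        assert popt[1] == pytest.approx(np.sqrt(2.0) * eps, rel=0.05)

    def test_pure_advection_moves_center_of_mass(self):
        """With uniform u and negligible mobility, phi is transported at u."""
        grid = GridSpec(nx=128, ny=32, dx=1e-5, dy=1e-5)
        eps = 2e-5
        params = PhaseFieldParams(sigma=0.025, eps_pf=eps, chi_mob=1e-9)
        x, y = grid.cell_centers()
        r = np.hypot(x - 0.3 * grid.lx, y - grid.ly / 2)
        phi = np.tanh((6e-5 - r) / (np.sqrt(2) * eps))
        st = PhaseFieldState(phi, chemical_potential(phi, grid, eps), 0.0, grid)
        u = np.full(grid.shape, 0.01)
        v = np.zeros(grid.shape)
        dt = 0.25 * grid.dx / 0.01
        n = 200
        w0 = (st.phi + 1.0)
        com0 = (w0 * x).sum() / w0.sum()
        for _ in range(n):
            st = cahn_hilliard_step(st, (u, v), params, dt)
        w1 = (st.phi + 1.0)
        com1 = (w1 * x).sum() / w1.sum()
        assert com1 - com0 == pytest.approx(0.01 * n * dt, abs=grid.dx)

    def test_cfl_violation_raises_with_admissible_dt(self):
        grid = small_grid("periodic")
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        st = spinodal_state(grid, params, np.random.default_rng(2))
        u = np.full(grid.shape, 1.0)
        dt_ok = advective_dt_limit(u, u, grid)
        with pytest.raises(ValueError, match="stability bound"):
            cahn_hilliard_step(st, (u, u), params, 3.0 * dt_ok)

    def test_rejects_nonpositive_dt(self):
        grid = small_grid("periodic")
        params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
        st = spinodal_state(grid, params, np.random.default_rng(2))
        with pytest.raises(ValueError):
            cahn_hilliard_step(st, None, params, 0.0)


class TestStateValidation:
    def test_overshoot_rejected(self):
        grid = small_grid()
        phi = np.full(grid.shape, 1.2)
        with pytest.raises(ValueError, match="overshoot"):
            PhaseFieldState(phi, np.zeros(grid.shape), 0.0, grid)

    def test_resolution_guard(self):
        grid = small_grid()
        params = PhaseFieldParams(sigma=0.025, eps_pf=0.5 * grid.dx)
        with pytest.raises(ValueError, match="eps_pf"):
            params.check_resolution(grid)


def test_snapshot_round_trip(tmp_path):
    grid = small_grid("periodic", n=32)
    params = PhaseFieldParams(sigma=0.025, eps_pf=2e-5)
    st = spinodal_state(grid, params, np.random.default_rng(3))
    path = tmp_path / "snap.h5"
    save_snapshot(path, st, params, extra_fields={"u": np.ones(grid.shape)})
    back, attrs = load_snapshot(path)
    assert np.allclose(back.phi, st.phi)
    assert attrs["sigma"] == 0.025
    assert back.grid == grid
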