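"""Flow solver benchmarks: kinematics, mixtures, penalization, channel flows."""

import numpy as np
import pytest

from airprint.hydrodynamics import (
    FluidProperties,
    FlowState,
    NozzleModel,
    flow_step,
    inject_air,
    max_divergence,
    mixture_viscosity,
    nozzle_forcing,
    quiescent_flow,
    shear_rate_magnitude,
    surface_tension_force,
    wall_penalization,
)
from airprint.phasefield import (
    GridSpec,
    PhaseFieldParams,
    PhaseFieldState,
    chemical_potential,
    equilibrium_profile,
)
from airprint.rheology import HerschelBulkleyParams


def periodic_grid(nx=64, ny=64, dx=1e-4):
    return GridSpec(nx=nx, ny=ny, dx=dx, dy=dx)


def newtonian(mu, rho=1000.0):
    return FluidProperties(
        rho_gel=rho, gel_hb=HerschelBulkleyParams(0.0, mu, 1.0)
    )


class TestShearRate:
    def test_rigid_translation_is_shear_free(self):
        grid = periodic_grid()
        flow = FlowState(
            u=np.full(grid.shape, 0.3), v=np.full(grid.shape, -0.1),
            p=np.zeros(grid.shape), time=0.0, grid=grid,
        )
        assert np.abs(shear_rate_magnitude(flow)).max() < 1e-12

    def test_simple_shear_closed_form(self):
        grid = periodic_grid()
        x, y = grid.cell_centers()
        gd0 = 7.0
        # linear-in-y velocity is not periodic; restrict the check to the
        # interior away from the wrap
        flow = FlowState(
            u=gd0 * y, v=np.zeros(grid.shape), p=np.zeros(grid.shape),
            time=0.0, grid=grid,
        )
        gd = shear_rate_magnitude(flow)
        assert np.allclose(gd[:, 2:-2], gd0, rtol=1e-10)

    def test_matches_independent_stencil_on_smooth_field(self):
        grid = periodic_grid()
        x, y = grid.cell_centers()
        kx, ky = 2 * np.pi / grid.lx, 2 * np.pi / grid.ly
        u = np.sin(kx * x) * np.cos(ky * y)
        v = np.cos(2 * kx * x) * np.sin(ky * y)
        flow = FlowState(u=u, v=v, p=np.zeros(grid.shape), time=0.0, grid=grid)
        gd = shear_rate_magnitude(flow)
        # independent oracle: same definition via np.gradient on a wrapped
        # extension of the fields
        ue = np.pad(u, 2, mode="wrap")
        ve = np.pad(v, 2, mode="wrap")
        uy, ux = np.gradient(ue, grid.dy, grid.dx, edge_order=2)
        # np.gradient axis order: fields here are (x, y), so gradient axis 0
        # is x and axis 1 is y
        ux, uy = np.gradient(ue, grid.dx, grid.dy, edge_order=2)
        vx, vy = np.gradient(ve, grid.dx, grid.dy, edge_order=2)
        ref = np.sqrt(2 * ux**2 + 2 * vy**2 + (uy + vx) ** 2)[2:-2, 2:-2]
        assert np.abs(gd - ref).max() < 1e-10 * ref.max() + 1e-10


class TestMixtureViscosity:
    def test_pure_air(self):
        grid = periodic_grid()
        props = newtonian(5.0)
        mu = mixture_viscosity(np.ones(grid.shape), np.ones(grid.shape), props)
        assert np.allclose(mu, props.mu_air)

    def test_pure_newtonian_gel(self):
        grid = periodic_grid()
        props = newtonian(5.0)
        mu = mixture_viscosity(-np.ones(grid.shape), np.ones(grid.shape), props)
        assert np.allclose(mu, 5.0)

    def test_blend_identity_at_midplane(self):
        props = newtonian(5.0)
        mu = mixture_viscosity(np.zeros(4), np.ones(4), props)
        assert np.allclose(mu, 0.5 * (props.mu_air + 5.0))

    def test_warns_when_air_not_thin(self):
        with pytest.warns(UserWarning):
            FluidProperties(
                mu_air=10.0, gel_hb=HerschelBulkleyParams(0.0, 1.0, 1.0)
            )


class TestSurfaceTensionForce:
    def params(self, grid):
        return PhaseFieldParams(sigma=0.025, eps_pf=2 * grid.dx)

    def test_uniform_phase_no_force(self):
        grid = periodic_grid()
        params = self.params(grid)
        st = PhaseFieldState(
            np.ones(grid.shape), np.zeros(grid.shape), 0.0, grid
        )
        fx, fy = surface_tension_force(st, params)
        assert np.abs(fx).max() == 0.0 and np.abs(fy).max() == 0.0

    def test_flat_interface_net_force_cancels(self):
        grid = periodic_grid(128, 32)
        params = self.params(grid)
        x, _ = grid.cell_centers()
        # two opposing interfaces (periodic slab)
        phi = equilibrium_profile(x - grid.lx / 4, params.eps_pf) * \
            equilibrium_profile(3 * grid.lx / 4 - x, params.eps_pf)
        psi = chemical_potential(phi, grid, params.eps_pf)
        st = PhaseFieldState(phi, psi, 0.0, grid)
        fx, fy = surface_tension_force(st, params)
        net = abs(fx.sum()) * grid.cell_area
        scale = np.abs(fx).max() * grid.cell_area * fx.size
        assert net <= 1e-10 * max(scale, 1e-300)
        assert np.abs(fx[np.abs(phi) > 0.99]).max() <= 5e-3 * np.abs(fx).max()


class TestFlowStep:
    def test_zero_everything_stays_zero(self):
        grid = periodic_grid(32, 32)
        props = newtonian(1.0)
        flow = quiescent_flow(grid)
        out = flow_step(flow, None, props, None, None, 1e-3, stokes=True)
        assert np.abs(out.u).max() == 0.0
        assert np.abs(out.v).max() == 0.0

    def test_divergence_free_after_each_step(self):
        grid = periodic_grid(64, 64)
        props = newtonian(0.1)
        flow = quiescent_flow(grid)
        rng = np.random.default_rng(0)
        bx = rng.standard_normal(grid.shape)
        for _ in range(5):
            flow = flow_step(
                flow, None, props, None, None, 1e-4,
                body_force=(bx, 0.0), enforce_cfl=False,
            )
            u_scale = max(np.abs(flow.u).max(), 1e-12)
            assert max_divergence(flow) <= 1e-8 * (u_scale / grid.dx)

    def test_dt_bound_enforced(self):
        grid = periodic_grid(32, 32)
        props = newtonian(1.0)
        flow = quiescent_flow(grid)
        flow.u += 1.0
        with pytest.raises(ValueError, match="stability bound"):
            flow_step(flow, None, props, None, None, 1.0)

    def test_newtonian_poiseuille_profile(self):
        """Body-force-driven channel between penalized walls matches the
        parabolic closed form within a few percent."""
        nx, ny, dx = 16, 96, 1e-4
        grid = GridSpec(nx=nx, ny=ny, dx=dx, dy=dx)
        mu = 1.0
        props = newtonian(mu)
        walls = wall_penalization(grid, 8)
        flow = quiescent_flow(grid)
        G = 100.0
        for _ in range(1200):
            flow = flow_step(
                flow, None, props, None, None, 2e-3, stokes=True,
                body_force=(G, 0.0), penalizations=[walls], enforce_cfl=False,
            )
        u = flow.u.mean(axis=0)
        y = (np.arange(ny) + 0.5) * dx
        y0, y1 = 8 * dx, (ny - 8) * dx
        h, yc = (y1 - y0) / 2, (y0 + y1) / 2
        exact = np.maximum(G / (2 * mu) * (h**2 - (y - yc) ** 2), 0.0)
        sel = np.abs(y - yc) < h
        assert np.abs(u[sel] - exact[sel]).max() <= 0.05 * exact.max()

    def test_bingham_channel_plug(self):
        """Yield-stress channel flow shows the analytic Bingham plug."""
        nx, ny, dx = 16, 128, 1e-4
        grid = GridSpec(nx=nx, ny=ny, dx=dx, dy=dx)
        mu_p, tau_y = 1.0, 2.0
        props = FluidProperties(
            rho_gel=1000.0,
            gel_hb=HerschelBulkleyParams(tau_y, mu_p, 1.0, m_reg=2000.0),
        )
        walls = wall_penalization(grid, 8)
        flow = quiescent_flow(grid)
        y0f, y1f = 8 * dx, (ny - 8) * dx
        h, yc = (y1f - y0f) / 2, (y0f + y1f) / 2
        G = tau_y / (0.4 * h)  # plug covers ~40% of the half width
        for _ in range(3500):
            flow = flow_step(
                flow, None, props, None, None, 1e-3, stokes=True,
                body_force=(G, 0.0), penalizations=[walls], enforce_cfl=False,
            )
        u = flow.u.mean(axis=0)
        y = (np.arange(ny) + 0.5) * dx
        yp = np.abs(y - yc)
        y_plug = tau_y / G
        exact = np.where(
            yp <= y_plug,
            G / (2 * mu_p) * (h - y_plug) ** 2,
            G / (2 * mu_p) * (h**2 - yp**2) - tau_y / mu_p * (h - yp),
        )
        exact = np.maximum(exact, 0.0)
        sel = yp < h
        assert np.abs(u[sel] - exact[sel]).max() <= 0.05 * exact.max()
        plug = u[yp < 0.3 * h]
        assert plug.std() / plug.mean() < 0.01  # flat plug core


class TestNozzle:
    def make_nozzle(self, grid, q=0.0, speed=0.1):
        return NozzleModel(
            shape="ball",
            diameter=4 * grid.dx,
            ball_diameter=8 * grid.dx,
            position=(grid.lx / 2, grid.ly / 2),
            velocity=(speed, 0.0),
            air_flow_rate=q,
        )

    def test_mask_velocity_converges_with_penalization(self):
        """Stronger Brinkman penalization drives the masked cells to the
        nozzle velocity (within 1% at high strength)."""
        grid = periodic_grid(64, 64)
        props = newtonian(1.0)
        errs = []
        for strength in (1e4, 1e8):
            noz = NozzleModel(
                shape="ball", diameter=4 * grid.dx, ball_diameter=8 * grid.dx,
                position=(grid.lx / 2, grid.ly / 2), velocity=(0.05, 0.0),
                air_flow_rate=0.0, penalization_strength=strength,
            )
            flow = quiescent_flow(grid)
            for _ in range(200):
                flow = flow_step(
                    flow, None, props, None, nozzle_forcing(noz, grid),
                    5e-4, stokes=True, enforce_cfl=False,
                )
            forcing = nozzle_forcing(noz, grid)
            core = forcing.solid.weight > 0.999
            errs.append(np.abs(flow.u[core] - 0.05).max() / 0.05)
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    def test_injection_volume_bookkeeping(self):
        """A stationary nozzle exuding air for time T injects Q*T of
        2D-equivalent volume within 5%."""
        grid = periodic_grid(96, 96)
        noz = self.make_nozzle(grid, q=2e-9, speed=0.0)
        forcing = nozzle_forcing(noz, grid)
        phi = -np.ones(grid.shape)
        q2d = noz.area_rate_2d
        dt, n = 1e-4, 400
        total = 0.0
        for _ in range(n):
            phi, added = inject_air(phi, forcing.injection_weight, q2d * dt,
                                    grid.cell_area)
            total += added
        expected = q2d * n * dt
        assert total == pytest.approx(expected, rel=0.05)
        air = (phi + 1.0).sum() * grid.cell_area / 2.0
        assert air == pytest.approx(total, rel=1e-9)

    def test_zero_flow_rate_conserves_air(self):
        grid = periodic_grid(48, 48)
        noz = self.make_nozzle(grid, q=0.0)
        forcing = nozzle_forcing(noz, grid)
        assert forcing.area_rate_2d == 0.0
        phi = -np.ones(grid.shape)
        phi2, added = inject_air(phi, forcing.injection_weight, 0.0,
                                 grid.cell_area)
        assert added == 0.0
        assert np.array_equal(phi, phi2)

    def test_aspiration_removes_air(self):
        grid = periodic_grid(48, 48)
        phi = np.ones(grid.shape) * 0.0  # half air everywhere
        w = np.zeros(grid.shape)
        w[20:28, 20:28] = 1.0
        phi2, removed = inject_air(phi, w, -1e-9, grid.cell_area)
        assert removed == pytest.approx(-1e-9)
        assert (phi2[20:28, 20:28] < phi[20:28, 20:28]).all()

    def test_nozzle_outside_domain_halts(self):
        grid = periodic_grid(48, 48)
        noz = NozzleModel(
            shape="straight", diameter=4 * grid.dx,
            position=(2 * grid.lx, grid.ly / 2), velocity=(0.1, 0.0),
            air_flow_rate=0.0,
        )
        with pytest.raises(RuntimeError, match="left the domain"):
            nozzle_forcing(noz, grid)

    def test_wake_fluidization(self):
        """A translating nozzle thins the shear-thinning bath near itself:
        the minimum viscosity within two diameters drops well below the
        quiescent far-field plateau."""
        from airprint.hydrodynamics import _shear_rate_filtered

        grid = GridSpec(nx=128, ny=64, dx=6.25e-5, dy=6.25e-5)
        props = FluidProperties(
            rho_gel=1000.0,
            gel_hb=HerschelBulkleyParams(120.0, 20.0, 0.45),
            mu_cap=1.0e4,
        )
        d = 8 * grid.dx
        noz = NozzleModel(
            shape="bent-horizontal-segment", diameter=d,
            position=(grid.lx / 2, grid.ly / 2), velocity=(0.1, 0.0),
            air_flow_rate=0.0,
        )
        flow = quiescent_flow(grid)
        for _ in range(150):
            flow = flow_step(
                flow, None, props, None, nozzle_forcing(noz, grid), 2e-5,
                stokes=True, penalizations=[wall_penalization(grid, 3)],
                enforce_cfl=False,
            )
        gd = _shear_rate_filtered(flow)
        mu = np.asarray(
            mixture_viscosity(-np.ones(grid.shape), gd, props)
        )
        x, y = grid.cell_centers()
        near = np.hypot(x - noz.position[0], y - noz.position[1]) < 2 * d
        far = np.hypot(x - noz.position[0], y - noz.position[1]) > 4 * d
        assert mu[near].min() < 0.5 * np.median(mu[far])
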