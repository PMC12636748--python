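"""Incompressible variable-viscosity flow of the air/gel mixture.

Solves the 2D momentum equation for the diffuse air/gel mixture,

    rho0 ( du/dt + (u.grad) u ) = -grad p + div( mu(phi, gamma_dot) grad u )
                                  + f_st + f_brinkman (+ buoyancy),

with the mixture viscosity blending the Newtonian air viscosity and the
regularized Herschel--Bulkley gel viscosity by phase volume fraction, the
phase-field continuum-surface-force (CSF) term
``f_st = (lambda/eps_pf^2) * psi * grad(phi)``, and moving solid obstacles
(nozzles, walls) realized by Brinkman penalization.

Numerical scheme, chosen for the enormous viscosity contrasts of
yield-stress baths (regularized plateaus of 1e3--1e6 Pa*s next to air):

* collocated cell-centered velocity on a fully periodic box; physical
  walls are penalized stationary strips inside the box;
* viscous term taken fully implicit with the true variable viscosity via
  a Douglas ADI splitting (batched cyclic tridiagonal solves) -- stable at
  any viscosity, steady-state consistent;
* the transpose part of the deviatoric stress divergence is omitted
  (div(mu grad u) form); this is exact wherever mu is uniform and for
  unidirectional flows, and confines the error to the diffuse interface;
* advection and CSF explicit (CFL- and capillary-limited time step);
* exact spectral pressure projection (no discrete checkerboard mode), so
  the velocity is divergence-free to round-off every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .phasefield import GridSpec, PhaseFieldParams, PhaseFieldState, gradient
from .rheology import DEFAULT_MU_MAX, HerschelBulkleyParams, effective_viscosity

__all__ = [
    "FluidProperties",
    "FlowState",
    "NozzleModel",
    "Penalization",
    "shear_rate_magnitude",
    "mixture_viscosity",
    "surface_tension_force",
    "flow_step",
    "nozzle_forcing",
    "nozzle_divergence_source",
    "inject_air",
    "wall_penalization",
    "max_divergence",
    "flow_dt_limit",
    "quiescent_flow",
]


@dataclass(frozen=True)
class FluidProperties:
    """Densities and viscosities of the two phases."""

    rho_air: float = 1.2  # kg/m^3
    mu_air: float = 1.8e-5  # Pa*s
    rho_gel: float = 1000.0  # kg/m^3
    gel_hb: HerschelBulkleyParams = field(
        default_factory=lambda: HerschelBulkleyParams(tau_y=100.0, K=20.0, n=0.45)
    )
    mu_cap: float = DEFAULT_MU_MAX  # Pa*s, cap on the gel viscosity

    def __post_init__(self) -> None:
        if min(self.rho_air, self.mu_air, self.rho_gel, self.mu_cap) <= 0:
            raise ValueError("fluid properties must be positive")
        import warnings

        gel_mu0 = effective_viscosity(0.0, self.gel_hb, mu_max=self.mu_cap)
        if self.mu_air >= gel_mu0:
            warnings.warn(
                "mu_air is not small compared with the gel zero-shear "
                "viscosity; the mixture model assumes a thin inner phase"
            )


@dataclass
class FlowState:
    """Cell-centered velocity and pressure fields on a periodic grid."""

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float
    grid: GridSpec
    divergence_residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u", "v", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} must be finite")


def quiescent_flow(grid: GridSpec) -> FlowState:
    z = np.zeros(grid.shape)
    return FlowState(u=z.copy(), v=z.copy(), p=z.copy(), time=0.0, grid=grid)


def _require_periodic(grid: GridSpec) -> None:
    if grid.bc_x != "periodic" or grid.bc_y != "periodic":
        raise ValueError(
            "the flow solver runs on a fully periodic box; realize walls "
            "as penalized strips (see wall_penalization)"
        )


# ---------------------------------------------------------------------------
# Kinematics and material fields
# ---------------------------------------------------------------------------

def shear_rate_magnitude(flow: FlowState) -> np.ndarray:
    """gamma_dot = sqrt(2 D:D) with D the rate-of-strain tensor (1/s)."""
    g = flow.grid
    ux, uy = gradient(flow.u, g)
    vx, vy = gradient(flow.v, g)
    return np.sqrt(2.0 * ux**2 + 2.0 * vy**2 + (uy + vx) ** 2)


def _box3(f: np.ndarray) -> np.ndarray:
    """Periodic 3-point [1/4, 1/2, 1/4] smoothing along both axes.

    Exactly annihilates the grid-Nyquist checkerboard. Used on the velocity
    before evaluating the shear rate that feeds the viscosity law: without
    it, grid-scale velocity noise registers as an enormous shear rate,
    collapses the shear-thinning viscosity, and removes the very damping
    that would kill the noise (a positive-feedback instability of
    regularized yield-stress rheology on a grid).
    """
    g = 0.25 * (np.roll(f, 1, axis=0) + np.roll(f, -1, axis=0)) + 0.5 * f
    return 0.25 * (np.roll(g, 1, axis=1) + np.roll(g, -1, axis=1)) + 0.5 * g


try:
    from numba import njit as _njit_sr

    @_njit_sr(cache=True)
    def _filtered_shear_jit(u, v, dx, dy):  # pragma: no cover - jit
        nx, ny = u.shape
        uf = np.empty((nx, ny))
        vf = np.empty((nx, ny))
        for i in range(nx):
            ip, im = (i + 1) % nx, (i - 1) % nx
            for j in range(ny):
                jp, jm = (j + 1) % ny, (j - 1) % ny
                a = 0.25 * (u[ip, j] + u[im, j]) + 0.5 * u[i, j]
                b = 0.25 * (u[ip, jp] + u[im, jp]) + 0.5 * u[i, jp]
                c = 0.25 * (u[ip, jm] + u[im, jm]) + 0.5 * u[i, jm]
                uf[i, j] = 0.25 * (b + c) + 0.5 * a
                a = 0.25 * (v[ip, j] + v[im, j]) + 0.5 * v[i, j]
                b = 0.25 * (v[ip, jp] + v[im, jp]) + 0.5 * v[i, jp]
                c = 0.25 * (v[ip, jm] + v[im, jm]) + 0.5 * v[i, jm]
                vf[i, j] = 0.25 * (b + c) + 0.5 * a
        gd = np.empty((nx, ny))
        for i in range(nx):
            ip, im = (i + 1) % nx, (i - 1) % nx
            for j in range(ny):
                jp, jm = (j + 1) % ny, (j - 1) % ny
                ux = (uf[ip, j] - uf[im, j]) / (2.0 * dx)
                uy = (uf[i, jp] - uf[i, jm]) / (2.0 * dy)
                vx = (vf[ip, j] - vf[im, j]) / (2.0 * dx)
                vy = (vf[i, jp] - vf[i, jm]) / (2.0 * dy)
                gd[i, j] = np.sqrt(
                    2.0 * ux * ux + 2.0 * vy * vy + (uy + vx) ** 2
                )
        return gd

    _HAVE_SR_JIT = True
except Exception:  # pragma: no cover
    _HAVE_SR_JIT = False


def _shear_rate_filtered(flow: FlowState) -> np.ndarray:
    g = flow.grid
    if _HAVE_SR_JIT:
        return _filtered_shear_jit(
            np.ascontiguousarray(flow.u), np.ascontiguousarray(flow.v),
            g.dx, g.dy,
        )
    u = _box3(flow.u)
    v = _box3(flow.v)
    ux, uy = gradient(u, g)
    vx, vy = gradient(v, g)
    return np.sqrt(2.0 * ux**2 + 2.0 * vy**2 + (uy + vx) ** 2)


def mixture_viscosity(
    phi: np.ndarray,
    gamma_dot: np.ndarray,
    props: FluidProperties,
) -> np.ndarray:
    """Arithmetic volume-fraction blend of air and gel viscosities."""
    from .phasefield import volume_fractions

    f_air, f_gel = volume_fractions(phi)
    mu_gel = effective_viscosity(gamma_dot, props.gel_hb, mu_max=props.mu_cap)
    return f_air * props.mu_air + f_gel * mu_gel


def surface_tension_force(
    state: PhaseFieldState, params: PhaseFieldParams
) -> tuple[np.ndarray, np.ndarray]:
    """CSF body force f = (lambda/eps^2) * psi * grad(phi)  (N/m^3).

    Vanishes away from the interface where psi ~ 0 and grad(phi) ~ 0.
    """
    pre = params.lambda_mix / params.eps_pf**2
    gx, gy = gradient(state.phi, state.grid)
    return pre * state.psi * gx, pre * state.psi * gy


def _surface_tension_force_stable(
    state: PhaseFieldState, params: PhaseFieldParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient-equivalent CSF form used inside the solver.

    psi grad(phi) = grad(phi psi) - phi grad(psi): the solver applies
    f = -(lambda/eps^2) phi grad(psi) and books the exact difference
    (lambda/eps^2) phi psi into the pressure. In the bulk, where phi is
    nearly constant, this form is a near-pure gradient that the projection
    removes, so small-scale phi noise cannot pump momentum into the flow
    (with psi grad(phi) it can, and does). Returns (fx, fy, p_gauge) with
    p_physical = p_projection + p_gauge.
    """
    pre = params.lambda_mix / params.eps_pf**2
    gx, gy = gradient(state.psi, state.grid)
    gauge = pre * state.phi * state.psi
    return -pre * state.phi * gx, -pre * state.phi * gy, gauge


# ---------------------------------------------------------------------------
# Brinkman penalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Penalization:
    """A penalized region: velocity driven to (u_target, v_target)."""

    weight: np.ndarray  # in [0, 1]
    u_target: np.ndarray | float
    v_target: np.ndarray | float
    strength: float  # 1/s


def wall_penalization(
    grid: GridSpec, thickness_cells: int, strength: float = 1.0e7
) -> Penalization:
    """No-slip walls as stationary strips at the y-extremes of the box."""
    w = np.zeros(grid.shape)
    w[:, :thickness_cells] = 1.0
    w[:, -thickness_cells:] = 1.0
    return Penalization(weight=w, u_target=0.0, v_target=0.0, strength=strength)


@dataclass(frozen=True)
class NozzleModel:
    """A moving nozzle: solid obstacle plus air source at its tip.

    ``shape`` selects the penalized footprint: "straight" and "ball" are
    discs (diameter ``ball_diameter`` for the ball), "bent-horizontal-segment"
    is a capsule of length 3*diameter aligned with the motion -- the 2D
    stand-in for the horizontal segment of a bent nozzle. Air is exuded in
    a disc of the lumen diameter just behind the trailing edge, with the
    flow direction parallel but opposite to the nozzle motion.
    """

    shape: str  # "bent-horizontal-segment" | "ball" | "straight"
    diameter: float  # m, lumen diameter
    position: tuple[float, float]  # m
    velocity: tuple[float, float]  # m/s
    air_flow_rate: float  # m^3/s (negative = aspiration)
    ball_diameter: float | None = None
    penalization_strength: float = 1.0e7  # 1/s
    injection_setback: float = 1.0  # extra gap solid->source, in diameters
    mouth_side: int = 1  # +1: mouth trails the motion (printing);
    # -1: mouth leads (retracing a path to aspirate printed air back)

    def __post_init__(self) -> None:
        if self.shape not in ("bent-horizontal-segment", "ball", "straight"):
            raise ValueError(f"unknown nozzle shape {self.shape!r}")
        if self.diameter <= 0:
            raise ValueError("nozzle diameter must be positive")
        if self.shape == "ball" and (
            self.ball_diameter is None or self.ball_diameter <= 0
        ):
            raise ValueError("ball nozzle needs a positive ball_diameter")

    @property
    def dispense_speed(self) -> float:
        """Mean air speed in the lumen, |Q| / (pi d^2 / 4)  (m/s)."""
        return abs(self.air_flow_rate) / (np.pi * self.diameter**2 / 4.0)

    @property
    def area_rate_2d(self) -> float:
        """2D-equivalent air area rate (m^2/s): Q per depth (pi/4)*d.

        Signed; dividing the volumetric rate by the effective slab depth
        (pi/4)*d makes the 2D bookkeeping consistent with the lumen mean
        speed: q2d = dispense_speed * d.
        """
        return self.air_flow_rate / (np.pi * self.diameter / 4.0)

    def motion_direction(self) -> np.ndarray:
        vx, vy = self.velocity
        speed = float(np.hypot(vx, vy))
        if speed < 1e-300:
            return np.array([1.0, 0.0])
        return np.array([vx, vy]) / speed


def _disc_weight(
    grid: GridSpec,
    center: tuple[float, float],
    radius: float,
    smooth: float | None = None,
) -> np.ndarray:
    """Smoothed indicator of a disc, periodic-aware (default one-cell ramp)."""
    x, y = grid.cell_centers()
    dx0 = np.remainder(x - center[0] + grid.lx / 2, grid.lx) - grid.lx / 2
    dy0 = np.remainder(y - center[1] + grid.ly / 2, grid.ly) - grid.ly / 2
    dist = np.hypot(dx0, dy0)
    h = smooth if smooth is not None else max(grid.dx, grid.dy)
    return np.clip((radius - dist) / h + 0.5, 0.0, 1.0)


def _capsule_weight(
    grid: GridSpec,
    center: tuple[float, float],
    direction: np.ndarray,
    length: float,
    width: float,
) -> np.ndarray:
    """Smoothed capsule (segment of given length, rounded ends)."""
    x, y = grid.cell_centers()
    dx0 = np.remainder(x - center[0] + grid.lx / 2, grid.lx) - grid.lx / 2
    dy0 = np.remainder(y - center[1] + grid.ly / 2, grid.ly) - grid.ly / 2
    s = dx0 * direction[0] + dy0 * direction[1]
    s_cl = np.clip(s, -length / 2, length / 2)
    ax = dx0 - s_cl * direction[0]
    ay = dy0 - s_cl * direction[1]
    dist = np.hypot(ax, ay)
    h = max(grid.dx, grid.dy)
    return np.clip((width / 2 - dist) / h + 0.5, 0.0, 1.0)


@dataclass(frozen=True)
class NozzleForcing:
    """Solid penalization plus the air-injection footprint of a nozzle."""

    solid: Penalization
    injection_weight: np.ndarray
    injection_velocity: tuple[float, float]
    area_rate_2d: float  # signed m^2/s


def nozzle_forcing(nozzle: NozzleModel, grid: GridSpec) -> NozzleForcing:
    """Build the forcing masks for a nozzle at its current position.

    The solid footprint is driven to the nozzle velocity by Brinkman
    penalization. Air exudes through a lumen-sized mouth behind the
    trailing edge ("the direction of air flow is parallel but opposite to
    the nozzle motion"): the mouth is realized as a velocity divergence
    source of integral q2d in :func:`flow_step` -- air volume is created
    there and pushes the interface outward hydrodynamically -- while the
    caller keeps the mouth's phase saturated with :func:`inject_air`.
    Whether the inflated air body follows the nozzle or is left behind
    (bubble shedding vs. continuous channel) is then decided by the bath's
    rheology, not by the source kinematics.
    """
    x0, y0 = nozzle.position
    if not (0.0 <= x0 <= grid.lx and 0.0 <= y0 <= grid.ly):
        raise RuntimeError(
            f"nozzle left the domain: position ({x0:g}, {y0:g}) m outside "
            f"[0, {grid.lx:g}] x [0, {grid.ly:g}] m"
        )
    e = nozzle.motion_direction()
    if nozzle.shape == "ball":
        r_solid = nozzle.ball_diameter / 2.0
        solid_w = _disc_weight(grid, nozzle.position, r_solid)
        back = r_solid
    elif nozzle.shape == "bent-horizontal-segment":
        length = 3.0 * nozzle.diameter
        solid_w = _capsule_weight(
            grid, nozzle.position, e, length, nozzle.diameter
        )
        back = length / 2.0 + nozzle.diameter / 2.0
    else:  # straight
        r_solid = nozzle.diameter / 2.0
        solid_w = _disc_weight(grid, nozzle.position, r_solid)
        back = r_solid
    # footprint sized to the volume-conservation deposit width: a nozzle
    # moving at v while exuding the 2D area rate q2d lays a band of width
    # q2d / v, which the swept source disc must be able to saturate
    r_inj = nozzle.diameter / 2.0  # the lumen mouth
    setback = back + r_inj + nozzle.injection_setback * nozzle.diameter
    side = 1 if nozzle.mouth_side >= 0 else -1
    inj_center = (
        x0 - side * setback * e[0],
        y0 - side * setback * e[1],
    )
    # transition widened to ~ the interface scale so the mouth's phase clamp
    # has a diffuse rim the Cahn--Hilliard step can carry without ringing
    inj_w = _disc_weight(grid, inj_center, r_inj, smooth=2.5 * max(grid.dx, grid.dy))
    inj_w = inj_w * (1.0 - solid_w)  # never inject inside the solid
    u_air = (
        nozzle.velocity[0] - nozzle.dispense_speed * e[0],
        nozzle.velocity[1] - nozzle.dispense_speed * e[1],
    )
    return NozzleForcing(
        solid=Penalization(
            weight=solid_w,
            u_target=nozzle.velocity[0],
            v_target=nozzle.velocity[1],
            strength=nozzle.penalization_strength,
        ),
        injection_weight=inj_w,
        injection_velocity=u_air,
        area_rate_2d=nozzle.area_rate_2d,
    )


def nozzle_divergence_source(
    forcing: NozzleForcing, phi: np.ndarray | None, grid: GridSpec
) -> np.ndarray | None:
    """Velocity divergence field (1/s) realizing the air flow rate.

    A mass source of integral q2d at the lumen mouth, balanced by a sink
    spread over the gel (the bath accommodates the added volume as a
    quasi-2D slab would out of plane); aspiration is the sign-reversed
    pair. The matching phase-transport correction is +phi * S (see
    :func:`airprint.phasefield.cahn_hilliard_step`'s ``source``), which
    turns the conservative advection into pure transport of the bulk
    phases and books the created air exactly.
    """
    q2d = forcing.area_rate_2d
    if q2d == 0.0:
        return None
    w_m = forcing.injection_weight
    a = grid.cell_area
    if phi is None:
        w_gel = (1.0 - forcing.solid.weight) * (1.0 - w_m)
        m_tot = float(w_m.sum()) * a
        g_tot = float(w_gel.sum()) * a
        if m_tot <= 0 or g_tot <= 0:
            return None
        return q2d * (w_m / m_tot - w_gel / g_tot)
    # the lumen feeds the air body at the mouth: weight the source by the
    # local air fraction, and normalize mouth and sink by their phi-weighted
    # integrals so the phase creation rate integral(phi S)/2 is exactly q2d
    # (the +phi*S transport correction cancels any part acting on mixture)
    phi_c = np.clip(phi, -1.0, 1.0)
    w_air = w_m * 0.5 * (1.0 + phi_c)
    if float(w_air.sum()) <= 0.05 * float(w_m.sum()):
        w_air = w_m  # mouth lost contact with air: nucleation fallback
    w_gel = 0.5 * (1.0 - phi_c) * (1.0 - forcing.solid.weight) * (1.0 - w_m)
    denom_m = float((w_air * phi_c).sum()) * a
    denom_g = float((w_gel * phi_c).sum()) * a
    if denom_m <= 0.05 * float(w_air.sum()) * a or denom_g >= 0.0:
        m_tot = float(w_air.sum()) * a
        g_tot = float(w_gel.sum()) * a
        if m_tot <= 0 or g_tot <= 0:
            return None
        return q2d * (w_air / m_tot - w_gel / g_tot)
    return q2d * (w_air / denom_m + w_gel / denom_g)


def inject_air(
    phi: np.ndarray,
    weight: np.ndarray,
    area_increment: float,
    cell_area: float,
) -> tuple[np.ndarray, float]:
    """Add (or remove) exactly ``area_increment`` of air within a footprint.

    Positive increments push phi toward +1 inside the weighted region in
    proportion to the local deficit (1 - phi); negative increments
    (aspiration) pull phi toward -1 in proportion to (1 + phi). The change
    of integral (1+phi)/2 * cell_area equals the requested increment unless
    the footprint saturates, in which case the realized amount is returned.
    """
    if area_increment >= 0:
        capacity = float((weight * (1.0 - phi)).sum()) * cell_area / 2.0
        if capacity <= 0:
            return phi, 0.0
        alpha = min(1.0, area_increment / capacity)
        new_phi = phi + alpha * weight * (1.0 - phi)
        return new_phi, alpha * capacity
    capacity = float((weight * (1.0 + phi)).sum()) * cell_area / 2.0
    if capacity <= 0:
        return phi, 0.0
    alpha = min(1.0, -area_increment / capacity)
    new_phi = phi - alpha * weight * (1.0 + phi)
    return new_phi, -alpha * capacity


# ---------------------------------------------------------------------------
# Batched cyclic tridiagonal solver (Thomas + Sherman--Morrison)
# ---------------------------------------------------------------------------

def _thomas_numpy(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Solve non-cyclic tridiagonal systems batched along axis 1."""
    n = b.shape[0]
    cp = np.empty_like(b)
    dp = np.empty_like(d)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    x = np.empty_like(d)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


try:  # JIT-compiled solvers; the numpy fallbacks are numerically identical
    from numba import njit

    @njit(cache=True)
    def _thomas_jit(a, b, c, d):  # pragma: no cover - thin jit wrapper
        n, m = b.shape
        cp = np.empty((n, m))
        dp = np.empty((n, m))
        x = np.empty((n, m))
        for j in range(m):
            cp[0, j] = c[0, j] / b[0, j]
            dp[0, j] = d[0, j] / b[0, j]
        for i in range(1, n):
            for j in range(m):
                w = b[i, j] - a[i, j] * cp[i - 1, j]
                cp[i, j] = c[i, j] / w
                dp[i, j] = (d[i, j] - a[i, j] * dp[i - 1, j]) / w
        for j in range(m):
            x[n - 1, j] = dp[n - 1, j]
        for i in range(n - 2, -1, -1):
            for j in range(m):
                x[i, j] = dp[i, j] - cp[i, j] * x[i + 1, j]
        return x

    @njit(cache=True)
    def _cyclic_thomas_jit(a, b, c, d):  # pragma: no cover - jit
        # Sherman--Morrison with a single shared LU-style factorization
        n, m = b.shape
        cp = np.empty((n, m))
        y = np.empty((n, m))
        z = np.empty((n, m))
        bb0 = np.empty(m)
        bbn = np.empty(m)
        x = np.empty((n, m))
        for j in range(m):
            alpha = c[n - 1, j]
            beta = a[0, j]
            gamma = -b[0, j]
            bb0[j] = b[0, j] - gamma
            bbn[j] = b[n - 1, j] - alpha * beta / gamma
        # forward sweeps for rhs d (-> y) and spike u (-> z)
        for j in range(m):
            cp[0, j] = c[0, j] / bb0[j]
            y[0, j] = d[0, j] / bb0[j]
            z[0, j] = -b[0, j] / bb0[j]  # u[0] = gamma = -b[0]
        for i in range(1, n):
            for j in range(m):
                bi = bbn[j] if i == n - 1 else b[i, j]
                w = bi - a[i, j] * cp[i - 1, j]
                cp[i, j] = c[i, j] / w
                ui = c[n - 1, j] if i == n - 1 else 0.0  # u[n-1] = alpha
                y[i, j] = (d[i, j] - a[i, j] * y[i - 1, j]) / w
                z[i, j] = (ui - a[i, j] * z[i - 1, j]) / w
        for i in range(n - 2, -1, -1):
            for j in range(m):
                y[i, j] = y[i, j] - cp[i, j] * y[i + 1, j]
                z[i, j] = z[i, j] - cp[i, j] * z[i + 1, j]
        for j in range(m):
            gamma = -b[0, j]
            beta = a[0, j]
            vy = y[0, j] + beta / gamma * y[n - 1, j]
            vz = z[0, j] + beta / gamma * z[n - 1, j]
            fac = vy / (1.0 + vz)
            for i in range(n):
                x[i, j] = y[i, j] - z[i, j] * fac
        return x

    def _thomas(a, b, c, d):
        return _thomas_jit(
            np.ascontiguousarray(a),
            np.ascontiguousarray(b),
            np.ascontiguousarray(c),
            np.ascontiguousarray(d),
        )

    _HAVE_JIT = True
except Exception:  # pragma: no cover - numba unavailable
    _thomas = _thomas_numpy
    _HAVE_JIT = False


def _cyclic_thomas(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Solve cyclic tridiagonal systems batched along axis 1.

    a[0] couples row 0 to the last unknown, c[-1] couples the last row to
    the first (periodic wrap); Sherman--Morrison reduction to two ordinary
    tridiagonal solves.
    """
    if _HAVE_JIT:
        return _cyclic_thomas_jit(
            np.ascontiguousarray(a),
            np.ascontiguousarray(b),
            np.ascontiguousarray(c),
            np.ascontiguousarray(d),
        )
    n = b.shape[0]
    alpha = c[n - 1].copy()  # A[n-1, 0]
    beta = a[0].copy()  # A[0, n-1]
    gamma = -b[0]
    bb = b.copy()
    bb[0] = b[0] - gamma
    bb[n - 1] = b[n - 1] - alpha * beta / gamma
    y = _thomas(a, bb, c, d)
    u = np.zeros_like(d)
    u[0] = gamma
    u[n - 1] = alpha
    z = _thomas(a, bb, c, u)
    vy = y[0] + beta / gamma * y[n - 1]
    vz = z[0] + beta / gamma * z[n - 1]
    return y - z * (vy / (1.0 + vz))


def _implicit_diffuse_axis(
    rhs: np.ndarray,
    mu: np.ndarray,
    grid: GridSpec,
    rho0: float,
    dt: float,
    axis: int,
    diag_extra: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Solve (I + diag_extra - dt/rho0 * d/dx(mu d/dx)) x = rhs along an axis.

    ``diag_extra`` carries the implicit Brinkman penalization dt*K*chi.
    """
    h = grid.dx if axis == 0 else grid.dy
    if axis == 1:
        mu = mu.T
        rhs = rhs.T
        diag_extra = np.asarray(diag_extra).T if np.ndim(diag_extra) else diag_extra
    mu_f = 0.5 * (mu + np.roll(mu, -1, axis=0))  # face i+1/2
    r = dt / (rho0 * h * h)
    c = -r * mu_f
    a = np.roll(c, 1, axis=0)  # -r * mu_{i-1/2}
    b = 1.0 - a - c + diag_extra
    x = _cyclic_thomas(a, b, c, rhs)
    return x.T if axis == 1 else x


def _explicit_diffuse_axis(
    vel: np.ndarray, mu: np.ndarray, grid: GridSpec, rho0: float, axis: int
) -> np.ndarray:
    """(1/rho0) d/dx(mu d/dx vel) along one periodic axis."""
    h = grid.dx if axis == 0 else grid.dy
    mu_f = 0.5 * (mu + np.roll(mu, -1, axis=axis))
    dvel = np.roll(vel, -1, axis=axis) - vel
    flux = mu_f * dvel / h
    return (flux - np.roll(flux, 1, axis=axis)) / (h * rho0)


# ---------------------------------------------------------------------------
# Advection, projection, time-step limits
# ---------------------------------------------------------------------------

def _upwind_advect(
    f: np.ndarray, u: np.ndarray, v: np.ndarray, grid: GridSpec
) -> np.ndarray:
    """First-order upwind (u.grad) f on the periodic box."""
    fx_m = (f - np.roll(f, 1, axis=0)) / grid.dx
    fx_p = (np.roll(f, -1, axis=0) - f) / grid.dx
    fy_m = (f - np.roll(f, 1, axis=1)) / grid.dy
    fy_p = (np.roll(f, -1, axis=1) - f) / grid.dy
    return u * np.where(u > 0, fx_m, fx_p) + v * np.where(v > 0, fy_m, fy_p)


def _wavenumbers(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    # Nyquist modes zeroed: spectral differentiation of a real field has no
    # consistent sign there, so they carry no divergence by convention
    kx = 2.0 * np.pi * sfft.fftfreq(grid.nx, d=grid.dx)
    ky = 2.0 * np.pi * sfft.fftfreq(grid.ny, d=grid.dy)
    if grid.nx % 2 == 0:
        kx[grid.nx // 2] = 0.0
    if grid.ny % 2 == 0:
        ky[grid.ny // 2] = 0.0
    return kx[:, None], ky[None, :]


def _wavenumbers_r(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    kx = 2.0 * np.pi * sfft.fftfreq(grid.nx, d=grid.dx)
    ky = 2.0 * np.pi * sfft.rfftfreq(grid.ny, d=grid.dy)
    if grid.nx % 2 == 0:
        kx[grid.nx // 2] = 0.0
    if grid.ny % 2 == 0:
        ky[-1] = 0.0
    return kx[:, None], ky[None, :]


def _project(
    u: np.ndarray,
    v: np.ndarray,
    grid: GridSpec,
    rho0: float,
    dt: float,
    div_source: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Spectral projection onto div u = S; returns (u, v, p, rms residual).

    ``div_source`` S (1/s) realizes volumetric air injection as a mass
    source; it must integrate to ~zero over the periodic box (the mean mode
    is discarded).
    """
    kx, ky = _wavenumbers_r(grid)
    uh = sfft.rfft2(u)
    vh = sfft.rfft2(v)
    div = 1j * (kx * uh + ky * vh)
    if div_source is not None:
        div = div - sfft.rfft2(div_source)
    k2 = kx**2 + ky**2
    zero = k2 == 0.0  # mean mode and the zeroed Nyquist lines
    k2 = np.where(zero, 1.0, k2)
    ph = (rho0 / dt) * div / (-k2)
    ph[zero] = 0.0
    uh -= (dt / rho0) * 1j * kx * ph
    vh -= (dt / rho0) * 1j * ky * ph
    div_after = 1j * (kx * uh + ky * vh)
    shape = grid.shape
    u_new = sfft.irfft2(uh, s=shape)
    v_new = sfft.irfft2(vh, s=shape)
    p = sfft.irfft2(ph, s=shape)
    # Parseval RMS of the residual divergence (zero to round-off by design)
    w = np.full(div_after.shape, 2.0)
    w[:, 0] = 1.0
    if grid.ny % 2 == 0:
        w[:, -1] = 1.0
    n_tot = grid.nx * grid.ny
    residual = float(np.sqrt((w * np.abs(div_after) ** 2).sum()) / n_tot)
    return u_new, v_new, p, residual


def flow_dt_limit(
    flow: FlowState,
    params: PhaseFieldParams | None,
    rho0: float,
    cfl: float = 0.4,
) -> float:
    """Stable step: advective CFL and the explicit-CSF capillary limit."""
    g = flow.grid
    speed = max(
        float(np.abs(flow.u).max()) / g.dx + float(np.abs(flow.v).max()) / g.dy,
        1e-300,
    )
    dt = cfl / speed
    if params is not None:
        h = min(g.dx, g.dy)
        dt_cap = np.sqrt(rho0 * h**3 / (4.0 * np.pi * params.sigma))
        dt = min(dt, dt_cap)
    return dt


def flow_step(
    flow: FlowState,
    phi_state: PhaseFieldState | None,
    props: FluidProperties,
    params: PhaseFieldParams | None,
    nozzle: NozzleForcing | None,
    dt: float,
    *,
    stokes: bool = False,
    gravity: tuple[float, float] = (0.0, 0.0),
    body_force: tuple[float | np.ndarray, float | np.ndarray] = (0.0, 0.0),
    penalizations: Sequence[Penalization] = (),
    enforce_cfl: bool = True,
    div_source: np.ndarray | None = None,
    use_nozzle_source: bool = True,
) -> FlowState:
    """Advance the velocity/pressure by one projection step.

    phi_state = None treats the whole box as gel; nozzle forcing must be
    built with :func:`nozzle_forcing` at the current nozzle position (air
    injection itself is applied to the phase field by the caller through
    :func:`inject_air`). Raises if dt exceeds the advective/capillary
    stability bound (Stokes mode drops the advective bound).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = flow.grid
    _require_periodic(grid)
    rho0 = props.rho_gel  # reference density of the projection

    if enforce_cfl:
        limit = flow_dt_limit(flow, params, rho0, cfl=0.9 if stokes else 0.45)
        if dt > limit * 1.0000001:
            raise ValueError(
                f"dt={dt:g} exceeds the stability bound {limit:g} "
                "(advective CFL / explicit capillary forcing)"
            )

    # material fields (filtered shear rate: see _box3)
    gamma_dot = _shear_rate_filtered(flow)
    if phi_state is not None:
        mu = mixture_viscosity(phi_state.phi, gamma_dot, props)
    else:
        mu = np.asarray(
            effective_viscosity(gamma_dot, props.gel_hb, mu_max=props.mu_cap)
        )
        mu = np.broadcast_to(mu, grid.shape).copy()

    # explicit accelerations
    ax = np.zeros(grid.shape)
    ay = np.zeros(grid.shape)
    if not stokes:
        ax -= _upwind_advect(flow.u, flow.u, flow.v, grid)
        ay -= _upwind_advect(flow.v, flow.u, flow.v, grid)
    p_gauge = None
    if phi_state is not None and params is not None:
        fx, fy, p_gauge = _surface_tension_force_stable(phi_state, params)
        ax += fx / rho0
        ay += fy / rho0
    bx, by = body_force
    ax += np.asarray(bx) / rho0
    ay += np.asarray(by) / rho0
    if gravity != (0.0, 0.0) and phi_state is not None:
        from .phasefield import volume_fractions

        f_air, f_gel = volume_fractions(phi_state.phi)
        rho = f_air * props.rho_air + f_gel * props.rho_gel
        ax += (rho - rho0) / rho0 * gravity[0]
        ay += (rho - rho0) / rho0 * gravity[1]

    if (
        div_source is None
        and use_nozzle_source
        and nozzle is not None
        and nozzle.area_rate_2d != 0.0
    ):
        div_source = nozzle_divergence_source(
            nozzle, phi_state.phi if phi_state is not None else None, grid
        )

    # Brinkman penalization, taken implicitly inside the first ADI solve so
    # the steady state satisfies the monolithic balance (no splitting slip)
    pens = list(penalizations)
    if nozzle is not None:
        pens.append(nozzle.solid)
    pen_diag = np.zeros(grid.shape)
    pen_u = np.zeros(grid.shape)
    pen_v = np.zeros(grid.shape)
    for pen in pens:
        k = dt * pen.strength * pen.weight
        pen_diag += k
        pen_u += k * pen.u_target
        pen_v += k * pen.v_target

    # Douglas ADI: implicit variable-viscosity diffusion per direction
    def diffuse(vel: np.ndarray, accel: np.ndarray, pen_rhs: np.ndarray) -> np.ndarray:
        ay_expl = _explicit_diffuse_axis(vel, mu, grid, rho0, axis=1)
        rhs1 = vel + dt * (accel + ay_expl) + pen_rhs
        v1 = _implicit_diffuse_axis(
            rhs1, mu, grid, rho0, dt, axis=0, diag_extra=pen_diag
        )
        rhs2 = v1 - dt * ay_expl
        return _implicit_diffuse_axis(rhs2, mu, grid, rho0, dt, axis=1)

    u = diffuse(flow.u, ax, pen_u)
    v = diffuse(flow.v, ay, pen_v)

    u, v, p, residual = _project(u, v, grid, rho0, dt, div_source=div_source)
    if p_gauge is not None:
        p = p + p_gauge  # report the physical pressure (Laplace jump lives here)
    return FlowState(
        u=u, v=v, p=p, time=flow.time + dt, grid=grid,
        divergence_residual=residual,
    )


def max_divergence(flow: FlowState) -> float:
    """Max |div u| measured with the spectral divergence (1/s)."""
    kx, ky = _wavenumbers(flow.grid)
    div = 1j * (kx * sfft.fft2(flow.u) + ky * sfft.fft2(flow.v))
    return float(np.abs(sfft.ifft2(div)).max())
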