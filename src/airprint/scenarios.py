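"""Virtual printing experiments and the closed-form printing theory.

The printability number PN is the ratio of the air dispense speed (mean
lumen speed Q / (pi d^2/4)) to the nozzle translation speed; by volume
conservation an air channel printed at flow rate Q and nozzle speed v has
the theoretical diameter D = sqrt(4 Q / (pi v)) = d sqrt(PN). A printed
channel of radius R survives surface tension when the plastocapillary
number Y = tau_y R / sigma exceeds a critical value; otherwise it
collapses into bubbles.

The simulation scenarios reproduce, at desk scale, the canonical virtual
experiments: a nozzle translating through the bath while exuding air
(bubble formation in weakly yielding baths, uniform channels in strongly
yielding ones), printability-number sweeps, free relaxation of air shapes,
aspiration of printed air, and the disturbance that printing a neighboring
channel inflicts on an existing one.

All simulations are 2D planar. The 2D analog of the volume-conservation
channel law is width w = PN * d (width ratio in 2D equals the
cross-section *area* ratio (D/d)^2 = PN in 3D), so a measured 2D width is
reported alongside its 3D-equivalent diameter D_eq = d * sqrt(w / d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    AirBody,
    channel_uniformity,
    circularity,
    extract_air_bodies,
    metrics_dataframe,
)
from .hydrodynamics import (
    FluidProperties,
    FlowState,
    NozzleModel,
    flow_dt_limit,
    flow_step,
    inject_air,
    nozzle_divergence_source,
    nozzle_forcing,
    quiescent_flow,
    wall_penalization,
)
from .phasefield import (
    GridSpec,
    PhaseFieldParams,
    PhaseFieldState,
    cahn_hilliard_step,
    chemical_potential,
)
from .rheology import DEFAULT_Y_CRIT, MaterialFormulation, yield_capillary_number

__all__ = [
    "PrintJob",
    "PrintResult",
    "SweepResult",
    "printability_number",
    "theoretical_channel_diameter",
    "channel_stability_criterion",
    "simulate_print",
    "pn_sweep",
    "run_relaxation",
    "run_neighbor_disturbance",
    "run_aspiration",
    "default_print_job",
    "channel_phase",
    "disc_phase",
    "rectangle_phase",
    "flow_rate_for_pn",
]


# ---------------------------------------------------------------------------
# Closed-form printing theory
# ---------------------------------------------------------------------------

def printability_number(Q: float, nozzle_diameter: float, nozzle_speed: float) -> float:
    """PN = (air dispense speed) / (nozzle speed) = Q / (pi d^2/4) / v."""
    if Q <= 0 or nozzle_diameter <= 0 or nozzle_speed <= 0:
        raise ValueError("Q, nozzle_diameter and nozzle_speed must be positive")
    dispense = Q / (math.pi * nozzle_diameter**2 / 4.0)
    return dispense / nozzle_speed


def flow_rate_for_pn(pn: float, nozzle_diameter: float, nozzle_speed: float) -> float:
    """Invert the PN definition: Q = PN * v * pi d^2 / 4 (m^3/s)."""
    if pn <= 0 or nozzle_diameter <= 0 or nozzle_speed <= 0:
        raise ValueError("pn, nozzle_diameter and nozzle_speed must be positive")
    return pn * nozzle_speed * math.pi * nozzle_diameter**2 / 4.0


def theoretical_channel_diameter(Q: float, nozzle_speed: float) -> float:
    """Volume-conservation channel diameter D = sqrt(4 Q / (pi v)) (m)."""
    if Q <= 0 or nozzle_speed <= 0:
        raise ValueError("Q and nozzle_speed must be positive")
    return math.sqrt(4.0 * Q / (math.pi * nozzle_speed))


def channel_stability_criterion(
    mat: MaterialFormulation,
    R: float,
    sigma: float | None = None,
    y_crit: float = DEFAULT_Y_CRIT,
) -> str:
    """Predict 'stable-channel' (Y >= y_crit) or 'collapses-to-bubbles'."""
    sigma = mat.surface_tension_vs_air if sigma is None else sigma
    if mat.hb.tau_y <= 0:
        return "collapses-to-bubbles"
    y = yield_capillary_number(mat.hb.tau_y, sigma, R)
    return "stable-channel" if y >= y_crit else "collapses-to-bubbles"


# ---------------------------------------------------------------------------
# Job definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintJob:
    """One virtual printing experiment.

    path: waypoints [(x, y, speed), ...]; the nozzle moves between
    consecutive waypoints at the speed attached to the segment's end point.
    ``post_relax_time`` continues the simulation with the nozzle removed
    after the path completes, letting the bath respond.
    """

    material: MaterialFormulation
    nozzle: NozzleModel
    path: tuple[tuple[float, float, float], ...]
    grid: GridSpec
    phase_params: PhaseFieldParams
    props: FluidProperties
    post_relax_time: float = 0.0
    dt: float | None = None  # None = automatic from stability bounds
    seed: int = 0
    output_every: int = 0  # snapshot cadence in steps; 0 = none
    snapshot_dir: str | None = None
    stokes: bool = True  # print flows are creeping; inertia available on request
    wall_cells: int = 3  # container walls (penalized strips) at the y edges
    wall_cells_x: int = 0  # optional container walls at the x edges
    gravity: tuple[float, float] = (0.0, 0.0)  # m/s^2; (0, -9.81) = side view

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError("path needs at least two waypoints")
        margin = 2.0 * self.nozzle.diameter
        for x, y, speed in self.path:
            if speed <= 0:
                raise ValueError("path speeds must be positive")
            if not (
                margin <= x <= self.grid.lx - margin
                and margin <= y <= self.grid.ly - margin
            ):
                raise ValueError(
                    "path must stay inside the domain with a margin of "
                    "two nozzle diameters"
                )


@dataclass
class PrintResult:
    """Outputs of one virtual print: final fields, bodies, per-step log."""

    job: PrintJob
    phase: PhaseFieldState
    flow: FlowState
    bodies: list[AirBody]
    log: pd.DataFrame
    injected_area: float  # m^2 actually injected
    sweep_row: dict
    snapshots: list[str] = field(default_factory=list)

    def body_metrics(self) -> pd.DataFrame:
        return metrics_dataframe(self.bodies)


@dataclass
class SweepResult:
    """Table of measured channel geometry across an independent variable."""

    variable: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.shape[0] < 2:
            raise ValueError("a sweep needs at least two rows")
        vals = self.table[self.variable].to_numpy()
        if (np.diff(vals) <= 0).any():
            raise ValueError("sweep rows must be sorted by the swept variable")


def default_print_job(
    material: MaterialFormulation,
    pn: float = 1.0,
    nozzle_diameter: float = 5.0e-4,
    nozzle_speed: float = 0.1,
    cells: tuple[int, int] = (256, 128),
    cells_per_diameter: int = 8,
    seed: int = 0,
    post_relax_time: float | None = None,
    path_y_frac: float = 0.5,
    **overrides,
) -> PrintJob:
    """Standard desk-scale print: straight path across a periodic box.

    The box spans cells/cells_per_diameter nozzle diameters (32 x 16 at the
    defaults) with the path along the midline, 100 mm/s nozzle speed, and
    the air flow rate set from the requested printability number.
    """
    nx, ny = cells
    dx = nozzle_diameter / cells_per_diameter
    grid = GridSpec(nx=nx, ny=ny, dx=dx, dy=dx)
    q = flow_rate_for_pn(pn, nozzle_diameter, nozzle_speed)
    y_path = path_y_frac * grid.ly
    nozzle = NozzleModel(
        shape="bent-horizontal-segment",
        diameter=nozzle_diameter,
        position=(2.5 * nozzle_diameter, y_path),
        velocity=(nozzle_speed, 0.0),
        air_flow_rate=q,
    )
    # the mouth trails the solid by (capsule half length + lumen + setback);
    # start with the mouth just off the left container wall so the channel's
    # tail end is anchored there (as when printing from the vessel boundary:
    # a free tail end lets the whole channel contract axially and fatten)
    mouth_setback = (
        1.5 * nozzle_diameter + 0.5 * nozzle_diameter
        + 0.5 * nozzle_diameter
        + nozzle.injection_setback * nozzle_diameter
    )
    wall_cells_x = 3
    x_start = mouth_setback + (wall_cells_x + 2) * dx
    params = PhaseFieldParams(
        sigma=material.surface_tension_vs_air, eps_pf=2.0 * dx, chi_mob=0.5
    )
    props = FluidProperties(
        rho_gel=material.density,
        gel_hb=material.hb,
        mu_cap=1.0e4,  # solver cap; far above any sheared-gel viscosity here
        mu_air=0.05,  # numerical air viscosity: caps the phase contrast;
        # the dynamics are gel-dominated (creeping flow), so the air
        # interior only needs to remain passive and well-conditioned
    )
    if post_relax_time is None:
        # a few capillary response times of the printed feature
        post_relax_time = 0.4 * grid.lx / nozzle_speed
    nozzle = replace(nozzle, position=(x_start, y_path))
    job = PrintJob(
        material=material,
        nozzle=nozzle,
        path=(
            (x_start, y_path, nozzle_speed),
            (grid.lx - 2.5 * nozzle_diameter, y_path, nozzle_speed),
        ),
        grid=grid,
        phase_params=params,
        props=props,
        post_relax_time=post_relax_time,
        seed=seed,
        wall_cells_x=wall_cells_x,
    )
    return replace(job, **overrides) if overrides else job


# ---------------------------------------------------------------------------
# Initial phase fields
# ---------------------------------------------------------------------------

def _tanh(signed_distance: np.ndarray, eps: float) -> np.ndarray:
    """phi = +1 where signed distance < 0 (inside = air)."""
    return np.tanh(-signed_distance / (np.sqrt(2.0) * eps))


def disc_phase(
    grid: GridSpec, center: tuple[float, float], radius: float, eps: float
) -> np.ndarray:
    x, y = grid.cell_centers()
    d = np.hypot(x - center[0], y - center[1]) - radius
    return _tanh(d, eps)


def rectangle_phase(
    grid: GridSpec,
    center: tuple[float, float],
    width: float,
    height: float,
    eps: float,
) -> np.ndarray:
    x, y = grid.cell_centers()
    ax = np.abs(x - center[0]) - width / 2.0
    ay = np.abs(y - center[1]) - height / 2.0
    outside = np.hypot(np.maximum(ax, 0.0), np.maximum(ay, 0.0))
    inside = np.minimum(np.maximum(ax, ay), 0.0)
    return _tanh(outside + inside, eps)


def channel_phase(
    grid: GridSpec,
    y_center: float,
    width: float,
    eps: float,
    x_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """A straight air channel along x (full-domain strip if x_range=None)."""
    if x_range is None:
        x, y = grid.cell_centers()
        return _tanh(np.abs(y - y_center) - width / 2.0, eps)
    x0, x1 = x_range
    return rectangle_phase(
        grid, ((x0 + x1) / 2.0, y_center), x1 - x0, width, eps
    )


# ---------------------------------------------------------------------------
# The core loop
# ---------------------------------------------------------------------------

def _path_position(
    path: tuple[tuple[float, float, float], ...], t: float
) -> tuple[tuple[float, float], tuple[float, float], bool]:
    """Nozzle position and velocity at time t along the waypoint path."""
    t_seg = 0.0
    for (x0, y0, _), (x1, y1, speed) in zip(path[:-1], path[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        dur = seg_len / speed
        if t <= t_seg + dur or dur == 0.0:
            s = (t - t_seg) / dur if dur > 0 else 1.0
            ex, ey = (x1 - x0) / seg_len, (y1 - y0) / seg_len
            return (
                (x0 + s * (x1 - x0), y0 + s * (y1 - y0)),
                (speed * ex, speed * ey),
                False,
            )
        t_seg += dur
    x1, y1, speed = path[-1]
    return (x1, y1), (0.0, 0.0), True


def path_duration(path: tuple[tuple[float, float, float], ...]) -> float:
    total = 0.0
    for (x0, y0, _), (x1, y1, speed) in zip(path[:-1], path[1:]):
        total += math.hypot(x1 - x0, y1 - y0) / speed
    return total


def _auto_dt(job: PrintJob) -> float:
    """Fixed step from the capillary bound and the path-speed CFL."""
    g = job.grid
    h = min(g.dx, g.dy)
    rho0 = job.props.rho_gel
    dt_cap = math.sqrt(rho0 * h**3 / (4.0 * math.pi * job.phase_params.sigma))
    speeds = [w[2] for w in job.path] + [job.nozzle.dispense_speed]
    dt_adv = 0.25 * h / max(max(speeds), 1e-12)
    return 0.8 * min(dt_cap, dt_adv)


def simulate_print(
    job: PrintJob,
    initial_phi: np.ndarray | None = None,
    collect: bool = False,
) -> PrintResult:
    """Run one virtual print and measure the resulting air bodies.

    The nozzle follows the waypoint path while exuding (or aspirating) air;
    when the path completes it is removed and the bath relaxes for
    ``post_relax_time``. The per-step log records time, divergence
    residual, total air area and injected air; with ``collect=True``
    snapshot states are kept in memory (``output_every`` cadence) instead
    of / in addition to being written to ``snapshot_dir``.
    """
    grid = job.grid
    params = job.phase_params
    params.check_resolution(grid)
    if initial_phi is None:
        phi = -np.ones(grid.shape)
    else:
        phi = np.array(initial_phi, dtype=float)
    state = PhaseFieldState(
        phi=phi, psi=chemical_potential(phi, grid, params.eps_pf), time=0.0,
        grid=grid,
    )
    flow = quiescent_flow(grid)
    dt0 = job.dt if job.dt is not None else _auto_dt(job)
    t_path = path_duration(job.path)
    t_end = t_path + job.post_relax_time

    walls = (
        [wall_penalization(grid, job.wall_cells)] if job.wall_cells > 0 else []
    )
    if job.wall_cells_x > 0:
        from .hydrodynamics import Penalization

        wx = np.zeros(grid.shape)
        wx[: job.wall_cells_x, :] = 1.0
        wx[-job.wall_cells_x :, :] = 1.0
        walls.append(
            Penalization(weight=wx, u_target=0.0, v_target=0.0, strength=1.0e7)
        )
    injected = 0.0
    rows = []
    snapshots: list[str] = []
    kept_states: list[PhaseFieldState] = []
    q2d = job.nozzle.area_rate_2d

    if q2d > 0.0 and initial_phi is None:
        # prime the source footprint with air ("nozzle full of air"), so the
        # deposit starts at the path start instead of after a fill-up lag
        pos0, vel0, _ = _path_position(job.path, 0.0)
        f0 = nozzle_forcing(
            replace(job.nozzle, position=pos0, velocity=vel0), grid
        )
        cap = float((f0.injection_weight * (1.0 - state.phi)).sum()) * (
            grid.cell_area / 2.0
        )
        state.phi, added = inject_air(
            state.phi, f0.injection_weight, cap, grid.cell_area
        )
        state.psi = chemical_potential(state.phi, grid, params.eps_pf)
        injected += added
        # the primed air is the nozzle's dead volume: hold the source off
        # until the flow rate has nominally delivered it, so the total
        # deposited volume stays q2d * t
        t_source_on = added / q2d if q2d > 0 else 0.0
    else:
        t_source_on = 0.0

    from .phasefield import advective_dt_limit

    step = 0
    t = 0.0
    _forcing_cache = None
    while t < t_end:
        # adaptive step: back off when transient speeds spike above the
        # bound (safety margin applies to the velocity-dependent part only)
        speed = max(
            float(np.abs(flow.u).max()) / grid.dx
            + float(np.abs(flow.v).max()) / grid.dy,
            1e-300,
        )
        dt = min(dt0, 0.6 * 0.45 / speed)
        on_path = t < t_path
        forcing = None
        if on_path:
            pos, vel, _ = _path_position(job.path, t)
            # rebuilding the penalization masks is costly; the nozzle moves
            # a fraction of a cell per step, so refresh on ~1/4-cell motion
            if (
                _forcing_cache is None
                or _forcing_cache[1] != vel
                or math.hypot(pos[0] - _forcing_cache[0][0],
                              pos[1] - _forcing_cache[0][1]) > 0.25 * grid.dx
            ):
                nozzle = replace(job.nozzle, position=pos, velocity=vel)
                _forcing_cache = (pos, vel, nozzle_forcing(nozzle, grid))
            forcing = _forcing_cache[2]
        # volume enters through the divergence source; +phi*S turns the
        # conservative advection into pure transport of the bulk phases and
        # books the created air exactly; the same source field drives the
        # flow and the phase step so the two stay consistent
        source_active = on_path and q2d != 0.0 and t >= t_source_on
        s_field = (
            nozzle_divergence_source(forcing, state.phi, grid)
            if source_active
            else None
        )
        for _attempt in range(6):
            flow_new = flow_step(
                flow, state, job.props, params, forcing, dt,
                stokes=job.stokes, penalizations=walls, enforce_cfl=False,
                gravity=job.gravity, div_source=s_field,
                use_nozzle_source=False,
            )
            # the phase field is advected by the *new* velocity: make sure
            # the step also satisfies its CFL bound, else retry smaller
            if dt <= advective_dt_limit(flow_new.u, flow_new.v, grid):
                break
            dt *= 0.5
        flow = flow_new
        ch_source = None
        if source_active:
            if s_field is not None:
                ch_source = state.phi * s_field
                injected += float(ch_source.sum()) * grid.cell_area * dt / 2.0
            # the mouth clamp only nucleates fresh air (or drains it under
            # aspiration) through shedding events
            w = forcing.injection_weight
            w_tot = float(w.sum())
            mouth_air = float((w * (1.0 + state.phi)).sum()) / (2.0 * w_tot)
            area = 0.0
            if q2d > 0 and mouth_air < 0.5:
                # mouth lost contact with air (a body was shed): nucleate
                deficit = float((w * (1.0 - state.phi)).sum()) * grid.cell_area / 2.0
                area = min(deficit, 2.0 * q2d * dt)
            if area != 0.0:
                state.phi, added = inject_air(state.phi, w, area, grid.cell_area)
                state.psi = chemical_potential(state.phi, grid, params.eps_pf)
                injected += added
        state = cahn_hilliard_step(
            state, (flow.u, flow.v), params, dt, source=ch_source
        )
        t += dt
        step += 1
        if job.output_every and step % job.output_every == 0:
            from .phasefield import free_energy

            rows.append(
                {
                    "time_s": state.time,
                    "divergence_residual": flow.divergence_residual,
                    "air_area_m2": state.air_area(),
                    "injected_area_m2": injected,
                    "max_speed_m_s": float(
                        np.hypot(flow.u, flow.v).max()
                    ),
                    "free_energy_J": free_energy(state, params),
                }
            )
            if collect:
                kept_states.append(
                    PhaseFieldState(
                        phi=state.phi.copy(), psi=state.psi.copy(),
                        time=state.time, grid=grid,
                    )
                )
            if job.snapshot_dir:
                from .phasefield import save_snapshot

                p = Path(job.snapshot_dir) / f"snap_{step + 1:07d}.h5"
                save_snapshot(
                    p, state, params,
                    extra_fields={"u": flow.u, "v": flow.v, "p": flow.p},
                    attrs={"seed": job.seed, "scheme": "semi-implicit-CH/ADI-flow"},
                )
                snapshots.append(str(p))

    bodies = extract_air_bodies(state.phi, grid)
    sweep_row = _sweep_row(job, bodies, t_path)
    result = PrintResult(
        job=job,
        phase=state,
        flow=flow,
        bodies=bodies,
        log=pd.DataFrame(rows),
        injected_area=injected,
        sweep_row=sweep_row,
        snapshots=snapshots,
    )
    if collect:
        result.snapshots = snapshots
        result.kept_states = kept_states  # type: ignore[attr-defined]
    return result


def _sweep_row(job: PrintJob, bodies: list[AirBody], t_path: float) -> dict:
    d = job.nozzle.diameter
    v = max(w[2] for w in job.path)
    q = job.nozzle.air_flow_rate
    pn = printability_number(q, d, v) if q > 0 else 0.0
    path_len = sum(
        math.hypot(x1 - x0, y1 - y0)
        for (x0, y0, _), (x1, y1, _) in zip(job.path[:-1], job.path[1:])
    )
    row = {
        "pn": pn,
        "flow_rate_m3_s": q,
        "nozzle_speed_m_s": v,
        "body_count": len(bodies),
        "channel_width_m": np.nan,
        "equivalent_diameter_m": np.nan,
        "uniformity_cv": np.nan,
        "span_fraction": 0.0,
        "stable_channel": False,
    }
    if not bodies:
        return row
    main = bodies[0]
    w = main.median_diameter
    row["channel_width_m"] = w
    row["equivalent_diameter_m"] = d * math.sqrt(max(w, 0.0) / d)
    span = (main.bbox[2] - main.bbox[0]) / max(path_len, 1e-300)
    row["span_fraction"] = float(span)
    if main.elongation >= 2.0:
        try:
            row["uniformity_cv"] = channel_uniformity(main)
        except ValueError:
            pass
    row["stable_channel"] = bool(
        len(bodies) == 1
        and span >= 0.8
        and np.isfinite(row["uniformity_cv"])
        and row["uniformity_cv"] <= 0.2
    )
    return row


# ---------------------------------------------------------------------------
# Scenario wrappers
# ---------------------------------------------------------------------------

def pn_sweep(
    material: MaterialFormulation,
    pn_values: tuple[float, ...] = (1.0, 2.0, 4.0),
    mode: str = "flow-rate",
    **job_kwargs,
) -> SweepResult:
    """Print at several printability numbers and measure channel diameters.

    ``mode`` selects whether PN is varied through the air flow rate at
    fixed nozzle speed ("flow-rate") or through the nozzle speed at fixed
    flow rate ("speed").
    """
    if mode not in ("flow-rate", "speed"):
        raise ValueError("mode must be 'flow-rate' or 'speed'")
    rows = []
    base_speed = job_kwargs.pop("nozzle_speed", 0.1)
    for pn in sorted(pn_values):
        if mode == "flow-rate":
            job = default_print_job(
                material, pn=pn, nozzle_speed=base_speed, **job_kwargs
            )
        else:
            # keep Q of PN=1 at the base speed; slow the nozzle down
            job = default_print_job(
                material, pn=pn, nozzle_speed=base_speed / pn, **job_kwargs
            )
            q_fixed = flow_rate_for_pn(1.0, job.nozzle.diameter, base_speed)
            job = replace(
                job, nozzle=replace(job.nozzle, air_flow_rate=q_fixed)
            )
        res = simulate_print(job)
        row = dict(res.sweep_row)
        row["theoretical_diameter_m"] = job.nozzle.diameter * math.sqrt(row["pn"])
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("pn").reset_index(drop=True)
    return SweepResult(variable="pn", table=table)


def run_relaxation(
    initial_phi: np.ndarray,
    material: MaterialFormulation,
    T: float,
    grid: GridSpec,
    phase_params: PhaseFieldParams | None = None,
    dt: float | None = None,
    record_every: int = 25,
    mu_cap: float = 1.0e4,
    stokes: bool = True,
) -> pd.DataFrame:
    """Free relaxation of an air shape under surface tension vs. yield stress.

    Returns a time series of the largest body's circularity, axes and the
    total air area. In a weakly yielding bath the shape rounds up toward a
    disc; a strongly yielding bath arrests the relaxation.
    """
    params = phase_params or PhaseFieldParams(
        sigma=material.surface_tension_vs_air, eps_pf=2.0 * grid.dx
    )
    props = FluidProperties(
        rho_gel=material.density, gel_hb=material.hb, mu_cap=mu_cap
    )
    state = PhaseFieldState(
        phi=np.array(initial_phi, dtype=float),
        psi=chemical_potential(initial_phi, grid, params.eps_pf),
        time=0.0,
        grid=grid,
    )
    flow = quiescent_flow(grid)
    if dt is None:
        h = min(grid.dx, grid.dy)
        dt = 0.8 * math.sqrt(props.rho_gel * h**3 / (4.0 * math.pi * params.sigma))
    dt0 = dt
    n_steps = int(math.ceil(T / dt0))
    rows = []

    def record() -> None:
        bodies = extract_air_bodies(state.phi, grid)
        if not bodies:
            return
        b = bodies[0]
        rows.append(
            {
                "time_s": state.time,
                "circularity": circularity(b),
                "axis_major_m": b.axis_major,
                "axis_minor_m": b.axis_minor,
                "air_area_m2": state.air_area(),
                "body_count": len(bodies),
            }
        )

    from .phasefield import advective_dt_limit

    record()
    t, step = 0.0, 0
    while t < T:
        dt = min(dt0, 0.6 * flow_dt_limit(flow, params, props.rho_gel))
        for _attempt in range(6):
            flow_new = flow_step(
                flow, state, props, params, None, dt, stokes=stokes,
                enforce_cfl=False,
            )
            if dt <= advective_dt_limit(flow_new.u, flow_new.v, grid):
                break
            dt *= 0.5
        flow = flow_new
        state = cahn_hilliard_step(state, (flow.u, flow.v), params, dt)
        t += dt
        step += 1
        if step % record_every == 0 or t >= T:
            record()
    return pd.DataFrame(rows)


def run_neighbor_disturbance(
    job: PrintJob,
    gap: float,
    channel_width: float | None = None,
    relax_factor: float = 5.0,
    pass_fraction: float = 0.55,
    disturb_with_printing: bool = False,
) -> dict:
    """Pass a nozzle next to an existing channel and measure its deformation.

    By default the disturbing pass exudes no air: the measured quantity is
    the permanent mechanical deformation inflicted by the moving nozzle
    itself (printing a parallel channel at small clearance merges the two
    air bodies instead of constricting the old one in 2D; set
    ``disturb_with_printing`` to study that regime).

    A pre-printed channel (width ``channel_width``, default 1.5 nozzle
    diameters -- the scale a unit-PN print lays down) spans the bath along
    x at the gap distance from the new path. The disturbing pass covers
    only the first ``pass_fraction`` of the channel, so the channel keeps
    an undisturbed far segment; after the pass the bath relaxes for
    ``relax_factor`` viscous relaxation times with the nozzle removed
    ("permanent" deformation). The deformation ratio is the minimal local
    width inside the disturbance zone over the median width of the
    undisturbed far segment, so slow diffuse-interface background drift of
    the channel width cancels and 1 means no permanent deformation.
    """
    d = job.nozzle.diameter
    if gap <= d / 2.0:
        raise ValueError(
            f"gap {gap:g} m does not clear the nozzle radius {d / 2:g} m "
            "(collision with the pre-printed channel)"
        )
    w0 = channel_width if channel_width is not None else 1.5 * d
    grid = job.grid
    y_path = job.path[0][1]
    # gap = clearance between the nozzle path line and the channel's near
    # surface (a center-to-center measure would merge the two channels
    # before any disturbance could be read off at small gaps)
    y_channel = y_path + gap + w0 / 2.0
    if not w0 <= y_channel <= grid.ly - w0:
        raise ValueError("pre-printed channel does not fit in the domain")
    phi0 = channel_phase(grid, y_channel, w0, job.phase_params.eps_pf)

    # shorten the pass: disturbance zone on the left, control on the right
    x0, y0p, v = job.path[0]
    x_end = pass_fraction * grid.lx
    job = replace(job, path=((x0, y0p, v), (x_end, y0p, v)))
    if not disturb_with_printing:
        job = replace(job, nozzle=replace(job.nozzle, air_flow_rate=0.0))

    # viscous relaxation time of the sheared gel at the print shear rate
    gd = v / d
    from .rheology import effective_viscosity

    mu_wake = float(effective_viscosity(gd, job.material.hb, mu_max=job.props.mu_cap))
    t_relax = mu_wake * d / job.material.surface_tension_vs_air
    job = replace(job, post_relax_time=relax_factor * t_relax)

    res = simulate_print(job, initial_phi=phi0)

    # measure the channel band directly: subcell widths along x
    from .geometry import _column_widths

    band = (
        np.abs(grid.cell_centers()[1] - y_channel) < max(gap / 2.0, 1.5 * w0)
    )
    mask = (res.phase.phi > 0) & band
    widths = _column_widths(
        np.where(band, res.phase.phi, -1.0), mask, axis=0, h_across=grid.dy
    )
    nx = grid.nx
    cols_with_air = mask.any(axis=1)
    full = np.zeros(nx)
    full[np.flatnonzero(cols_with_air)[: widths.size]] = widths
    zone = slice(int(0.1 * nx), int((pass_fraction - 0.08) * grid.lx / grid.dx))
    far = slice(int((pass_fraction + 0.15) * grid.lx / grid.dx), int(0.92 * nx))
    width_min = float(full[zone].min()) if full[zone].size else 0.0
    nominal = float(np.median(full[far][full[far] > 0])) if (full[far] > 0).any() else w0
    ratio = min(width_min / max(nominal, 1e-12), 1.0)
    return {
        "gap_m": gap,
        "deformation_ratio": float(ratio),
        "min_width_m": float(width_min),
        "nominal_width_m": float(nominal),
        "relax_time_s": float(relax_factor * t_relax),
        "result": res,
    }


def run_aspiration(
    job: PrintJob, aspiration_rate: float | None = None
) -> dict:
    """Print a channel, then retrace the path aspirating the air back.

    Returns the printed and recovered 2D air areas and the effective
    recovery rate; ``aspiration_rate`` defaults to the print flow rate.
    """
    res = simulate_print(job)
    area_printed = res.phase.air_area()
    q_asp = -(aspiration_rate if aspiration_rate is not None else job.nozzle.air_flow_rate)
    back_path = tuple(reversed(job.path))
    # retracing reverses the motion, so the (physically fixed) mouth now
    # leads: it meets the intact channel before the solid disturbs it
    job_back = replace(
        job,
        path=back_path,
        nozzle=replace(job.nozzle, air_flow_rate=q_asp, mouth_side=-1),
        post_relax_time=0.0,
    )
    res2 = simulate_print(job_back, initial_phi=res.phase.phi)
    area_left = res2.phase.air_area()
    t_back = path_duration(back_path)
    removed = area_printed - area_left
    q2d = abs(job_back.nozzle.area_rate_2d)
    # two measures: total air change (includes slow diffuse-interface
    # background drift) and the amount booked through the mouth sink
    booked = -res2.injected_area
    return {
        "printed_area_m2": float(area_printed),
        "removed_area_m2": float(removed),
        "aspirated_area_m2": float(booked),
        "aspirated_fraction": float(removed / max(area_printed, 1e-300)),
        "removal_rate_ratio": float(removed / (q2d * t_back)),
        "mouth_rate_ratio": float(booked / (q2d * t_back)),
        "result": res2,
    }
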