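"""Coupled fluid-membrane simulation and the benchmark scenarios.

The per-step loop follows the immersed-boundary ordering: membrane
constitutive forces -> spread to the grid -> LBM collide + stream ->
interpolate velocities -> advect vertices. Cells are kept unwrapped in
physical space; the periodic wrap happens inside the IBM stencils, so a
cell leaving the outlet is reintroduced at the inlet automatically.

Scenario presets cover the four studies: cylindrical pipe flow laden
with red blood cells over a range of hematocrit, a single RBC in a
plane-shear box (tank-treading / rolling / tumbling regimes), a wedge
channel for surface shear stress, and the micropost channel used for
tumor-cell trajectory generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import (BoundaryMask, DomainSpec, FaceBC, ObstacleSet,
                       voxelize_scene)
from .ibm import (DeltaKernel, MembraneState, advect_membrane,
                  interpolate_velocities, spread_membrane_forces)
from .lattice import (FluidField, RelaxationSpec, StabilityError,
                      get_velocity_set, lbm_step, relaxation_time)
from .membrane import ElasticParams, LennardJones, adhesion_forces, total_forces
from .meshes import TriMeshCell, build_biconcave_mesh, mesh_measures
from .units import UnitConverter

logger = logging.getLogger(__name__)

# Hct <-> initial RBC spacing map, linear in 1/d through the two stated
# endpoints (Hct 0.1 at 22 um, Hct 0.49 at 4.5 um).
_HCT_A = (1 / 4.5e-6 - 1 / 22e-6) / (0.49 - 0.10)
_HCT_B = 1 / 22e-6 - _HCT_A * 0.10


def hct_to_spacing(hct: float) -> float:
    """Initial center-to-center RBC spacing (m) for a target hematocrit."""
    if not 0 < hct <= 0.5:
        raise ValueError("Hct must lie in (0, 0.5]")
    return 1.0 / (_HCT_A * hct + _HCT_B)


def spacing_to_hct(d: float) -> float:
    return (1.0 / d - _HCT_B) / _HCT_A


@dataclass
class TrajectoryRecord:
    """One time sample of a cell's center-of-mass kinematics (SI units)."""

    t: float
    x: float
    y: float
    z: float
    vx: float
    vy: float
    vz: float
    label: str = ""
    seed: int = 0

    def as_row(self):
        return (self.t, self.x, self.y, self.z, self.vx, self.vy, self.vz,
                self.label, self.seed)


class Simulation:
    """Two-way coupled LBM + IBM + spring-network membrane simulation."""

    def __init__(self, domain: DomainSpec, converter: UnitConverter,
                 nu_p: float = 1.0e-6,
                 cells: list[TriMeshCell] | None = None,
                 obstacles: ObstacleSet | None = None,
                 body_force: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 kernel: DeltaKernel | None = None,
                 velocity_set: str = "D3Q19",
                 lj: LennardJones | None = None,
                 post_surface_nodes: np.ndarray | None = None,
                 volume_guard: bool = True):
        self.domain = domain
        self.conv = converter
        self.cells = list(cells or [])
        self.kernel = kernel or DeltaKernel("cosine")
        self.vset = get_velocity_set(velocity_set)
        self.relax: RelaxationSpec = relaxation_time(nu_p, converter.dx,
                                                     converter.dt)
        self.mask: BoundaryMask = voxelize_scene(domain, obstacles, converter)
        self.field = FluidField(domain.grid_shape, self.vset)
        # constant driving force in lattice units (applied on fluid nodes)
        g_lat = np.asarray(body_force, float) / converter.force_density_scale
        self._g_lat = g_lat
        self.lj = lj
        self._post_nodes = post_surface_nodes
        self._lo_pad = np.array([int(domain.wall_pad(a + "-")) for a in "xyz"])
        self._periodic = tuple(domain.bc[a + "-"].kind == "periodic"
                               for a in "xyz")
        self.time = 0.0
        self.step_count = 0
        self._vertex_velocity: list[np.ndarray] = [
            np.zeros_like(c.vertices) for c in self.cells]
        self.spread_deficit = 0.0  # force dropped into solid nodes (lattice units)
        self.volume_guard = volume_guard
        self.volume_correction = 0.0  # cumulative |dV| removed by the guard

    # --- coordinate transforms -----------------------------------------
    def to_lattice(self, x_phys: np.ndarray) -> np.ndarray:
        return x_phys / self.conv.dx + (self._lo_pad - 0.5)

    def to_physical(self, x_lat: np.ndarray) -> np.ndarray:
        return (x_lat - self._lo_pad + 0.5) * self.conv.dx

    # --- forces ---------------------------------------------------------
    def membrane_forces(self, cell: TriMeshCell) -> np.ndarray:
        f = total_forces(cell)
        if self.lj is not None and self._post_nodes is not None:
            f = f + adhesion_forces(cell, self._post_nodes, self.lj)
        return f

    # --- one coupled step -------------------------------------------------
    def step(self) -> None:
        grid = self.domain.grid_shape
        body = np.empty((3, *grid))
        body[:] = self._g_lat[:, None, None, None]
        for cell in self.cells:
            F_phys = self.membrane_forces(cell)
            state = MembraneState(
                X=self.to_lattice(cell.vertices),
                U=np.zeros_like(cell.vertices),
                F=F_phys / self.conv.force_scale,
            )
            spread_membrane_forces(state, self.kernel, grid, out=body)
        # forces landing in solid nodes are dropped (conservation deficit logged)
        solid = self.mask.solid
        if solid.any():
            deficit = np.abs(body[:, solid]).sum()
            if deficit:
                self.spread_deficit += float(deficit)
            body[:, solid] = 0.0
        self.field.body_force = body
        lbm_step(self.field, self.relax, self.mask)
        u_phys = self.field.u * self.conv.velocity_scale
        for ci, cell in enumerate(self.cells):
            state = MembraneState(X=self.to_lattice(cell.vertices),
                                  U=np.zeros_like(cell.vertices),
                                  F=np.zeros_like(cell.vertices))
            U = interpolate_velocities(self.field.u, state.X, self.kernel)
            state.U = U
            advect_membrane(state, dt=1.0, periodic_shape=None)
            cell.vertices = cell.vertices + U * self.conv.dx  # dt=1 lattice
            self._vertex_velocity[ci] = U * self.conv.velocity_scale
            if self.volume_guard:
                self._apply_volume_guard(cell)
        self.step_count += 1
        self.time += self.conv.dt
        del u_phys

    def _apply_volume_guard(self, cell: TriMeshCell) -> None:
        """Correct the slow enclosed-volume drift of the interpolated IBM
        velocity field (which is not exactly divergence-free) by rescaling
        the shape about its centroid once |dV| nears the tau_v pole. The
        removed strain is accumulated for diagnostics.
        """
        from .meshes import signed_volume
        tau_v = cell.params.tau_v if cell.params is not None else 0.01
        V = signed_volume(cell.vertices, cell.faces)
        dV = (V - cell.rest_volume) / cell.rest_volume
        if abs(dV) > 0.6 * tau_v:
            target = cell.rest_volume * (1.0 + 0.5 * tau_v * np.sign(dV))
            c = cell.centroid()
            cell.vertices = c + (cell.vertices - c) * (target / V) ** (1 / 3)
            self.volume_correction += abs(dV) - 0.5 * tau_v

    def run(self, n_steps: int, record_every: int | None = None,
            labels: list[str] | None = None, seed: int = 0,
            membrane_history: bool = False,
            on_record=None):
        """Advance ``n_steps``; optionally record COM kinematics and meshes.

        Returns (records, history) where ``records[i]`` is the list of
        :class:`TrajectoryRecord` for cell i and ``history[i]`` the list of
        (t, vertices) snapshots when ``membrane_history``.
        """
        labels = labels or [c.phenotype for c in self.cells]
        records: list[list[TrajectoryRecord]] = [[] for _ in self.cells]
        history: list[list[tuple[float, np.ndarray]]] = [[] for _ in self.cells]

        def record():
            for i, cell in enumerate(self.cells):
                com = cell.vertices.mean(axis=0)
                vel = self._vertex_velocity[i].mean(axis=0)
                com_w = self._wrap_position(com)
                records[i].append(TrajectoryRecord(
                    self.time, *com_w, *vel, label=labels[i], seed=seed))
                if membrane_history:
                    history[i].append((self.time, cell.vertices.copy()))
            if on_record is not None:
                on_record(self)

        record()
        for k in range(n_steps):
            self.step()
            if record_every and (k + 1) % record_every == 0:
                record()
        return records, history

    def _wrap_position(self, x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for ax in range(3):
            if self._periodic[ax]:
                out[ax] = np.mod(out[ax], self.domain.size[ax])
        return out


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    simulation: Simulation
    records: list
    membrane_history: list
    config: object = None


def make_pipe_simulation(length: float = 45e-6, radius: float = 4.5e-6,
                         dx: float = 0.5e-6, dt: float = 0.5e-7,
                         hct: float | None = 0.1,
                         n_cells: int | None = None,
                         re_target: float = 0.1,
                         rbc_diameter: float = 8e-6,
                         refinement: int = 2,
                         params: ElasticParams | None = None) -> Simulation:
    """RBC-laden pressure-driven pipe flow (periodic along the axis).

    Cells are spaced d_RBC apart (from the hematocrit map), discs
    initially perpendicular to the flow. The body force is set from the
    analytic plasma Poiseuille solution for the requested Reynolds number
    (defined with the pipe diameter).
    """
    conv = UnitConverter(dx=dx, dt=dt)
    nu_p, rho = 1.0e-6, 1.0e3
    mu = nu_p * rho
    # G R^2/(8 mu) = u_mean;  Re = rho u_mean 2R / mu
    u_mean = re_target * mu / (rho * 2 * radius)
    G = 8 * mu * u_mean / radius**2
    side = 2 * radius + 2 * dx
    ny = int(np.ceil(side / dx))
    domain = DomainSpec(size=(length, ny * dx, ny * dx), dx=dx,
                        bc={"x-": FaceBC("periodic"), "x+": FaceBC("periodic"),
                            "y-": FaceBC("wall"), "y+": FaceBC("wall"),
                            "z-": FaceBC("wall"), "z+": FaceBC("wall")},
                        pipe_radius=radius, label="pipe")
    cells = []
    if hct is not None or n_cells:
        d_rbc = hct_to_spacing(hct) if hct is not None else length / n_cells
        n = n_cells if n_cells is not None else max(1, int(length // d_rbc))
        params = params or ElasticParams()
        for i in range(n):
            cell = build_biconcave_mesh(rbc_diameter, refinement=refinement,
                                        params=params, phenotype="rbc")
            # disc plane perpendicular to the flow axis: symmetry axis -> x
            rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
            cell.rotate(rot, about=np.zeros(3))
            cell.translate(np.array([
                (i + 0.5) * d_rbc if n > 1 else length / 2,
                domain.size[1] / 2, domain.size[2] / 2]) - cell.centroid())
            cells.append(cell)
    sim = Simulation(domain, conv, nu_p=nu_p, cells=cells,
                     body_force=(G, 0.0, 0.0))
    # start from the developed plasma Poiseuille profile so the measured
    # transient is the cells' adaptation, not the fluid spin-up
    xs, ys, zs = domain.node_centers()
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    r2 = (Y - domain.size[1] / 2) ** 2 + (Z - domain.size[2] / 2) ** 2
    u_prof = 2 * u_mean * np.clip(1 - r2 / radius**2, 0.0, None)
    u0 = np.zeros((3, *domain.grid_shape))
    u0[0] = (u_prof / conv.velocity_scale)[None, :, :]
    u0[:, sim.mask.solid] = 0.0
    sim.field = FluidField(domain.grid_shape, sim.vset, rho=1.0, u=u0)
    return sim


def make_shear_simulation(shear_rate: float, orientation: str = "A",
                          box=(20e-6, 20e-6, 10e-6),
                          dx: float = 0.5e-6, dt: float | None = None,
                          rbc_diameter: float = 8e-6, refinement: int = 2,
                          nu_p: float = 1.0e-6,
                          params: ElasticParams | None = None) -> Simulation:
    """Single RBC between counter-moving plates (gap d along z).

    The plate speed is v0 = shear_rate * d / 2 ("the shear rate is
    2 v0 / d"). Orientation A: one long axis along the flow; B: both long
    axes perpendicular to the flow (disc axis along the flow direction x).
    The time step is chosen so the plate Mach number stays small.
    """
    d = box[2]
    v0 = shear_rate * d / 2.0
    if dt is None:
        # keep plate speed at 0.02 lattice units (Mach guard), tau in range
        dt = min(0.02 * dx / max(v0, 1e-12), 0.5 * dx**2 / nu_p)
    conv = UnitConverter(dx=dx, dt=dt)
    domain = DomainSpec(size=box, dx=dx,
                        bc={"x-": FaceBC("periodic"), "x+": FaceBC("periodic"),
                            "y-": FaceBC("periodic"), "y+": FaceBC("periodic"),
                            "z-": FaceBC("moving_wall", (-v0, 0.0, 0.0)),
                            "z+": FaceBC("moving_wall", (v0, 0.0, 0.0))},
                        label="shear_box")
    cell = build_biconcave_mesh(rbc_diameter, refinement=refinement,
                                params=params or ElasticParams(),
                                phenotype="rbc")
    if orientation.upper() == "A":
        pass  # long axes along x and y; disc (symmetry) axis along z
    elif orientation.upper() == "B":
        # rotate symmetry axis from z to x: long axes in the y-z plane
        rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        cell.rotate(rot)
    else:
        raise ValueError("orientation must be 'A' or 'B'")
    center = np.array(box) / 2.0
    cell.translate(center - cell.centroid())
    return Simulation(domain, conv, nu_p=nu_p, cells=[cell])


def make_wedge_simulation(channel=(60e-6, 20e-6, 20e-6),
                          wedge_height_frac: float = 0.5,
                          dx: float = 1.0e-6, dt: float = 2.0e-7,
                          re_target: float = 5.0,
                          hct: float = 0.0, rbc_diameter: float = 8e-6,
                          refinement: int = 2, seed: int = 0,
                          params: ElasticParams | None = None):
    """Wedge (ramp + flat top) channel driven by a body force.

    Returns (simulation, wedge_obstacle). RBCs, if any, are seeded
    uniformly at random in the free lumen upstream of and above the wedge.
    """
    from .geometry import WedgeObstacle
    Lx, Ly, Lz = channel
    wedge = WedgeObstacle(x0=0.25 * Lx, ramp=0.25 * Lx, flat=0.25 * Lx,
                          height=wedge_height_frac * Lz)
    conv = UnitConverter(dx=dx, dt=dt)
    nu_p, rho = 1.0e-6, 1.0e3
    mu = nu_p * rho
    u_mean = re_target * mu / (rho * Lz)
    G = 12 * mu * u_mean / Lz**2  # slit estimate for the unobstructed part
    domain = DomainSpec(size=channel, dx=dx,
                        bc={"x-": FaceBC("periodic"), "x+": FaceBC("periodic"),
                            "y-": FaceBC("periodic"), "y+": FaceBC("periodic"),
                            "z-": FaceBC("wall"), "z+": FaceBC("wall")},
                        label="wedge")
    obstacles = ObstacleSet(wedges=[wedge])
    cells = []
    if hct > 0:
        rng = np.random.default_rng(seed)
        lumen_volume = Lx * Ly * Lz * (1 - 0.375 * wedge_height_frac)
        v_rbc = 0.35 * (4 / 3) * np.pi * (rbc_diameter / 2) ** 3
        n = max(1, int(hct * lumen_volume / v_rbc))
        par = params or ElasticParams()
        placed = 0
        while placed < n:
            pos = rng.random(3) * [Lx, Ly, Lz]
            if wedge.contains(*(pos + [0, 0, -rbc_diameter / 2])) or \
               pos[2] < rbc_diameter / 2 or pos[2] > Lz - rbc_diameter / 2:
                continue
            cell = build_biconcave_mesh(rbc_diameter, refinement=refinement,
                                        params=par, phenotype="rbc")
            cell.rotate(_random_rotation(rng))
            cell.translate(pos - cell.centroid())
            cells.append(cell)
            placed += 1
    sim = Simulation(domain, conv, nu_p=nu_p, cells=cells,
                     obstacles=obstacles, body_force=(G, 0.0, 0.0))
    return sim, wedge


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def run_scenario(config) -> ScenarioResult:
    """Run a validated ScenarioConfig end to end.

    Builds the preset simulation for the configured geometry, advances it
    for ``duration`` seconds and records center-of-mass kinematics every
    ``record_interval``. Membrane history is kept for the shear box (the
    regime diagnostics need vertex positions).
    """
    geom = config.geometry
    params = ElasticParams()
    mult = config.cells[0].stiffness_multiplier if config.cells else 1.0
    if mult != 1.0:
        params = params.stiffened(mult)
    keep_history = geom == "shear_box"
    if geom == "pipe":
        sim = make_pipe_simulation(
            dx=config.dx, dt=config.dt,
            hct=config.hct if config.hct > 0 else None,
            re_target=config.driving.re_target or 0.1,
            params=params)
    elif geom == "shear_box":
        sim = make_shear_simulation(
            shear_rate=config.driving.shear_rate,
            orientation=config.orientation, dx=config.dx,
            params=params)
    elif geom == "wedge":
        sim, _ = make_wedge_simulation(dx=config.dx, dt=config.dt,
                                       re_target=config.driving.re_target or 5.0,
                                       hct=config.hct, seed=config.seed,
                                       params=params)
    elif geom == "micropost":
        from .dataset import ChannelPreset, build_channel
        preset = (ChannelPreset.paper_scale() if config.preset == "paper"
                  else ChannelPreset())
        domain, conv, layout = build_channel(preset, config.seed,
                                             layout=config.layout_file)
        mu, rho = 1.0e-3, 1.0e3
        G = (config.driving.body_force
             or (12 * mu * preset.u_mean / preset.depth**2, 0.0, 0.0))
        sim = Simulation(domain, conv, nu_p=mu / rho, obstacles=layout,
                         body_force=G)
    else:  # pragma: no cover - config validation forbids this
        raise ValueError(f"unknown geometry {geom!r}")
    n_steps = max(1, int(round(config.duration / sim.conv.dt)))
    rec_every = max(1, int(round(config.record_interval / sim.conv.dt)))
    records, history = sim.run(n_steps, record_every=rec_every,
                               seed=config.seed,
                               membrane_history=keep_history)
    return ScenarioResult(simulation=sim, records=records,
                          membrane_history=history, config=config)


def post_surface_points(obstacles: ObstacleSet, spacing: float,
                        z_range: tuple[float, float]) -> np.ndarray:
    """Sample points on every post's lateral surface at ~``spacing``."""
    pts = []
    z0, z1 = z_range
    nz = max(2, int(np.ceil((z1 - z0) / spacing)))
    zs = np.linspace(z0, z1, nz)
    for p in obstacles.posts:
        ntheta = max(8, int(np.ceil(2 * np.pi * p.radius / spacing)))
        th = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
        ring = np.stack([p.center[0] + p.radius * np.cos(th),
                         p.center[1] + p.radius * np.sin(th)], axis=1)
        for z in zs:
            pts.append(np.column_stack([ring, np.full(len(ring), z)]))
    return np.concatenate(pts, axis=0) if pts else np.empty((0, 3))
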