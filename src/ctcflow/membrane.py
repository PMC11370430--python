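"""Spring-network constitutive forces of the cell membrane.

Four force families act on the triangulated membrane, each with a
pole-regularized strain law that diverges at a limiting strain tau:

* link (in-plane spectrin stretching),   F ~ -kappa_l dL/p [1 + 1/(tau_l^2 - dL^2)]
* bending (dihedral angle restoring),    F ~ -kappa_b dtheta/L0 [1 + 1/(tau_b^2 - dtheta^2)]
* local area conservation,               F ~ -kappa_a dA/L0 [1 + 1/(tau_a^2 - dA^2)]
* global volume conservation,            F ~ -kappa_v dV/L0 [1/(tau_v^2 - dV^2)]

with relative strains dL = (L - L0)/L0, dtheta = theta - theta0,
dA = (A - A0)/A0, dV = (V - V0)/V0. The scalar laws are available
verbatim (``*_force_scalar``); the per-vertex vector fields are the exact
analytic gradients of the corresponding energies, which keeps the total
force field conservative and makes every family pass a central-difference
energy-gradient check. Stiffnesses are given in units of k_B T.

Crossing a pole (|strain| >= tau) means the time step is unstable and is
a hard error, never silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .meshes import (TriMeshCell, dihedral_angles, face_areas_normals,
                     signed_volume)

KB = 1.380649e-23  # J/K


class MembraneStabilityError(RuntimeError):
    """A membrane strain crossed its limiting pole (unstable step size)."""


@dataclass(frozen=True)
class ElasticParams:
    """Membrane elastic constants.

    kappa_* are dimensionless multiples of k_B T; tau_* are the limiting
    strains (tau_b is an angle limit in radians); p is the spectrin
    persistence length in metres.
    """

    kappa_l: float = 15.0
    kappa_b: float = 80.0
    kappa_a: float = 5.0
    kappa_v: float = 20.0
    tau_l: float = 2.0
    tau_b: float = np.pi / 2
    tau_a: float = 2.0
    tau_v: float = 0.01
    p: float = 2.5e-9
    kBT: float = KB * 300.0

    def __post_init__(self):
        for name in ("kappa_l", "kappa_b", "kappa_a", "kappa_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_l", "tau_a", "tau_v"):
            v = getattr(self, name)
            if not 0 < v <= 2.0 + 1e-12 and name != "tau_v":
                raise ValueError(f"{name} must lie in (0, 2]")
        if not 0 < self.tau_b < np.pi:
            raise ValueError("tau_b must lie in (0, pi)")
        if self.p <= 0 or self.kBT <= 0:
            raise ValueError("p and kBT must be positive")

    def stiffened(self, factor: float) -> "ElasticParams":
        """Phenotype variant: multiply kappa_l and kappa_b only."""
        return replace(self, kappa_l=self.kappa_l * factor,
                       kappa_b=self.kappa_b * factor)

    @property
    def kl(self) -> float:  # J
        return self.kappa_l * self.kBT

    @property
    def kb(self) -> float:
        return self.kappa_b * self.kBT

    @property
    def ka(self) -> float:
        return self.kappa_a * self.kBT

    @property
    def kv(self) -> float:
        return self.kappa_v * self.kBT


def _params(cell: TriMeshCell) -> ElasticParams:
    return cell.params if cell.params is not None else ElasticParams()


# ---------------------------------------------------------------------------
# scalar strain laws (verbatim) and their potentials
# ---------------------------------------------------------------------------

def link_force_scalar(dL, params: ElasticParams):
    """-kappa_l dL / p * [1 + 1/(tau_l^2 - dL^2)]  (N)."""
    return -params.kl * dL / params.p * (1.0 + 1.0 / (params.tau_l**2 - dL**2))


def bending_force_scalar(dtheta, L0, params: ElasticParams):
    """-kappa_b dtheta / L0 * [1 + 1/(tau_b^2 - dtheta^2)]  (N)."""
    return -params.kb * dtheta / L0 * (1.0 + 1.0 / (params.tau_b**2 - dtheta**2))


def area_force_scalar(dA, L0, params: ElasticParams):
    """-kappa_a dA / L0 * [1 + 1/(tau_a^2 - dA^2)]  (N)."""
    return -params.ka * dA / L0 * (1.0 + 1.0 / (params.tau_a**2 - dA**2))


def volume_force_scalar(dV, L0, params: ElasticParams):
    """-kappa_v dV / L0 * [1/(tau_v^2 - dV^2)]  (N); pure pole term."""
    return -params.kv * dV / L0 * (1.0 / (params.tau_v**2 - dV**2))


def _g_regularized(x, tau):
    """g(x) = x (1 + 1/(tau^2 - x^2)) = -d/dx of the link/bend/area potential."""
    return x * (1.0 + 1.0 / (tau**2 - x**2))


def _G_potential(x, tau):
    """G(x) = x^2/2 - (1/2) ln((tau^2 - x^2)/tau^2), with G' = g."""
    return 0.5 * x**2 - 0.5 * np.log((tau**2 - x**2) / tau**2)


def _g_pole(x, tau):
    return x / (tau**2 - x**2)


def _G_pole(x, tau):
    return -0.5 * np.log((tau**2 - x**2) / tau**2)


def _scatter_add(forces: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """forces[idx] += vals via bincount (much faster than np.add.at)."""
    n = len(forces)
    for c in range(3):
        forces[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


def _check(strain, tau, kind):
    if np.any(np.abs(strain) >= tau):
        worst = float(np.abs(strain).max())
        raise MembraneStabilityError(
            f"{kind} strain |{worst:.4g}| crossed its pole tau={tau:.4g}; "
            "reduce the time step")


# ---------------------------------------------------------------------------
# vector force fields (exact energy gradients)
# ---------------------------------------------------------------------------

def link_forces(cell: TriMeshCell) -> np.ndarray:
    """Per-vertex stretching forces; equal and opposite along each edge."""
    p = _params(cell)
    a, b = cell.edges[:, 0], cell.edges[:, 1]
    dvec = cell.vertices[b] - cell.vertices[a]
    L = np.linalg.norm(dvec, axis=1)
    dL = (L - cell.rest_lengths) / cell.rest_lengths
    _check(dL, p.tau_l, "link")
    # scalar law gives the endpoint force magnitude directly
    s = link_force_scalar(dL, p)          # negative when stretched
    ehat = dvec / L[:, None]
    forces = np.zeros_like(cell.vertices)
    _scatter_add(forces, b, s[:, None] * ehat)
    _scatter_add(forces, a, -s[:, None] * ehat)
    return forces


def link_energy(cell: TriMeshCell) -> float:
    p = _params(cell)
    a, b = cell.edges[:, 0], cell.edges[:, 1]
    L = np.linalg.norm(cell.vertices[b] - cell.vertices[a], axis=1)
    dL = (L - cell.rest_lengths) / cell.rest_lengths
    _check(dL, p.tau_l, "link")
    return float((p.kl * cell.rest_lengths / p.p
                  * _G_potential(dL, p.tau_l)).sum())


def _dihedral_gradients(verts, hinges):
    """Analytic gradient of the signed dihedral angle for every hinge.

    Returns (grad_x0, grad_x1, grad_x2, grad_x3), each (H, 3), for hinges
    [x0, x1 | x2, x3] with faces (x0,x1,x2) and (x0,x3,x1).
    """
    x0, x1 = verts[hinges[:, 0]], verts[hinges[:, 1]]
    x2, x3 = verts[hinges[:, 2]], verts[hinges[:, 3]]
    e = x1 - x0
    elen = np.linalg.norm(e, axis=1)
    n1 = np.cross(x1 - x0, x2 - x0)
    n2 = np.cross(x3 - x0, x1 - x0)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # off-hinge vertices move along the (area-normalized) face normals
    g2 = -(elen / n1sq)[:, None] * n1
    g3 = -(elen / n2sq)[:, None] * n2
    # hinge vertices carry the lever-arm compensation (net force & torque = 0)
    d20 = np.einsum("ij,ij->i", x2 - x1, e) / elen
    d30 = np.einsum("ij,ij->i", x3 - x1, e) / elen
    d21 = np.einsum("ij,ij->i", x2 - x0, e) / elen
    d31 = np.einsum("ij,ij->i", x3 - x0, e) / elen
    g0 = (d20 / elen)[:, None] * g2 + (d30 / elen)[:, None] * g3
    g1 = -(d21 / elen)[:, None] * g2 - (d31 / elen)[:, None] * g3
    return g0, g1, g2, g3


def bending_forces(cell: TriMeshCell) -> np.ndarray:
    """Per-vertex bending forces (gradient of the hinge-angle energy)."""
    p = _params(cell)
    theta = dihedral_angles(cell.vertices, cell.hinges)
    dtheta = theta - cell.rest_angles
    _check(dtheta, p.tau_b, "bending")
    coef = -p.kb * _g_regularized(dtheta, p.tau_b)   # = -dE/dtheta
    g0, g1, g2, g3 = _dihedral_gradients(cell.vertices, cell.hinges)
    forces = np.zeros_like(cell.vertices)
    for col, g in zip(range(4), (g0, g1, g2, g3)):
        _scatter_add(forces, cell.hinges[:, col], coef[:, None] * g)
    return forces


def bending_energy(cell: TriMeshCell) -> float:
    p = _params(cell)
    theta = dihedral_angles(cell.vertices, cell.hinges)
    dtheta = theta - cell.rest_angles
    _check(dtheta, p.tau_b, "bending")
    return float((p.kb * _G_potential(dtheta, p.tau_b)).sum())


def area_forces(cell: TriMeshCell) -> np.ndarray:
    """Per-vertex local-area forces; point toward the face centroid when
    the face is dilated (dA > 0) and away when compressed."""
    p = _params(cell)
    areas, normals = face_areas_normals(cell.vertices, cell.faces)
    dA = (areas - cell.rest_areas) / cell.rest_areas
    _check(dA, p.tau_a, "area")
    coef = -p.ka * _g_regularized(dA, p.tau_a) / cell.rest_areas  # = -dE/dA
    v0 = cell.vertices[cell.faces[:, 0]]
    v1 = cell.vertices[cell.faces[:, 1]]
    v2 = cell.vertices[cell.faces[:, 2]]
    # grad of triangle area wrt each vertex: 1/2 (n_hat x opposite_edge)
    gA0 = 0.5 * np.cross(normals, v2 - v1)
    gA1 = 0.5 * np.cross(normals, v0 - v2)
    gA2 = 0.5 * np.cross(normals, v1 - v0)
    forces = np.zeros_like(cell.vertices)
    for col, g in zip(range(3), (gA0, gA1, gA2)):
        _scatter_add(forces, cell.faces[:, col], coef[:, None] * g)
    return forces


def area_energy(cell: TriMeshCell) -> float:
    p = _params(cell)
    areas, _ = face_areas_normals(cell.vertices, cell.faces)
    dA = (areas - cell.rest_areas) / cell.rest_areas
    _check(dA, p.tau_a, "area")
    return float((p.ka * _G_potential(dA, p.tau_a)).sum())


def volume_forces(cell: TriMeshCell) -> np.ndarray:
    """Per-vertex volume-restoring forces (toward the centroid when inflated)."""
    p = _params(cell)
    V = signed_volume(cell.vertices, cell.faces)
    dV = (V - cell.rest_volume) / cell.rest_volume
    _check(dV, p.tau_v, "volume")
    coef = -p.kv * _g_pole(dV, p.tau_v) / cell.rest_volume  # = -dE/dV
    v0 = cell.vertices[cell.faces[:, 0]]
    v1 = cell.vertices[cell.faces[:, 1]]
    v2 = cell.vertices[cell.faces[:, 2]]
    forces = np.zeros_like(cell.vertices)
    # grad of signed volume: dV/dv0 = (v1 x v2)/6, cyclic
    _scatter_add(forces, cell.faces[:, 0], coef * np.cross(v1, v2) / 6.0)
    _scatter_add(forces, cell.faces[:, 1], coef * np.cross(v2, v0) / 6.0)
    _scatter_add(forces, cell.faces[:, 2], coef * np.cross(v0, v1) / 6.0)
    return forces


def volume_energy(cell: TriMeshCell) -> float:
    p = _params(cell)
    V = signed_volume(cell.vertices, cell.faces)
    dV = (V - cell.rest_volume) / cell.rest_volume
    _check(dV, p.tau_v, "volume")
    return float(p.kv * _G_pole(dV, p.tau_v))


def total_forces(cell: TriMeshCell) -> np.ndarray:
    return (link_forces(cell) + bending_forces(cell)
            + area_forces(cell) + volume_forces(cell))


def total_energy(cell: TriMeshCell) -> float:
    return (link_energy(cell) + bending_energy(cell)
            + area_energy(cell) + volume_energy(cell))


# ---------------------------------------------------------------------------
# Lennard-Jones adhesion to micropost surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LennardJones:
    """12-6 potential: epsilon well depth (J), r_min zero-force distance (m),
    cutoff (m). Repulsion is capped below r_cap to avoid blow-up."""

    epsilon: float
    r_min: float
    cutoff: float
    r_cap_fraction: float = 0.5

    @property
    def sigma(self) -> float:
        return self.r_min / 2.0 ** (1.0 / 6.0)

    def force_magnitude(self, r):
        """dU/dr with U = eps[(rm/r)^12 - 2(rm/r)^6]; positive = repulsive."""
        r = np.asarray(r, dtype=float)
        rcap = self.r_cap_fraction * self.r_min
        rc = np.maximum(r, rcap)
        s6 = (self.r_min / rc) ** 6
        f = 12.0 * self.epsilon / rc * (s6**2 - s6)
        return np.where(r <= self.cutoff, f, 0.0)


def adhesion_forces(cell: TriMeshCell, post_surface_nodes: np.ndarray,
                    lj: LennardJones) -> np.ndarray:
    """Pairwise LJ forces between membrane vertices and post surface nodes.

    Positive force magnitude pushes the vertex away from the node
    (repulsion inside r_min, attraction out to the cutoff).
    """
    nodes = np.asarray(post_surface_nodes, dtype=float).reshape(-1, 3)
    forces = np.zeros_like(cell.vertices)
    if len(nodes) == 0:
        return forces
    from scipy.spatial import cKDTree
    tree = cKDTree(nodes)
    pairs = tree.query_ball_point(cell.vertices, r=lj.cutoff)
    import logging
    log = logging.getLogger(__name__)
    for vi, idx in enumerate(pairs):
        if not idx:
            continue
        dvec = cell.vertices[vi] - nodes[idx]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < lj.r_cap_fraction * lj.r_min):
            log.warning("LJ separation below cap at vertex %d; repulsion capped", vi)
        f = lj.force_magnitude(r)
        safe_r = np.maximum(r, 1e-300)
        forces[vi] += (f / safe_r) @ dvec
    return forces
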