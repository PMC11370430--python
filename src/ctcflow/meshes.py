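"""Triangulated closed-membrane cell meshes.

Red blood cells are built as an Evans-Fung biconcave disc of given
diameter; circulating tumor cells as elastic spheres. The reference
geometry captured at build time (edge rest lengths, face rest areas,
hinge rest angles, enclosed volume) is the force-free state of the
constitutive model in :mod:`ctcflow.membrane`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh

# Evans–Fung biconcave profile coefficients (shape normalized to unit radius)
_EF_C0 = 0.207161
_EF_C1 = 2.002558
_EF_C2 = -1.122762


@dataclass
class TriMeshCell:
    """A closed triangulated membrane with its reference (rest) geometry.

    vertices : (n, 3) float, metres
    faces    : (m, 3) int, outward-oriented
    edges    : (E, 2) int, unique undirected edges
    hinges   : (H, 4) int, per interior edge: [v_edge0, v_edge1, v_oppA, v_oppB]
    """

    vertices: np.ndarray
    faces: np.ndarray
    edges: np.ndarray
    hinges: np.ndarray
    rest_lengths: np.ndarray      # L0 per edge
    rest_areas: np.ndarray        # A0 per face
    rest_angles: np.ndarray       # theta0 per hinge
    rest_volume: float            # V0
    params: object = None         # ElasticParams
    phenotype: str = "default"
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "TriMeshCell":
        c = TriMeshCell(
            vertices=self.vertices.copy(), faces=self.faces,
            edges=self.edges, hinges=self.hinges,
            rest_lengths=self.rest_lengths, rest_areas=self.rest_areas,
            rest_angles=self.rest_angles, rest_volume=self.rest_volume,
            params=self.params, phenotype=self.phenotype,
            meta=dict(self.meta),
        )
        return c

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def translate(self, offset) -> "TriMeshCell":
        self.vertices = self.vertices + np.asarray(offset, dtype=float)
        return self

    def rotate(self, rotation: np.ndarray, about=None) -> "TriMeshCell":
        """Apply a 3x3 rotation matrix about ``about`` (default: centroid)."""
        about = self.centroid() if about is None else np.asarray(about)
        self.vertices = (self.vertices - about) @ np.asarray(rotation).T + about
        return self


class MeshBuildError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometric primitives shared with the force evaluators
# ---------------------------------------------------------------------------

def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by the divergence theorem (positive when outward)."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->i", np.cross(v0, v1), v2).sum() / 6.0)


def face_areas_normals(vertices: np.ndarray, faces: np.ndarray):
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    a2 = np.linalg.norm(n, axis=1)
    bad = a2 <= 0
    if bad.any():
        raise MeshBuildError(f"{bad.sum()} degenerate faces")
    return 0.5 * a2, n / a2[:, None]


def dihedral_angles(vertices: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    """Signed bending angle at each hinge (0 for coplanar faces).

    The angle is measured between the two face normals, signed by whether
    the hinge folds toward (+) or away from (-) the first face's normal.
    """
    x0 = vertices[hinges[:, 0]]
    x1 = vertices[hinges[:, 1]]
    x2 = vertices[hinges[:, 2]]
    x3 = vertices[hinges[:, 3]]
    e = x1 - x0
    n1 = np.cross(x1 - x0, x2 - x0)   # face (x0, x1, x2)
    n2 = np.cross(x3 - x0, x1 - x0)   # face (x0, x3, x1)
    ehat = e / np.linalg.norm(e, axis=1)[:, None]
    cosq = np.einsum("ij,ij->i", n1, n2) / (
        np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1))
    sinq = np.einsum("ij,ij->i", np.cross(n1, n2), ehat) / (
        np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1))
    return np.arctan2(sinq, np.clip(cosq, -1.0, 1.0))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _connectivity(mesh: trimesh.Trimesh):
    edges = mesh.edges_unique
    adj_faces = mesh.face_adjacency            # (H, 2) face indices
    adj_edges = mesh.face_adjacency_edges      # (H, 2) shared edge vertices
    hinges = np.empty((len(adj_faces), 4), dtype=np.int64)
    for h, ((fa, fb), (ea, eb)) in enumerate(zip(adj_faces, adj_edges)):
        shared = {ea, eb}
        oa = [v for v in mesh.faces[fa] if v not in shared][0]
        ob = [v for v in mesh.faces[fb] if v not in shared][0]
        hinges[h] = (ea, eb, oa, ob)
    return edges, hinges


def _freeze_reference(mesh: trimesh.Trimesh, params, phenotype, meta) -> TriMeshCell:
    if not mesh.is_watertight:
        raise MeshBuildError("membrane mesh must be closed (watertight)")
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    edges, hinges = _connectivity(mesh)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    L0 = np.linalg.norm(verts[edges[:, 1]] - verts[edges[:, 0]], axis=1)
    A0, _ = face_areas_normals(verts, faces)
    theta0 = dihedral_angles(verts, hinges)
    V0 = signed_volume(verts, faces)
    if V0 <= 0 or np.any(L0 <= 0) or np.any(A0 <= 0):
        raise MeshBuildError("reference geometry must be strictly positive")
    cell = TriMeshCell(
        vertices=verts, faces=faces, edges=edges, hinges=hinges,
        rest_lengths=L0, rest_areas=A0, rest_angles=theta0,
        rest_volume=V0, params=params, phenotype=phenotype, meta=meta,
    )
    if cell.euler_characteristic() != 2:
        raise MeshBuildError("mesh is not a closed genus-0 surface")
    return cell


def build_sphere_mesh(diameter: float, refinement: int = 2, params=None,
                      phenotype: str = "ctc") -> TriMeshCell:
    """Icosphere membrane of the given diameter (m)."""
    if diameter <= 0:
        raise MeshBuildError("diameter must be positive")
    if refinement < 1:
        raise MeshBuildError("refinement must be >= 1")
    mesh = trimesh.creation.icosphere(subdivisions=refinement,
                                      radius=diameter / 2.0)
    return _freeze_reference(mesh, params, phenotype,
                             {"shape": "sphere", "diameter": diameter,
                              "refinement": refinement})


def biconcave_profile(rho: np.ndarray) -> np.ndarray:
    """Evans-Fung thickness factor f(rho); z = +- R sqrt(1-rho^2) f(rho)."""
    r2 = np.asarray(rho) ** 2
    return 0.5 * (_EF_C0 + _EF_C1 * r2 + _EF_C2 * r2**2)


def build_biconcave_mesh(diameter: float, refinement: int = 2, params=None,
                         phenotype: str = "rbc") -> TriMeshCell:
    """Evans-Fung biconcave disc of the given in-plane diameter (m).

    Built by mapping an icosphere: the in-plane coordinates are kept and
    the axial coordinate is scaled by the biconcave thickness profile, so
    the surface stays closed and genus-0 and the dimple depth follows the
    classic parametrization. refinement >= 2 is required to resolve the
    central dimple.
    """
    if diameter <= 0:
        raise MeshBuildError("diameter must be positive")
    if refinement < 2:
        raise MeshBuildError(
            "refinement < 2 cannot resolve the biconcave dimple")
    sphere = trimesh.creation.icosphere(subdivisions=refinement, radius=1.0)
    v = np.asarray(sphere.vertices)
    rho = np.sqrt(v[:, 0] ** 2 + v[:, 1] ** 2)
    scaled = v.copy()
    scaled[:, 2] = v[:, 2] * biconcave_profile(np.clip(rho, 0.0, 1.0))
    scaled *= diameter / 2.0
    mesh = trimesh.Trimesh(vertices=scaled, faces=sphere.faces, process=False)
    return _freeze_reference(mesh, params, phenotype,
                             {"shape": "biconcave", "diameter": diameter,
                              "refinement": refinement})


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def mesh_measures(cell: TriMeshCell, axis=None) -> dict:
    """Volume, surface area, cross-section extent h, principal axes.

    ``axis`` is the measurement direction for h (default: x, the paper's
    initial cell-diameter direction); principal axes come from the vertex
    covariance (largest eigenvalue first).
    """
    areas, _ = face_areas_normals(cell.vertices, cell.faces)
    vol = signed_volume(cell.vertices, cell.faces)
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    proj = cell.vertices @ axis
    h = float(proj.max() - proj.min())
    centered = cell.vertices - cell.vertices.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return {
        "volume": float(vol),
        "area": float(areas.sum()),
        "h": h,
        "principal_axes": evecs[:, order].T,
        "principal_moments": evals[order],
    }
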