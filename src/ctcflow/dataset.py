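"""Two-phenotype tumor-cell trajectory dataset generation.

A micropost channel is built once per seed; cells of two elastic
phenotypes (the stiff one has kappa_l and kappa_b multiplied by 5, with
kappa_a and kappa_v unchanged) are released at random inlet positions
and their center-of-mass position + velocity are recorded at even
intervals (1 ms by default), six kinematic columns per sample.

Two generation modes share the same geometry, membrane model and
phenotype encoding:

* ``full`` - two-way immersed-boundary coupling (the complete model);
  cost scales with the fluid grid, suitable for small validation runs.
* ``fast`` (default) - the steady plasma flow through the post array is
  solved once with the LBM, then each deformable cell is advanced by
  overdamped membrane dynamics in that frozen field (interpolated fluid
  velocity plus mobility times elastic + post-contact forces). This
  reduced-order mode is what makes hundreds of trajectories per class
  tractable on one CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .geometry import DomainSpec, FaceBC, ObstacleSet, micropost_layout
from .ibm import DeltaKernel, interpolate_velocities
from .membrane import ElasticParams, LennardJones, total_forces
from .meshes import build_sphere_mesh
from .simulate import Simulation, post_surface_points
from .units import UnitConverter

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ("t", "x", "y", "z", "vx", "vy", "vz")


@dataclass
class ChannelPreset:
    """Micropost-channel configuration (desk-scale defaults).

    The paper-scale device subdomain is 300 x 2200 x 25 um^3; the desk
    preset shortens the channel so a trajectory takes O(10^3) membrane
    steps while keeping the post diameter / cell diameter ratio and the
    quasi-2D confinement of the device.
    """

    length: float = 120e-6          # flow direction (x)
    width: float = 40e-6            # lateral (y)
    depth: float = 12e-6            # z confinement
    dx: float = 1.0e-6
    dt: float = 1.0e-7
    n_posts: int = 12
    post_radius: float = 3.0e-6
    min_gap: float = 4.0e-6
    u_mean: float = 1.5e-3          # target mean inlet speed (m/s)
    ctc_diameter: float = 8.0e-6
    refinement: int = 1
    stiff_factor: float = 5.0
    record_interval: float = 1.0e-3
    steady_steps: int = 2500
    cell_dt: float = 4.0e-5         # overdamped membrane step (fast mode)
    mobility_radius: float = 0.25e-6
    max_steps: int = 5000           # observation window, units of cell_dt

    @classmethod
    def paper_scale(cls) -> "ChannelPreset":
        return cls(length=2200e-6, width=300e-6, depth=25e-6, n_posts=600,
                   steady_steps=20000)


@dataclass
class TrajectoryDataset:
    """Labeled center-of-mass trajectory sequences.

    sequences : list of (T_i, 6) float arrays (x, y, z, vx, vy, vz; SI)
    labels    : phenotype per sequence ("soft" / "stiff")
    times     : list of (T_i,) sample times (s)
    """

    sequences: list
    labels: list
    times: list
    meta: dict = dc_field(default_factory=dict)

    def __len__(self):
        return len(self.sequences)

    @property
    def classes(self):
        return sorted(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (seq, lab, ts) in enumerate(
                zip(self.sequences, self.labels, self.times)):
            df = pd.DataFrame(seq, columns=TRAJECTORY_COLUMNS[1:])
            df.insert(0, "t", ts)
            df["label"] = lab
            df["trajectory"] = k
            df["seed"] = self.meta.get("seed", 0)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta=None) -> "TrajectoryDataset":
        seqs, labs, times = [], [], []
        for _, g in df.groupby("trajectory", sort=True):
            seqs.append(g[list(TRAJECTORY_COLUMNS[1:])].to_numpy(float))
            labs.append(str(g["label"].iloc[0]))
            times.append(g["t"].to_numpy(float))
        return cls(seqs, labs, times, meta=dict(meta or {}))

    @classmethod
    def load_csv(cls, path) -> "TrajectoryDataset":
        # round_trip parsing keeps the stored doubles bit-exact
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def save_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            h5.attrs["meta"] = json.dumps(self.meta, default=str)
            for k, (seq, lab, ts) in enumerate(
                    zip(self.sequences, self.labels, self.times)):
                g = h5.create_group(f"trajectory_{k:05d}")
                g.create_dataset("kinematics", data=seq)
                g.create_dataset("t", data=ts)
                g.attrs["label"] = lab

    @classmethod
    def load_hdf5(cls, path) -> "TrajectoryDataset":
        import h5py
        seqs, labs, times = [], [], []
        with h5py.File(path, "r") as h5:
            meta = json.loads(h5.attrs.get("meta", "{}"))
            for key in sorted(h5.keys()):
                g = h5[key]
                seqs.append(np.asarray(g["kinematics"]))
                times.append(np.asarray(g["t"]))
                labs.append(str(g.attrs["label"]))
        return cls(seqs, labs, times, meta=meta)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for seq, lab in zip(self.sequences, self.labels):
            h.update(np.ascontiguousarray(seq).tobytes())
            h.update(lab.encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# channel construction and steady background flow
# ---------------------------------------------------------------------------

def build_channel(preset: ChannelPreset, seed: int, layout=None):
    """Voxelized micropost channel + converter + post layout."""
    conv = UnitConverter(dx=preset.dx, dt=preset.dt)
    margin = preset.post_radius + 2 * preset.dx
    if layout is None:
        layout = micropost_layout(
            ((margin + 0.1 * preset.length, 0.92 * preset.length - margin),
             (margin, preset.width - margin)),
            n_posts=preset.n_posts, radius=preset.post_radius,
            min_gap=preset.min_gap, seed=seed,
            z0=-np.inf, z1=np.inf)
    domain = DomainSpec(
        size=(preset.length, preset.width, preset.depth), dx=preset.dx,
        bc={"x-": FaceBC("periodic"), "x+": FaceBC("periodic"),
            "y-": FaceBC("wall"), "y+": FaceBC("wall"),
            "z-": FaceBC("wall"), "z+": FaceBC("wall")},
        label="micropost")
    return domain, conv, layout


def steady_flow(preset: ChannelPreset, seed: int, layout=None,
                n_steps: int | None = None):
    """LBM solve of the plasma flow through the post array to steady state.

    Returns (simulation, layout). The body force is set from the slit
    Poiseuille estimate for the requested mean speed and the velocity
    field is advanced a fixed number of steps (default from the preset).
    """
    domain, conv, layout = build_channel(preset, seed, layout)
    mu, rho = 1.0e-3, 1.0e3
    G = 12 * mu * preset.u_mean / preset.depth**2
    sim = Simulation(domain, conv, nu_p=mu / rho, obstacles=layout,
                     body_force=(G, 0.0, 0.0))
    steps = preset.steady_steps if n_steps is None else n_steps
    for _ in range(steps):
        sim.step()
    return sim, layout


# ---------------------------------------------------------------------------
# fast-mode cell propagation
# ---------------------------------------------------------------------------

def _project_contacts(verts: np.ndarray, layout: ObstacleSet,
                      width: float, depth: float,
                      post_margin: float = 0.6e-6,
                      wall_margin: float = 0.8e-6,
                      max_push: float = 0.25e-6) -> np.ndarray:
    """Hard-contact projection against posts and channel walls.

    Any vertex closer than ``post_margin`` to a post's lateral surface is
    moved radially out to that standoff (analytic cylinder distance);
    vertices are likewise clamped off the y/z walls. Projection is
    unconditionally stable at the overdamped step size, unlike a stiff
    short-range potential; the membrane elasticity then carries the
    contact deformation to the rest of the cell.
    """
    if layout.posts:
        centers = np.array([p.center for p in layout.posts])
        radii = np.array([p.radius for p in layout.posts])
        com = verts[:, :2].mean(axis=0)
        dxy = verts[:, None, :2] - centers[None]             # (n, P, 2)
        dist_c = np.linalg.norm(dxy, axis=2)
        nearest = dist_c.argmin(axis=1)
        rows = np.arange(len(verts))
        dmin = dist_c[rows, nearest]
        target = radii[nearest] + post_margin
        inside = dmin < target
        if inside.any():
            # push offending vertices along the cell-centroid radial
            # direction so the contact acts on the cell coherently
            # (per-vertex radial projection can tear a straddling mesh)
            for k in np.unique(nearest[inside]):
                sel = inside & (nearest == k)
                d = com - centers[k]
                nd = np.linalg.norm(d)
                d = d / nd if nd > 1e-12 else np.array([0.0, 1.0])
                p = verts[sel, :2] - centers[k]
                pd = p @ d
                R = radii[k] + post_margin
                disc = np.maximum(pd**2 + R**2
                                  - np.einsum("ij,ij->i", p, p), 0.0)
                delta = -pd + np.sqrt(disc)
                # resolve deep penetration over several steps: a large
                # instantaneous displacement would tear the mesh
                np.clip(delta, 0.0, max_push, out=delta)
                verts[sel, :2] += delta[:, None] * d[None]
    np.clip(verts[:, 1], wall_margin, width - wall_margin, out=verts[:, 1])
    np.clip(verts[:, 2], wall_margin, depth - wall_margin, out=verts[:, 2])
    return verts



try:
    import numba

    @numba.njit(cache=True)
    def _forces_kernel(verts, edges, hinges, faces, L0, A0, theta0, V0,
                       kl_p, kb, ka, kv, tl, tb, ta, tv):  # pragma: no cover
        B, n, _ = verts.shape
        F = np.zeros((B, n, 3))
        Vol = np.zeros(B)
        bad = np.zeros(B, numba.boolean)
        E = edges.shape[0]
        H = hinges.shape[0]
        NF = faces.shape[0]
        for c in range(B):
            v = verts[c]
            # --- links ---
            for e in range(E):
                i, j = edges[e, 0], edges[e, 1]
                dx = v[j, 0] - v[i, 0]
                dy = v[j, 1] - v[i, 1]
                dz = v[j, 2] - v[i, 2]
                L = np.sqrt(dx * dx + dy * dy + dz * dz)
                dL = (L - L0[e]) / L0[e]
                if not np.isfinite(dL):
                    bad[c] = True
                    dL = 0.0
                if dL > 0.999 * tl:
                    dL = 0.999 * tl
                elif dL < -0.999 * tl:
                    dL = -0.999 * tl
                s = -kl_p * dL * (1.0 + 1.0 / (tl * tl - dL * dL))
                s /= max(L, 1e-12)
                F[c, j, 0] += s * dx; F[c, j, 1] += s * dy; F[c, j, 2] += s * dz
                F[c, i, 0] -= s * dx; F[c, i, 1] -= s * dy; F[c, i, 2] -= s * dz
            # --- bending ---
            for h in range(H):
                i0, i1, i2, i3 = hinges[h, 0], hinges[h, 1], hinges[h, 2], hinges[h, 3]
                ex = v[i1, 0] - v[i0, 0]; ey = v[i1, 1] - v[i0, 1]; ez = v[i1, 2] - v[i0, 2]
                ax = v[i2, 0] - v[i0, 0]; ay = v[i2, 1] - v[i0, 1]; az = v[i2, 2] - v[i0, 2]
                bx = v[i3, 0] - v[i0, 0]; by = v[i3, 1] - v[i0, 1]; bz = v[i3, 2] - v[i0, 2]
                elen = np.sqrt(ex * ex + ey * ey + ez * ez)
                if elen < 1e-12:
                    elen = 1e-12
                # n1 = e x a, n2 = b x e
                n1x = ey * az - ez * ay; n1y = ez * ax - ex * az; n1z = ex * ay - ey * ax
                n2x = by * ez - bz * ey; n2y = bz * ex - bx * ez; n2z = bx * ey - by * ex
                n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 1e-40)
                n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 1e-40)
                cosq = n1x * n2x + n1y * n2y + n1z * n2z
                crx = n1y * n2z - n1z * n2y
                cry = n1z * n2x - n1x * n2z
                crz = n1x * n2y - n1y * n2x
                sinq = (crx * ex + cry * ey + crz * ez) / elen
                th = np.arctan2(sinq, cosq)
                dth = th - theta0[h]
                if dth > 0.999 * tb:
                    dth = 0.999 * tb
                elif dth < -0.999 * tb:
                    dth = -0.999 * tb
                coef = -kb * dth * (1.0 + 1.0 / (tb * tb - dth * dth))
                s2 = -elen / n1sq
                s3 = -elen / n2sq
                g2x = s2 * n1x; g2y = s2 * n1y; g2z = s2 * n1z
                g3x = s3 * n2x; g3y = s3 * n2y; g3z = s3 * n2z
                d20 = ((v[i2, 0] - v[i1, 0]) * ex + (v[i2, 1] - v[i1, 1]) * ey
                       + (v[i2, 2] - v[i1, 2]) * ez) / elen
                d30 = ((v[i3, 0] - v[i1, 0]) * ex + (v[i3, 1] - v[i1, 1]) * ey
                       + (v[i3, 2] - v[i1, 2]) * ez) / elen
                d21 = (ax * ex + ay * ey + az * ez) / elen
                d31 = (bx * ex + by * ey + bz * ez) / elen
                c20 = d20 / elen; c30 = d30 / elen
                c21 = d21 / elen; c31 = d31 / elen
                F[c, i0, 0] += coef * (c20 * g2x + c30 * g3x)
                F[c, i0, 1] += coef * (c20 * g2y + c30 * g3y)
                F[c, i0, 2] += coef * (c20 * g2z + c30 * g3z)
                F[c, i1, 0] += coef * (-c21 * g2x - c31 * g3x)
                F[c, i1, 1] += coef * (-c21 * g2y - c31 * g3y)
                F[c, i1, 2] += coef * (-c21 * g2z - c31 * g3z)
                F[c, i2, 0] += coef * g2x; F[c, i2, 1] += coef * g2y; F[c, i2, 2] += coef * g2z
                F[c, i3, 0] += coef * g3x; F[c, i3, 1] += coef * g3y; F[c, i3, 2] += coef * g3z
            # --- faces: volume first, then area + volume forces ---
            Vtot = 0.0
            for f in range(NF):
                p0, p1, p2 = faces[f, 0], faces[f, 1], faces[f, 2]
                cx = v[p0, 1] * v[p1, 2] - v[p0, 2] * v[p1, 1]
                cy = v[p0, 2] * v[p1, 0] - v[p0, 0] * v[p1, 2]
                cz = v[p0, 0] * v[p1, 1] - v[p0, 1] * v[p1, 0]
                Vtot += (cx * v[p2, 0] + cy * v[p2, 1] + cz * v[p2, 2]) / 6.0
            Vol[c] = Vtot
            dV = (Vtot - V0) / V0
            if dV > 0.999 * tv:
                dV = 0.999 * tv
            elif dV < -0.999 * tv:
                dV = -0.999 * tv
            coefV = -kv * dV / (tv * tv - dV * dV) / V0
            for f in range(NF):
                p0, p1, p2 = faces[f, 0], faces[f, 1], faces[f, 2]
                u1x = v[p1, 0] - v[p0, 0]; u1y = v[p1, 1] - v[p0, 1]; u1z = v[p1, 2] - v[p0, 2]
                u2x = v[p2, 0] - v[p0, 0]; u2y = v[p2, 1] - v[p0, 1]; u2z = v[p2, 2] - v[p0, 2]
                nx = u1y * u2z - u1z * u2y
                ny = u1z * u2x - u1x * u2z
                nz = u1x * u2y - u1y * u2x
                a2n = max(np.sqrt(nx * nx + ny * ny + nz * nz), 1e-40)
                area = 0.5 * a2n
                dA = (area - A0[f]) / A0[f]
                if dA > 0.999 * ta:
                    dA = 0.999 * ta
                elif dA < -0.999 * ta:
                    dA = -0.999 * ta
                coefA = -ka * dA * (1.0 + 1.0 / (ta * ta - dA * dA)) / A0[f]
                hx = nx / a2n; hy = ny / a2n; hz = nz / a2n
                # area gradients: 0.5 * nhat x (opposite edge)
                w0x = v[p2, 0] - v[p1, 0]; w0y = v[p2, 1] - v[p1, 1]; w0z = v[p2, 2] - v[p1, 2]
                gA0x = 0.5 * (hy * w0z - hz * w0y)
                gA0y = 0.5 * (hz * w0x - hx * w0z)
                gA0z = 0.5 * (hx * w0y - hy * w0x)
                gA1x = 0.5 * (hy * (-u2z) - hz * (-u2y))
                gA1y = 0.5 * (hz * (-u2x) - hx * (-u2z))
                gA1z = 0.5 * (hx * (-u2y) - hy * (-u2x))
                gA2x = 0.5 * (hy * u1z - hz * u1y)
                gA2y = 0.5 * (hz * u1x - hx * u1z)
                gA2z = 0.5 * (hx * u1y - hy * u1x)
                gV0x = (v[p1, 1] * v[p2, 2] - v[p1, 2] * v[p2, 1]) / 6.0
                gV0y = (v[p1, 2] * v[p2, 0] - v[p1, 0] * v[p2, 2]) / 6.0
                gV0z = (v[p1, 0] * v[p2, 1] - v[p1, 1] * v[p2, 0]) / 6.0
                gV1x = (v[p2, 1] * v[p0, 2] - v[p2, 2] * v[p0, 1]) / 6.0
                gV1y = (v[p2, 2] * v[p0, 0] - v[p2, 0] * v[p0, 2]) / 6.0
                gV1z = (v[p2, 0] * v[p0, 1] - v[p2, 1] * v[p0, 0]) / 6.0
                gV2x = (v[p0, 1] * v[p1, 2] - v[p0, 2] * v[p1, 1]) / 6.0
                gV2y = (v[p0, 2] * v[p1, 0] - v[p0, 0] * v[p1, 2]) / 6.0
                gV2z = (v[p0, 0] * v[p1, 1] - v[p0, 1] * v[p1, 0]) / 6.0
                F[c, p0, 0] += coefA * gA0x + coefV * gV0x
                F[c, p0, 1] += coefA * gA0y + coefV * gV0y
                F[c, p0, 2] += coefA * gA0z + coefV * gV0z
                F[c, p1, 0] += coefA * gA1x + coefV * gV1x
                F[c, p1, 1] += coefA * gA1y + coefV * gV1y
                F[c, p1, 2] += coefA * gA1z + coefV * gV1z
                F[c, p2, 0] += coefA * gA2x + coefV * gV2x
                F[c, p2, 1] += coefA * gA2y + coefV * gV2y
                F[c, p2, 2] += coefA * gA2z + coefV * gV2z
        return F, bad, Vol

    _HAVE_NUMBA_FORCES = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_FORCES = False

class _BatchedMembrane:
    """Vectorized constitutive forces for a batch of identical-topology cells.

    Same force laws as :mod:`ctcflow.membrane` (exact energy gradients of
    the pole-regularized strain potentials) evaluated for a (B, n, 3)
    vertex stack in one shot, with one reduced-order concession: strains
    are clamped just inside their pole, so a hard post contact saturates
    the restoring force instead of aborting the run (the fully coupled
    model treats a pole crossing as a hard error). Only genuine tearing -
    a stretching or area strain past its pole - flags a cell as failed in
    the returned mask.
    """

    def __init__(self, template, params: ElasticParams):
        self.p = params
        self.edges = template.edges
        self.faces = template.faces
        self.hinges = template.hinges
        self.L0 = template.rest_lengths
        self.A0 = template.rest_areas
        self.theta0 = template.rest_angles
        self.V0 = template.rest_volume
        self.n = template.n_vertices
        self._build_incidence()

    def _build_incidence(self):
        """One sparse vertex-incidence matrix gathers every per-element
        force contribution in a single matmul (much faster than repeated
        scatter-adds for large batches). Column blocks: edges (with the
        action-reaction sign folded in), the four hinge roles, and the
        three face corners (area + volume contributions share them)."""
        from scipy import sparse
        E, H, F = len(self.edges), len(self.hinges), len(self.faces)
        rows, cols, data = [], [], []
        col0 = 0
        rows += list(self.edges[:, 1]) + list(self.edges[:, 0])
        cols += list(range(E)) * 2
        data += [1.0] * E + [-1.0] * E
        col0 += E
        for c in range(4):
            rows += list(self.hinges[:, c])
            cols += list(range(col0, col0 + H))
            data += [1.0] * H
            col0 += H
        for c in range(3):
            rows += list(self.faces[:, c])
            cols += list(range(col0, col0 + F))
            data += [1.0] * F
            col0 += F
        self._n_slots = col0
        self._S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n, col0))

    def _gather(self, blocks, B):
        """blocks: list of (B, m_i, 3) arrays in incidence column order."""
        vals = np.concatenate(blocks, axis=1)          # (B, M, 3)
        Y = self._S @ vals.transpose(1, 0, 2).reshape(self._n_slots, -1)
        return Y.reshape(self.n, B, 3).transpose(1, 0, 2)

    def forces(self, verts: np.ndarray):
        p = self.p
        if _HAVE_NUMBA_FORCES:
            F, bad, V = _forces_kernel(
                np.ascontiguousarray(verts), self.edges, self.hinges,
                self.faces, self.L0, self.A0, self.theta0, self.V0,
                p.kl / p.p, p.kb, p.ka, p.kv,
                p.tau_l, p.tau_b, p.tau_a, p.tau_v)
            return F, bad, V
        B = len(verts)
        bad = np.zeros(B, dtype=bool)

        # --- links ---
        a, b = self.edges[:, 0], self.edges[:, 1]
        dvec = verts[:, b] - verts[:, a]
        L = np.linalg.norm(dvec, axis=2)
        dL = (L - self.L0[None]) / self.L0[None]
        bad |= ~np.isfinite(dL).all(axis=1)
        # stretching saturates at its pole as well; only a non-finite
        # state (genuine numerical blow-up) fails a cell in this mode
        dL = np.clip(dL, -0.999 * p.tau_l, 0.999 * p.tau_l)
        s = -p.kl / p.p * dL * (1.0 + 1.0 / (p.tau_l**2 - dL**2))
        sv = s[:, :, None] * (dvec / np.maximum(L, 1e-12)[:, :, None])

        # --- bending ---
        h = self.hinges
        x0, x1 = verts[:, h[:, 0]], verts[:, h[:, 1]]
        x2, x3 = verts[:, h[:, 2]], verts[:, h[:, 3]]
        e = x1 - x0
        elen = np.linalg.norm(e, axis=2)
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        n1sq = np.maximum(np.einsum("bij,bij->bi", n1, n1), 1e-40)
        n2sq = np.maximum(np.einsum("bij,bij->bi", n2, n2), 1e-40)
        elen = np.maximum(elen, 1e-12)
        ehat = e / elen[:, :, None]
        cosq = np.einsum("bij,bij->bi", n1, n2)
        sinq = np.einsum("bij,bij->bi", np.cross(n1, n2), ehat)
        theta = np.arctan2(sinq, cosq)
        dth = theta - self.theta0[None]
        # bending saturates (folds cannot exceed the limiting angle)
        dth = np.clip(dth, -0.999 * p.tau_b, 0.999 * p.tau_b)
        coef = -p.kb * dth * (1.0 + 1.0 / (p.tau_b**2 - dth**2))
        g2 = -(elen / n1sq)[:, :, None] * n1
        g3 = -(elen / n2sq)[:, :, None] * n2
        d20 = np.einsum("bij,bij->bi", x2 - x1, e) / elen
        d30 = np.einsum("bij,bij->bi", x3 - x1, e) / elen
        d21 = np.einsum("bij,bij->bi", x2 - x0, e) / elen
        d31 = np.einsum("bij,bij->bi", x3 - x0, e) / elen
        g0 = (d20 / elen)[:, :, None] * g2 + (d30 / elen)[:, :, None] * g3
        g1 = -(d21 / elen)[:, :, None] * g2 - (d31 / elen)[:, :, None] * g3
        cf = coef[:, :, None]

        # --- local area ---
        f = self.faces
        v0, v1, v2 = verts[:, f[:, 0]], verts[:, f[:, 1]], verts[:, f[:, 2]]
        nrm = np.cross(v1 - v0, v2 - v0)
        a2 = np.maximum(np.linalg.norm(nrm, axis=2), 1e-40)
        areas = 0.5 * a2
        nhat = nrm / a2[:, :, None]
        dA = (areas - self.A0[None]) / self.A0[None]
        # local area saturates at its pole like bending (contact squeeze)
        dA = np.clip(dA, -0.999 * p.tau_a, 0.999 * p.tau_a)
        coefA = (-p.ka * dA * (1.0 + 1.0 / (p.tau_a**2 - dA**2))
                 / self.A0[None])[:, :, None]

        # --- volume ---
        V = np.einsum("bij,bij->bi", np.cross(v0, v1), v2).sum(axis=1) / 6.0
        dV = (V - self.V0) / self.V0
        # the volume guard in the propagator keeps dV inside the pole
        dV = np.clip(dV, -0.999 * p.tau_v, 0.999 * p.tau_v)
        coefV = (-p.kv * dV / (p.tau_v**2 - dV**2) / self.V0)[:, None, None]
        face0 = coefA * 0.5 * np.cross(nhat, v2 - v1) + coefV * np.cross(v1, v2) / 6.0
        face1 = coefA * 0.5 * np.cross(nhat, v0 - v2) + coefV * np.cross(v2, v0) / 6.0
        face2 = coefA * 0.5 * np.cross(nhat, v1 - v0) + coefV * np.cross(v0, v1) / 6.0
        F = self._gather([sv, cf * g0, cf * g1, cf * g2, cf * g3,
                          face0, face1, face2], B)
        return F, bad, V


def propagate_cell_fast(sim: Simulation, layout: ObstacleSet,
                        preset: ChannelPreset, params: ElasticParams,
                        inlet_pos: np.ndarray, phenotype: str,
                        seed: int = 0,
                        max_steps: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Advance one cell through the frozen steady flow (overdamped mode).

    Returns (times, kinematics) with kinematics (T, 6). Sampling interval
    is ``preset.record_interval``; the run stops when the cell's center
    passes 95 % of the channel length or ``max_steps`` is hit.
    """
    cell = build_sphere_mesh(preset.ctc_diameter, refinement=preset.refinement,
                             params=params, phenotype=phenotype)
    cell.translate(inlet_pos - cell.centroid())
    mu = 1.0e-3
    mobility = 1.0 / (6 * np.pi * mu * preset.mobility_radius)
    kernel = DeltaKernel("cosine")
    dt = preset.cell_dt
    rec_every = max(1, int(round(preset.record_interval / dt)))
    x_stop = 0.95 * preset.length
    times, rows = [], []
    t = 0.0
    u_field = sim.field.u
    v_scale = sim.conv.velocity_scale
    for k in range(max_steps):
        X = sim.to_lattice(cell.vertices)
        U = interpolate_velocities(u_field, X, kernel) * v_scale
        V = U + mobility * total_forces(cell)
        # cap per-step vertex displacement (explicit-step safety)
        vmax = 0.4e-6 / dt
        speed = np.linalg.norm(V, axis=1, keepdims=True)
        V = np.where(speed > vmax, V * (vmax / np.maximum(speed, 1e-300)), V)
        if k % rec_every == 0:
            com = cell.centroid()
            vel = V.mean(axis=0)
            times.append(t)
            rows.append([com[0], com[1], com[2], vel[0], vel[1], vel[2]])
        cell.vertices = cell.vertices + dt * V
        _project_contacts(cell.vertices, layout, preset.width, preset.depth)
        _volume_guard(cell)
        t += dt
        if cell.vertices[:, 0].mean() > x_stop:
            break
    return np.asarray(times), np.asarray(rows)


def _volume_guard(cell, frac: float = 0.6) -> None:
    """Quasi-incompressibility projection for the overdamped mode.

    The explicit overdamped update cannot resolve the very stiff volume
    pole (tau_v = 0.01) at a tractable step size, so when a contact event
    drives |dV| past ``frac * tau_v`` the shape is rescaled about its
    centroid back to half the limiting strain - the same quasi-
    incompressible behavior the pole enforces in the fully coupled model.
    """
    from .meshes import signed_volume
    tau_v = cell.params.tau_v if cell.params is not None else 0.01
    V = signed_volume(cell.vertices, cell.faces)
    dV = (V - cell.rest_volume) / cell.rest_volume
    if abs(dV) > frac * tau_v:
        target = cell.rest_volume * (1.0 + 0.5 * tau_v * np.sign(dV))
        c = cell.centroid()
        cell.vertices = c + (cell.vertices - c) * (target / V) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# batched propagation and dataset generation
# ---------------------------------------------------------------------------

def propagate_batch_fast(sim: Simulation, layout: ObstacleSet,
                         preset: ChannelPreset, params: ElasticParams,
                         inlets: np.ndarray, max_steps: int = 6000):
    """Advance a batch of non-interacting cells through the frozen flow.

    All cells share one mesh topology and phenotype, so the membrane
    forces, interpolation and guards are evaluated for the whole (B, n, 3)
    stack at once. Returns (per-cell (times, kinematics) list, failed
    mask); a cell fails if a membrane strain crosses its pole.
    """
    template = build_sphere_mesh(preset.ctc_diameter,
                                 refinement=preset.refinement, params=params)
    base = template.vertices - template.centroid()
    inlets = np.atleast_2d(inlets)
    B = len(inlets)
    verts = inlets[:, None, :] + base[None]
    bm = _BatchedMembrane(template, params)
    mu = 1.0e-3
    mobility = 1.0 / (6 * np.pi * mu * preset.mobility_radius)
    kernel = DeltaKernel("cosine")
    # Elastic stability: the fastest membrane relaxation rate is about
    # (incident edges) * mobility * k_edge = lam, and the explicit
    # overdamped step must resolve it (lam*dt <~ 0.7). Resolving the
    # relaxation - rather than capping it - is what preserves the
    # phenotypes' different deformation response, so the 5x-stiff class
    # runs at a proportionally smaller dt and is simply more expensive.
    # dt divides the 1 ms record interval exactly.
    k_edge = (params.kl / params.p) * (1 + 1 / params.tau_l**2) / bm.L0.min()
    lam = 6.0 * mobility * k_edge
    dt_target = min(preset.cell_dt, 0.7 / lam)
    rec_every = int(np.ceil(preset.record_interval / dt_target))
    dt = preset.record_interval / rec_every
    n_steps = int(round(max_steps * preset.cell_dt / dt))
    vmax = 0.4e-6 / dt
    x_stop = 0.95 * preset.length
    u_field = sim.field.u
    v_scale = sim.conv.velocity_scale
    tau_v = params.tau_v
    times = [[] for _ in range(B)]
    rows = [[] for _ in range(B)]
    active = np.ones(B, dtype=bool)
    failed = np.zeros(B, dtype=bool)
    t = 0.0
    for k in range(n_steps):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        sub = verts[idx]
        X = sim.to_lattice(sub.reshape(-1, 3))
        U = (interpolate_velocities(u_field, X, kernel)
             .reshape(sub.shape)) * v_scale
        F, bad, V = bm.forces(sub)
        vel = U + mobility * F
        speed = np.linalg.norm(vel, axis=2, keepdims=True)
        np.clip(speed / vmax, 1.0, None, out=speed)
        vel = vel / speed
        if k % rec_every == 0:
            com = sub.mean(axis=1)
            vmean = vel.mean(axis=1)
            for j, i in enumerate(idx):
                times[i].append(t)
                rows[i].append([*com[j], *vmean[j]])
        sub = sub + dt * vel
        # contact projection (only cells actually near a post need the loop)
        if layout.posts:
            centers = np.array([p.center for p in layout.posts])
            radii = np.array([p.radius for p in layout.posts])
            gaps = (np.linalg.norm(
                sub[:, :, None, :2] - centers[None, None], axis=3)
                - radii[None, None])
            touching = (gaps.min(axis=(1, 2)) < 0.6e-6)
            for j in np.flatnonzero(touching):
                _project_contacts(sub[j], layout, preset.width, preset.depth)
        for ax, L in ((1, preset.width), (2, preset.depth)):
            np.clip(sub[:, :, ax], 0.8e-6, L - 0.8e-6, out=sub[:, :, ax])
        # volume guard (quasi-incompressibility at the overdamped step)
        Vnow = _batch_volume(sub, bm.faces)
        dV = (Vnow - bm.V0) / bm.V0
        for j in np.flatnonzero(np.abs(dV) > 0.6 * tau_v):
            target = bm.V0 * (1.0 + 0.5 * tau_v * np.sign(dV[j]))
            c = sub[j].mean(axis=0)
            sub[j] = c + (sub[j] - c) * (target / Vnow[j]) ** (1.0 / 3.0)
        verts[idx] = sub
        # retire finished and failed cells
        done = sub[:, :, 0].mean(axis=1) > x_stop
        failed[idx[bad]] = True
        active[idx[bad | done]] = False
        t += dt
    out = [(np.asarray(ts), np.asarray(r)) for ts, r in zip(times, rows)]
    return out, failed


def _batch_volume(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = verts[:, faces[:, 0]], verts[:, faces[:, 1]], verts[:, faces[:, 2]]
    return np.einsum("bij,bij->bi", np.cross(v0, v1), v2).sum(axis=1) / 6.0


def generate_trajectory_dataset(n_per_class: int, seed: int = 0,
                                preset: ChannelPreset | None = None,
                                params: ElasticParams | None = None,
                                mode: str = "fast",
                                retry_budget: int = 20,
                                min_samples: int = 8) -> TrajectoryDataset:
    """Generate a labeled two-phenotype trajectory dataset.

    Both phenotypes flow through the same channel realization (the device
    is fixed); cells are released at random inlet positions and recorded
    at even intervals. Deterministic for fixed (n_per_class, seed,
    preset). Failed cells (membrane pole crossing) are replaced up to
    ``retry_budget`` per class.
    """
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    preset = preset or ChannelPreset()
    base = params or ElasticParams()
    phenos = {"soft": base, "stiff": base.stiffened(preset.stiff_factor)}
    rng = np.random.default_rng(seed)
    sim, layout = steady_flow(preset, seed)
    margin = preset.ctc_diameter / 2 + 1.5e-6

    def draw_inlets(count):
        y0 = margin + rng.random(count) * (preset.width - 2 * margin)
        z0 = preset.depth / 2 + (rng.random(count) - 0.5) * 1e-6
        x0 = np.full(count, preset.ctc_diameter / 2 + 1e-6)
        return np.column_stack([x0, y0, z0])

    seqs, labs, times_all = [], [], []
    for label, par in phenos.items():
        made, tries = 0, 0
        while made < n_per_class:
            want = n_per_class - made
            if mode == "fast":
                results, failed = propagate_batch_fast(
                    sim, layout, preset, par, draw_inlets(want),
                    max_steps=preset.max_steps)
            else:
                results, failed = [], np.zeros(want, dtype=bool)
                for inlet in draw_inlets(want):
                    results.append(_propagate_cell_full(preset, layout, par,
                                                        inlet, label))
            for (ts, kin), bad in zip(results, failed):
                if bad or len(ts) < min_samples:
                    tries += 1
                    if tries > retry_budget:
                        raise RuntimeError("trajectory retry budget exhausted")
                    continue
                seqs.append(kin)
                labs.append(label)
                times_all.append(ts)
                made += 1
    meta = {"seed": seed, "mode": mode, "n_per_class": n_per_class,
            "record_interval": preset.record_interval,
            "stiff_factor": preset.stiff_factor,
            "channel": {"length": preset.length, "width": preset.width,
                        "depth": preset.depth, "n_posts": preset.n_posts}}
    return TrajectoryDataset(seqs, labs, times_all, meta=meta)


def _propagate_cell_full(preset: ChannelPreset, layout, params,
                         inlet_pos, phenotype, max_steps: int = 4000):
    """One cell with full two-way IBM coupling (small validation runs)."""
    domain, conv, layout = build_channel(preset, 0, layout)
    cell = build_sphere_mesh(preset.ctc_diameter, refinement=preset.refinement,
                             params=params, phenotype=phenotype)
    cell.translate(np.asarray(inlet_pos) - cell.centroid())
    mu, rho = 1.0e-3, 1.0e3
    G = 12 * mu * preset.u_mean / preset.depth**2
    lj = LennardJones(epsilon=2.0e-19, r_min=1.2e-6, cutoff=2.5e-6)
    posts_pts = post_surface_points(layout, spacing=1.0e-6,
                                    z_range=(0.0, preset.depth))
    sim = Simulation(domain, conv, nu_p=mu / rho, cells=[cell],
                     obstacles=layout, body_force=(G, 0.0, 0.0),
                     lj=lj, post_surface_nodes=posts_pts)
    rec_every = max(1, int(round(preset.record_interval / conv.dt)))
    records, _ = sim.run(max_steps, record_every=rec_every,
                         labels=[phenotype])
    rows = np.array([[r.x, r.y, r.z, r.vx, r.vy, r.vz] for r in records[0]])
    ts = np.array([r.t for r in records[0]])
    return ts, rows


def class_divergence(dataset: TrajectoryDataset, n_bins: int = 8):
    """Mean pairwise lateral separation between classes vs downstream distance.

    Bins all samples by x and returns (bin_centers, |mean_y_soft -
    mean_y_stiff| per bin) - the global path-divergence diagnostic.
    """
    xs, ys, labs = [], [], []
    for seq, lab in zip(dataset.sequences, dataset.labels):
        xs.append(seq[:, 0]); ys.append(seq[:, 1])
        labs.append(np.full(len(seq), lab == dataset.classes[-1]))
    x = np.concatenate(xs); y = np.concatenate(ys)
    is_b = np.concatenate(labs)
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    centers, gaps = [], []
    for k in range(n_bins):
        m = (x >= edges[k]) & (x < edges[k + 1])
        if (m & is_b).sum() and (m & ~is_b).sum():
            centers.append(0.5 * (edges[k] + edges[k + 1]))
            gaps.append(abs(y[m & is_b].mean() - y[m & ~is_b].mean()))
    return np.array(centers), np.array(gaps)
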