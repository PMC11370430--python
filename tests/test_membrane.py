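"""Membrane mesh builders, constitutive forces and their energies.

The central check is the energy-gradient oracle: every force family must
equal minus the central-difference gradient of its potential.
"""

import numpy as np
import pytest

from ctcflow import membrane as M
from ctcflow.membrane import (ElasticParams, LennardJones,
                              MembraneStabilityError, adhesion_forces,
                              area_energy, area_forces, bending_energy,
                              bending_forces, link_energy, link_forces,
                              total_energy, total_forces, volume_energy,
                              volume_forces)
from ctcflow.meshes import (MeshBuildError, build_biconcave_mesh,
                            build_sphere_mesh, mesh_measures, signed_volume)


class TestBuilders:
    def test_biconcave_extent_is_diameter(self, biconcave_cell):
        ext = biconcave_cell.vertices.max(0) - biconcave_cell.vertices.min(0)
        assert np.isclose(ext[0], 8e-6, rtol=0.01)
        assert np.isclose(ext[1], 8e-6, rtol=0.01)
        assert ext[2] < 0.5 * ext[0]  # flattened disc

    def test_closed_genus_zero(self, biconcave_cell, sphere_cell):
        assert biconcave_cell.euler_characteristic() == 2
        assert sphere_cell.euler_characteristic() == 2

    def test_biconcave_volume_below_circumscribing_sphere(self, biconcave_cell):
        v_sphere = 4 / 3 * np.pi * (4e-6) ** 3  # 268.1 um^3
        assert 0 < biconcave_cell.rest_volume < v_sphere

    def test_biconcave_has_dimple(self, biconcave_cell):
        # vertices near the axis sit lower than the rim thickness maximum
        rho = np.linalg.norm(biconcave_cell.vertices[:, :2], axis=1)
        z = np.abs(biconcave_cell.vertices[:, 2])
        near_axis = z[rho < 1e-6].max()
        rim = z.max()
        assert near_axis < 0.6 * rim

    def test_dimple_needs_refinement(self):
        with pytest.raises(MeshBuildError):
            build_biconcave_mesh(8e-6, refinement=1)

    def test_sphere_vertices_on_radius(self, sphere_cell):
        r = np.linalg.norm(sphere_cell.vertices, axis=1)
        assert np.allclose(r, 4e-6, rtol=1e-6)

    def test_sphere_volume_converges(self):
        exact = np.pi / 6  # unit diameter
        errs = []
        for ref in (1, 2):
            cell = build_sphere_mesh(1.0, refinement=ref)
            errs.append(abs(cell.rest_volume - exact) / exact)
        assert errs[1] < errs[0] < 0.15

    def test_builders_deterministic(self):
        a = build_sphere_mesh(8e-6, refinement=1)
        b = build_sphere_mesh(8e-6, refinement=1)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)


class TestReferenceState:
    def test_reference_is_force_free(self, sphere_cell, biconcave_cell):
        for cell in (sphere_cell, biconcave_cell):
            for fn in (link_forces, bending_forces, area_forces,
                       volume_forces):
                assert np.abs(fn(cell)).max() == 0.0


class TestScalarLaws:
    def test_link_direct_substitution(self):
        # force at dL = 0.1 equals hand substitution into the strain law
        p = ElasticParams()
        dL = 0.1
        expected = -p.kappa_l * p.kBT * dL / p.p * (
            1 + 1 / (p.tau_l**2 - dL**2))
        assert np.isclose(M.link_force_scalar(dL, p), expected)
        assert expected < 0  # stretched edge pulls its endpoints together

    def test_volume_direct_substitution(self):
        p = ElasticParams()
        dV, L0 = 0.005, 2e-6
        expected = -p.kv * dV / L0 / (p.tau_v**2 - dV**2)
        assert np.isclose(M.volume_force_scalar(dV, L0, p), expected)
        assert np.isfinite(expected)

    def test_bending_magnitude_diverges_at_pole(self):
        p = ElasticParams()
        near = abs(M.bending_force_scalar(0.999 * p.tau_b, 1e-6, p))
        mid = abs(M.bending_force_scalar(0.5 * p.tau_b, 1e-6, p))
        assert near > 100 * mid


class TestVectorForces:
    def test_link_forces_sum_to_zero(self, perturbed_sphere):
        f = link_forces(perturbed_sphere)
        assert np.abs(f.sum(0)).max() < 1e-20

    def test_total_force_residual_small(self, perturbed_sphere):
        f = total_forces(perturbed_sphere)
        assert np.abs(f.sum(0)).max() < 1e-10 * np.abs(f).max()

    def test_stretched_edge_force_matches_scalar_law(self, sphere_cell):
        cell = sphere_cell.copy()
        # stretch the whole mesh isotropically by 5%
        cell.vertices = cell.vertices * 1.05
        p = ElasticParams()
        f = link_forces(cell)
        # each vertex pulled inward; compare one edge's contribution using
        # an isolated two-vertex reconstruction
        a, b = cell.edges[0]
        L = np.linalg.norm(cell.vertices[b] - cell.vertices[a])
        dL = (L - cell.rest_lengths[0]) / cell.rest_lengths[0]
        assert dL > 0.049
        mag = abs(M.link_force_scalar(dL, p))
        assert mag > 0
        # inward direction: force opposes further inflation
        assert (f * cell.vertices).sum() < 0

    def test_area_forces_point_toward_centroid_when_inflated(self, sphere_cell):
        cell = sphere_cell.copy()
        cell.vertices = cell.vertices * 1.04
        f = area_forces(cell)
        v0 = cell.vertices[cell.faces[:, 0]]
        cent = cell.vertices[cell.faces].mean(axis=1)
        # force on each face's first vertex has positive component toward
        # that face's centroid
        contrib = np.einsum("ij,ij->i", f[cell.faces[:, 0]], cent - v0)
        assert (contrib > 0).mean() > 0.95

    def test_volume_forces_point_inward_when_inflated(self, sphere_cell):
        cell = sphere_cell.copy()
        cell.vertices = cell.vertices * (1 + 0.002)  # dV ~ 0.006 < tau_v
        f = volume_forces(cell)
        centroid = cell.centroid()
        inward = np.einsum("ij,ij->i", f, centroid - cell.vertices)
        assert np.all(inward > 0)

    @pytest.mark.parametrize("family", [
        (link_forces, link_energy),
        (bending_forces, bending_energy),
        (area_forces, area_energy),
        (volume_forces, volume_energy),
        (total_forces, total_energy),
    ], ids=["link", "bending", "area", "volume", "total"])
    def test_force_is_minus_energy_gradient(self, family, perturbed_sphere):
        force_fn, energy_fn = family
        cell = perturbed_sphere
        ana = force_fn(cell)
        eps = 1e-12
        check_vertices = range(0, cell.n_vertices, 7)
        num = []
        for i in check_vertices:
            row = []
            for k in range(3):
                cp = cell.copy()
                cp.vertices = cell.vertices.copy()
                cp.vertices[i, k] += eps
                cm = cell.copy()
                cm.vertices = cell.vertices.copy()
                cm.vertices[i, k] -= eps
                row.append(-(energy_fn(cp) - energy_fn(cm)) / (2 * eps))
            num.append(row)
        num = np.array(num)
        sel = ana[list(check_vertices)]
        scale = max(np.abs(num).max(), 1e-30)
        assert np.abs(sel - num).max() / scale < 1e-4

    def test_pole_crossing_is_hard_error(self, sphere_cell):
        cell = sphere_cell.copy()
        cell.vertices = cell.vertices * 3.5  # dL ~ 2.5 > tau_l
        with pytest.raises(MembraneStabilityError):
            link_forces(cell)
        cell2 = sphere_cell.copy()
        cell2.vertices = cell2.vertices * 1.01  # dV ~ 0.03 > tau_v = 0.01
        with pytest.raises(MembraneStabilityError):
            volume_forces(cell2)


class TestOverdampedRelaxation:
    def test_energy_decreases_monotonically(self, perturbed_sphere):
        cell = perturbed_sphere.copy()
        cell.vertices = perturbed_sphere.vertices.copy()
        # scale perturbation down so the volume strain stays inside tau_v
        c0 = cell.centroid()
        V = signed_volume(cell.vertices, cell.faces)
        cell.vertices = c0 + (cell.vertices - c0) * (
            cell.rest_volume / V) ** (1 / 3)
        energies = [total_energy(cell)]
        mob = 5e6
        for _ in range(30):
            cell.vertices = cell.vertices + mob * 1e-4 * total_forces(cell)
            energies.append(total_energy(cell))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-25)
        assert energies[-1] < 0.5 * energies[0]


class TestAdhesion:
    LJ = LennardJones(epsilon=1e-20, r_min=1e-6, cutoff=2.5e-6)

    def test_zero_force_at_minimum(self):
        assert np.isclose(self.LJ.force_magnitude(1e-6), 0.0, atol=1e-30)

    def test_zero_beyond_cutoff(self):
        assert self.LJ.force_magnitude(2.6e-6) == 0.0

    def test_attraction_beyond_minimum(self, sphere_cell):
        cell = sphere_cell.copy()
        cell.vertices = cell.vertices.copy()
        # one post node 1.5 r_min away from the closest vertex, along +x
        closest = cell.vertices[:, 0].argmax()
        node = cell.vertices[closest] + np.array([1.5e-6, 0, 0])
        f = adhesion_forces(cell, node[None], self.LJ)
        assert f[closest, 0] > 0  # pulled toward the node
        far = np.abs(f).sum(axis=1) == 0
        assert far.sum() > cell.n_vertices / 2  # only local vertices feel it


class TestMeshMeasures:
    def test_undeformed_rbc_cross_section(self, biconcave_cell):
        m = mesh_measures(biconcave_cell, axis=[1, 0, 0])
        assert np.isclose(m["h"], 8e-6, rtol=0.01)

    def test_unit_sphere_volume(self):
        cell = build_sphere_mesh(1.0, refinement=3)
        assert np.isclose(cell.rest_volume, np.pi / 6, rtol=0.01)

    def test_rotation_invariance(self, biconcave_cell, rng):
        m0 = mesh_measures(biconcave_cell, axis=[1, 0, 0])
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
        cell = biconcave_cell.copy()
        cell.vertices = cell.vertices @ R.T
        m1 = mesh_measures(cell, axis=R @ np.array([1, 0, 0]))
        assert np.isclose(m1["volume"], m0["volume"], rtol=1e-10)
        assert np.isclose(m1["area"], m0["area"], rtol=1e-10)
        assert np.isclose(m1["h"], m0["h"], rtol=1e-10)
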