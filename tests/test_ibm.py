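"""Immersed-boundary kernels: spreading, interpolation, advection, and
the coupled momentum bookkeeping."""

import numpy as np
import pytest

from ctcflow.ibm import (DeltaKernel, MembraneState, advect_membrane,
                         interpolate_velocities, spread_membrane_forces)
from ctcflow.lattice import FluidField, get_velocity_set, lbm_step, relaxation_time
from ctcflow.geometry import DomainSpec
from ctcflow.meshes import build_sphere_mesh, signed_volume
from ctcflow.membrane import ElasticParams
from ctcflow.simulate import Simulation
from ctcflow.units import UnitConverter

GRID = (12, 10, 8)


@pytest.mark.parametrize("name", ["linear", "cosine"])
class TestKernelProperties:
    def test_partition_of_unity(self, name, rng):
        kernel = DeltaKernel(name)
        X = rng.random((50, 3)) * GRID
        _, w = kernel.stencil(X, GRID)
        axis_sums = w.sum(axis=1)
        assert np.allclose(axis_sums, 1.0, atol=1e-12)

    def test_non_negative_compact(self, name, rng):
        kernel = DeltaKernel(name)
        X = rng.random((20, 3)) * GRID
        _, w = kernel.stencil(X, GRID)
        assert np.all(w >= -1e-15)
        assert w.shape[1] == kernel.support


class TestSpreading:
    def test_total_force_conserved(self, rng):
        kernel = DeltaKernel("cosine")
        state = MembraneState(X=rng.random((30, 3)) * GRID,
                              U=np.zeros((30, 3)),
                              F=rng.standard_normal((30, 3)))
        body = spread_membrane_forces(state, kernel, GRID)
        assert np.allclose(body.sum(axis=(1, 2, 3)), state.F.sum(axis=0),
                           atol=1e-12)

    def test_on_node_point_gets_everything(self):
        kernel = DeltaKernel("linear")
        state = MembraneState(X=np.array([[3.0, 4.0, 5.0]]),
                              U=np.zeros((1, 3)),
                              F=np.array([[1.0, -2.0, 0.5]]))
        body = spread_membrane_forces(state, kernel, GRID)
        assert np.allclose(body[:, 3, 4, 5], [1.0, -2.0, 0.5])
        assert np.isclose(np.abs(body).sum(), 3.5)

    def test_midpoint_splits_equally(self):
        kernel = DeltaKernel("linear")
        state = MembraneState(X=np.array([[3.5, 4.0, 5.0]]),
                              U=np.zeros((1, 3)),
                              F=np.array([[2.0, 0.0, 0.0]]))
        body = spread_membrane_forces(state, kernel, GRID)
        assert np.isclose(body[0, 3, 4, 5], 1.0)
        assert np.isclose(body[0, 4, 4, 5], 1.0)

    def test_non_finite_position_rejected(self):
        kernel = DeltaKernel("linear")
        state = MembraneState(X=np.array([[np.nan, 0, 0]]),
                              U=np.zeros((1, 3)), F=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            spread_membrane_forces(state, kernel, GRID)


class TestInterpolation:
    def test_constant_field_reproduced(self, rng):
        u = np.ones((3, *GRID)) * np.array([0.3, -0.1, 0.7])[:, None, None, None]
        X = rng.random((40, 3)) * (np.array(GRID) - 4) + 2
        for name in ("linear", "cosine"):
            U = interpolate_velocities(u, X, DeltaKernel(name))
            assert np.allclose(U, [0.3, -0.1, 0.7], atol=1e-12)

    def test_linear_shear_field_exact_with_hat_kernel(self, rng):
        gdot = 0.01
        z = np.arange(GRID[2], dtype=float)
        u = np.zeros((3, *GRID))
        u[0] = gdot * z[None, None, :]
        X = np.column_stack([rng.random(25) * GRID[0],
                             rng.random(25) * GRID[1],
                             rng.random(25) * (GRID[2] - 3) + 1])
        U = interpolate_velocities(u, X, DeltaKernel("linear"))
        assert np.allclose(U[:, 0], gdot * X[:, 2], atol=1e-12)

    def test_vertex_on_node(self):
        u = np.zeros((3, *GRID))
        u[1, 5, 5, 5] = 0.42
        U = interpolate_velocities(u, np.array([[5.0, 5.0, 5.0]]),
                                   DeltaKernel("linear"))
        assert np.isclose(U[0, 1], 0.42)


class TestAdvection:
    def test_zero_velocity_keeps_positions(self):
        state = MembraneState(X=np.array([[1.0, 2.0, 3.0]]),
                              U=np.zeros((1, 3)), F=np.zeros((1, 3)))
        advect_membrane(state, dt=1.0)
        assert np.allclose(state.X, [[1.0, 2.0, 3.0]])

    def test_constant_velocity_forward_euler(self):
        state = MembraneState(X=np.array([[1.0, 2.0, 3.0]]),
                              U=np.array([[0.1, -0.2, 0.05]]),
                              F=np.zeros((1, 3)))
        advect_membrane(state, dt=0.5)
        assert np.allclose(state.X, [[1.05, 1.9, 3.025]])

    def test_matches_independent_euler_oracle(self, rng):
        X = rng.random((15, 3)) * GRID
        U = 0.3 * rng.standard_normal((15, 3))
        expected = np.mod(X + 0.8 * U, GRID)  # independent explicit Euler
        state = MembraneState(X=X.copy(), U=U, F=np.zeros_like(U))
        advect_membrane(state, dt=0.8, periodic_shape=GRID)
        assert np.allclose(state.X, expected, atol=1e-14)

    def test_large_step_logged(self, caplog):
        state = MembraneState(X=np.zeros((1, 3)),
                              U=np.array([[3.0, 0, 0]]),
                              F=np.zeros((1, 3)))
        import logging
        with caplog.at_level(logging.WARNING, logger="ctcflow.ibm"):
            advect_membrane(state, dt=1.0)
        assert any("IBM" in r.message for r in caplog.records)


class TestCoupledMomentum:
    def test_spread_force_enters_fluid_momentum(self, rng):
        """Momentum injected by spreading equals sum(F) dt per step."""
        vset = get_velocity_set()
        field = FluidField(GRID, vset)
        kernel = DeltaKernel("cosine")
        relax = relaxation_time(1 / 6, 1.0, 1.0)
        F = 1e-5 * rng.standard_normal((20, 3))
        X = rng.random((20, 3)) * GRID
        mom0 = field.momentum()
        for _ in range(3):
            state = MembraneState(X=X, U=np.zeros_like(X), F=F)
            field.body_force = spread_membrane_forces(state, kernel, GRID)
            lbm_step(field, relax)
        gained = field.momentum() - mom0
        assert np.allclose(gained, 3 * F.sum(axis=0), rtol=1e-9)


class TestNeutralSphereAdvection:
    def test_translates_at_flow_speed_with_small_volume_drift(self):
        """A membrane sphere in uniform flow moves with the flow (no-slip)
        and keeps its enclosed volume."""
        conv = UnitConverter(dx=1e-6, dt=1e-7)
        dom = DomainSpec(size=(24e-6, 16e-6, 16e-6), dx=1e-6)  # periodic
        cell = build_sphere_mesh(8e-6, refinement=1, params=ElasticParams())
        cell.translate(np.array([8e-6, 8e-6, 8e-6]) - cell.centroid())
        G = 5.0  # N/m^3 driving, fully periodic -> uniform acceleration
        sim = Simulation(dom, conv, nu_p=1e-6, cells=[cell],
                         body_force=(G, 0.0, 0.0))
        V0 = cell.rest_volume
        com0 = cell.centroid()
        n = 800
        for _ in range(n):
            sim.step()
        # uniform periodic forcing: u(t) = G t / rho, cell displacement
        # integrates to G t^2 / (2 rho)
        t = sim.time
        expected_disp = G * t**2 / (2 * 1e3)
        disp = (cell.centroid() - com0)[0]
        assert np.isclose(disp, expected_disp, rtol=0.02)
        V = signed_volume(cell.vertices, cell.faces)
        assert abs(V - V0) / V0 < 0.01
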