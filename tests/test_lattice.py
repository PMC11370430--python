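"""Fluid-solver unit tests: velocity sets, equilibrium, collision,
streaming, moments, and the two analytic channel flows."""

import numpy as np
import pytest

from ctcflow.geometry import DomainSpec, FaceBC, voxelize_scene
from ctcflow.lattice import (CS2, FluidField, StabilityError,
                             bgk_collision_step, equilibrium_populations,
                             get_velocity_set, lbm_step, macroscopic_fields,
                             relaxation_time, streaming_step)
from ctcflow.units import UnitConverter


@pytest.fixture(scope="module")
def d3q19():
    return get_velocity_set("D3Q19")


@pytest.mark.parametrize("name", ["D3Q19", "D3Q27"])
def test_velocity_set_invariants(name):
    vs = get_velocity_set(name)
    assert np.isclose(vs.w.sum(), 1.0)
    assert np.all(vs.w > 0)
    assert np.allclose((vs.w[:, None] * vs.c).sum(0), 0.0)
    assert np.array_equal(vs.c[vs.opposite], -vs.c)
    # second moment isotropy: sum w c_a c_b = cs^2 delta_ab
    second = np.einsum("i,ia,ib->ab", vs.w, vs.c.astype(float),
                       vs.c.astype(float))
    assert np.allclose(second, CS2 * np.eye(3))


class TestEquilibrium:
    def test_rest_state_gives_weights(self, d3q19):
        rho = np.ones((3, 3, 3))
        u = np.zeros((3, 3, 3, 3))
        feq = equilibrium_populations(rho, u, d3q19)
        assert np.allclose(feq, d3q19.w[:, None, None, None] * rho[None])
        assert np.allclose(feq.sum(axis=0), 1.0)

    def test_linear_in_density(self, d3q19):
        rho = np.zeros((2, 2, 2))
        feq = equilibrium_populations(rho, np.zeros((3, 2, 2, 2)), d3q19)
        assert np.all(feq == 0.0)

    def test_moments_match_direct_summation(self, d3q19, rng):
        # the zeroth/first moments of f_eq must recover rho and rho*u
        rho = 1.0 + 0.05 * rng.random((4, 3, 2))
        u = 0.02 * rng.standard_normal((3, 4, 3, 2))
        feq = equilibrium_populations(rho, u, d3q19)
        assert np.allclose(feq.sum(axis=0), rho, atol=1e-14)
        mom = np.tensordot(d3q19.c.astype(float).T, feq, axes=([1], [0]))
        assert np.allclose(mom, rho[None] * u, atol=1e-14)

    def test_rejects_non_finite_input(self, d3q19):
        rho = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError):
            equilibrium_populations(rho, np.zeros((3, 2, 2, 2)), d3q19)


class TestRelaxationTime:
    def test_inverts_lattice_viscosity(self):
        # nu_lbm = 1/6 corresponds to tau = 1
        spec = relaxation_time(nu_p=(1 / 6), dx=1.0, dt=1.0)
        assert np.isclose(spec.tau, 1.0)

    def test_zero_viscosity_limit_flagged(self):
        with pytest.warns(RuntimeWarning):
            spec = relaxation_time(nu_p=0.0, dx=1e-6, dt=1e-7)
        assert spec.tau == 0.5
        with pytest.raises(StabilityError):
            spec.require_stable()

    def test_plasma_parameters(self):
        # water-like plasma at dx = 0.5 um, dt = 0.05 us
        spec = relaxation_time(nu_p=1.0e-6, dx=0.5e-6, dt=0.5e-7)
        assert np.isclose(spec.nu_lbm, 0.2)
        assert np.isclose(spec.tau, 1.1)


class TestCollision:
    def _field(self, d3q19, shape=(4, 4, 4), u_amp=0.0, seed=0):
        r = np.random.default_rng(seed)
        u = u_amp * r.standard_normal((3, *shape))
        return FluidField(shape, d3q19, rho=1.0, u=u)

    def test_equilibrium_is_fixed_point(self, d3q19):
        field = self._field(d3q19, u_amp=0.01)
        before = field.f.copy()
        relax = relaxation_time(1 / 6, 1.0, 1.0)
        bgk_collision_step(field, relax, backend="numpy")
        assert np.allclose(field.f, before, atol=1e-14)

    def test_full_relaxation_at_tau_one(self, d3q19):
        field = self._field(d3q19, u_amp=0.01, seed=1)
        field.f += 1e-3 * np.random.default_rng(2).random(field.f.shape)
        field.update_moments()
        feq = equilibrium_populations(field.rho, field.u, d3q19)
        relax = relaxation_time(1 / 6, 1.0, 1.0)
        bgk_collision_step(field, relax, backend="numpy")
        assert np.allclose(field.f, feq, atol=1e-14)

    def test_momentum_input_rate_equals_force(self, d3q19):
        # uniform resting fluid with constant body force: the macroscopic
        # momentum (with the half-force shift) grows by f per unit step
        field = self._field(d3q19)
        f0 = np.array([1e-4, -2e-4, 5e-5])
        relax = relaxation_time(0.8 / 3, 1.0, 1.0)
        mom = []
        for _ in range(4):
            field.body_force[:] = f0[:, None, None, None]
            lbm_step(field, relax)
            mom.append(field.momentum() / np.prod(field.shape))
        gains = np.diff(np.array(mom), axis=0)
        assert np.allclose(gains, f0[None], rtol=1e-10)

    def test_unphysical_tau_rejected(self, d3q19):
        field = self._field(d3q19)
        bad = relaxation_time(1 / 6, 1.0, 1.0)
        object.__setattr__(bad, "tau", 0.4)
        with pytest.raises(StabilityError):
            bgk_collision_step(field, bad)

    def test_numba_matches_numpy(self, d3q19):
        field_a = self._field(d3q19, u_amp=0.02, seed=3)
        field_a.body_force[:] = 1e-4
        field_a.update_moments()
        field_b = FluidField(field_a.shape, d3q19)
        field_b.f = field_a.f.copy()
        field_b.body_force = field_a.body_force.copy()
        field_b.rho, field_b.u = field_a.rho.copy(), field_a.u.copy()
        relax = relaxation_time(0.9 / 3, 1.0, 1.0)
        bgk_collision_step(field_a, relax, backend="numpy")
        bgk_collision_step(field_b, relax, backend="numba")
        assert np.allclose(field_a.f, field_b.f, atol=1e-14)


class TestStreaming:
    def test_uniform_periodic_invariance(self, d3q19):
        field = FluidField((4, 5, 6), d3q19)
        before = field.f.copy()
        streaming_step(field, mask=None)
        assert np.allclose(field.f, before)

    def test_halfway_bounce_back_reverses(self, d3q19):
        conv = UnitConverter(dx=1e-6, dt=1e-7)
        dom = DomainSpec(size=(4e-6, 4e-6, 4e-6), dx=1e-6,
                         bc={"z-": FaceBC("wall"), "z+": FaceBC("wall")})
        mask = voxelize_scene(dom, converter=conv)
        field = FluidField(dom.grid_shape, d3q19, rho=1.0)
        field.f[:] = 0.0
        i_up = next(i for i, c in enumerate(d3q19.c)
                    if tuple(c) == (0, 0, 1))
        kz_top = dom.grid_shape[2] - 2  # last fluid layer
        field.f[i_up, 2, 2, kz_top] = 0.7
        streaming_step(field, mask)
        j = d3q19.opposite[i_up]
        assert np.isclose(field.f[j, 2, 2, kz_top], 0.7)

    def test_mass_conserved_with_resting_walls(self, d3q19, rng):
        conv = UnitConverter(dx=1e-6, dt=1e-7)
        dom = DomainSpec(size=(5e-6, 4e-6, 4e-6), dx=1e-6,
                         bc={"z-": FaceBC("wall"), "z+": FaceBC("wall")})
        mask = voxelize_scene(dom, converter=conv)
        field = FluidField(dom.grid_shape, d3q19, rho=1.0,
                           u=0.01 * rng.standard_normal((3, *dom.grid_shape)))
        fluid = mask.fluid
        m0 = field.f[:, fluid].sum()
        relax = relaxation_time(1 / 6, 1.0, 1.0)
        for _ in range(50):
            lbm_step(field, relax, mask)
        assert np.isclose(field.f[:, fluid].sum(), m0, rtol=1e-12)

    def test_shape_mismatch_rejected(self, d3q19):
        conv = UnitConverter(dx=1e-6, dt=1e-7)
        dom = DomainSpec(size=(4e-6, 4e-6, 4e-6), dx=1e-6,
                         bc={"z-": FaceBC("wall"), "z+": FaceBC("wall")})
        mask = voxelize_scene(dom, converter=conv)
        field = FluidField((3, 3, 3), d3q19)
        with pytest.raises(ValueError):
            streaming_step(field, mask)


class TestMacroscopic:
    def test_weights_give_unit_rest_state(self, d3q19):
        f = np.broadcast_to(d3q19.w[:, None, None, None],
                            (19, 2, 2, 2)).copy()
        rho, u = macroscopic_fields(f, np.zeros((3, 2, 2, 2)), d3q19)
        assert np.allclose(rho, 1.0)
        assert np.allclose(u, 0.0)
        rho2, u2 = macroscopic_fields(2 * f, np.zeros((3, 2, 2, 2)), d3q19)
        assert np.allclose(rho2, 2.0)
        assert np.allclose(u2, 0.0)

    def test_round_trip_with_equilibrium(self, d3q19, rng):
        rho = 1.0 + 0.03 * rng.random((3, 3, 3))
        u = 0.02 * rng.standard_normal((3, 3, 3, 3))
        feq = equilibrium_populations(rho, u, d3q19)
        rho2, u2 = macroscopic_fields(feq, np.zeros((3, 3, 3, 3)), d3q19)
        assert np.allclose(rho2, rho, atol=1e-14)
        assert np.allclose(u2, u, atol=1e-14)

    def test_blowup_detected(self, d3q19):
        f = -np.ones((19, 2, 2, 2))
        with pytest.raises(StabilityError):
            macroscopic_fields(f, np.zeros((3, 2, 2, 2)), d3q19)


def _couette_error(nz):
    dx = 10e-6 / nz
    conv = UnitConverter(dx=dx, dt=dx**2 / 1e-6 * 0.2)
    gdot, d = 1000.0, 10e-6
    v0 = gdot * d / 2
    dom = DomainSpec(size=(2 * dx, 2 * dx, d), dx=dx,
                     bc={"z-": FaceBC("moving_wall", (-v0, 0, 0)),
                         "z+": FaceBC("moving_wall", (v0, 0, 0))})
    mask = voxelize_scene(dom, converter=conv)
    vs = get_velocity_set()
    relax = relaxation_time(1e-6, conv.dx, conv.dt)
    field = FluidField(dom.grid_shape, vs)
    for _ in range(150 * nz):
        lbm_step(field, relax, mask)
    z = dom.node_centers()[2]
    fluid = mask.fluid[1, 1, :]
    uf = field.u[0, 1, 1, :][fluid] * conv.velocity_scale
    exact = gdot * (z[fluid] - d / 2)
    return np.linalg.norm(uf - exact) / np.linalg.norm(exact)


def test_couette_linear_profile():
    """Counter-moving plates give the linear profile u = gdot (z - d/2)."""
    assert _couette_error(12) < 1e-6


def _poiseuille_error(nz, steps=None):
    d = 10e-6
    dx = d / nz
    conv = UnitConverter(dx=dx, dt=dx**2 / 1e-6 * 0.2)
    dom = DomainSpec(size=(2 * dx, 2 * dx, d), dx=dx,
                     bc={"z-": FaceBC("wall"), "z+": FaceBC("wall")})
    mask = voxelize_scene(dom, converter=conv)
    vs = get_velocity_set()
    relax = relaxation_time(1e-6, conv.dx, conv.dt)
    G = 3.2e4  # N/m^3
    g_lat = G / conv.force_density_scale
    field = FluidField(dom.grid_shape, vs)
    for _ in range(steps or 300 * nz):
        field.body_force[:] = 0.0
        field.body_force[0] = g_lat
        lbm_step(field, relax, mask)
    z = dom.node_centers()[2]
    fluid = mask.fluid[1, 1, :]
    uf = field.u[0, 1, 1, :][fluid] * conv.velocity_scale
    exact = G / (2 * 1e3 * 1e-6) * z[fluid] * (d - z[fluid])
    return np.linalg.norm(uf - exact) / np.linalg.norm(exact)


def test_poiseuille_profile_and_convergence():
    """Body-force channel flow matches the parabola; error shrinks with dx."""
    err_coarse = _poiseuille_error(10)
    err_fine = _poiseuille_error(20)
    assert err_coarse < 0.02
    assert err_fine < err_coarse
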