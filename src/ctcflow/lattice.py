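"""Forced BGK lattice-Boltzmann solver for incompressible plasma flow.

Populations ``f_i(x, t)`` evolve on a 3D lattice by collide-and-stream:

    f_i(x + c_i, t + 1) - f_i(x, t) = -(f_i - f_i^eq)/tau + F_i

with the second-order (Guo) forcing term

    F_i = (1 - 1/(2 tau)) w_i [ (c_i - u)/c_s^2 + (c_i . u) c_i / c_s^4 ] . f

and the half-force velocity shift in the macroscopic momentum,
``rho u = sum_i f_i c_i + f/2``. Everything here is in lattice units
(dx = dt = 1); :class:`ctcflow.units.UnitConverter` handles the mapping
to SI.

Boundaries are handled by halfway bounce-back (resting and moving walls)
plus periodic wrap, driven by a :class:`ctcflow.geometry.BoundaryMask`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CS2 = 1.0 / 3.0  # lattice speed of sound squared

try:  # fused collision kernel; the numpy path below stays the reference
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _collide_kernel(f, rho, u, g, c, w, tau):  # pragma: no cover - jit
        q, n = f.shape
        pref = 1.0 - 0.5 / tau
        inv_tau = 1.0 / tau
        for k in range(n):
            ux, uy, uz = u[0, k], u[1, k], u[2, k]
            gx, gy, gz = g[0, k], g[1, k], g[2, k]
            usq = ux * ux + uy * uy + uz * uz
            uf = ux * gx + uy * gy + uz * gz
            r = rho[k]
            for i in range(q):
                cu = c[i, 0] * ux + c[i, 1] * uy + c[i, 2] * uz
                cf = c[i, 0] * gx + c[i, 1] * gy + c[i, 2] * gz
                feq = w[i] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
                forcing = pref * w[i] * (3.0 * (cf - uf) + 9.0 * cu * cf)
                f[i, k] += -(f[i, k] - feq) * inv_tau + forcing

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


class StabilityError(RuntimeError):
    """Raised when the simulation enters an unphysical state."""


# ---------------------------------------------------------------------------
# velocity sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VelocitySet:
    """A discrete velocity set (abscissae + weights of the lattice quadrature).

    Invariants: weights sum to 1, first moment vanishes, and the set is
    closed under negation (required by bounce-back); ``opposite[i]`` gives
    the index of ``-c[i]``.
    """

    name: str
    c: np.ndarray        # (q, 3) int
    w: np.ndarray        # (q,) float
    opposite: np.ndarray  # (q,) int

    @property
    def q(self) -> int:
        return len(self.w)

    @property
    def cs2(self) -> float:
        return CS2

    def validate(self) -> None:
        if not np.isclose(self.w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if np.any(self.w <= 0):
            raise ValueError("weights must be positive")
        if not np.allclose((self.w[:, None] * self.c).sum(0), 0.0):
            raise ValueError("first moment of the velocity set must vanish")
        if not np.array_equal(self.c[self.opposite], -self.c):
            raise ValueError("velocity set must be closed under negation")


def _build_opposites(c: np.ndarray) -> np.ndarray:
    opp = np.empty(len(c), dtype=np.int64)
    for i, ci in enumerate(c):
        matches = np.where((c == -ci).all(axis=1))[0]
        if len(matches) != 1:
            raise ValueError("velocity set is not closed under negation")
        opp[i] = matches[0]
    return opp


def d3q19() -> VelocitySet:
    """Standard D3Q19 set: rest, 6 axis, 12 face-diagonal velocities."""
    c = [(0, 0, 0)]
    c += [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    diag = []
    for a in range(3):
        for b in range(a + 1, 3):
            for sa in (1, -1):
                for sb in (1, -1):
                    v = [0, 0, 0]
                    v[a], v[b] = sa, sb
                    diag.append(tuple(v))
    c += diag
    c = np.array(c, dtype=np.int64)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    vs = VelocitySet("D3Q19", c, w, _build_opposites(c))
    vs.validate()
    return vs


def d3q27() -> VelocitySet:
    """D3Q27 (full 3x3x3 stencil); drop-in alternative to D3Q19."""
    c, w = [], []
    wmap = {0: 8 / 27, 1: 2 / 27, 2: 1 / 54, 3: 1 / 216}
    for x in (0, 1, -1):
        for y in (0, 1, -1):
            for z in (0, 1, -1):
                c.append((x, y, z))
                w.append(wmap[abs(x) + abs(y) + abs(z)])
    c = np.array(c, dtype=np.int64)
    w = np.array(w)
    vs = VelocitySet("D3Q27", c, w, _build_opposites(c))
    vs.validate()
    return vs


def get_velocity_set(name: str = "D3Q19") -> VelocitySet:
    try:
        return {"D3Q19": d3q19, "D3Q27": d3q27}[name.upper()]()
    except KeyError:
        raise ValueError(f"unknown velocity set {name!r}") from None


# ---------------------------------------------------------------------------
# relaxation time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationSpec:
    """Relaxation time tau and the viscosities it encodes.

    nu_lbm = (tau - 1/2)/3 and nu_p = (dx^2/dt) nu_lbm; tau must exceed
    1/2 for a positive viscosity.
    """

    tau: float
    nu_lbm: float
    nu_p: float
    dx: float
    dt: float

    def require_stable(self) -> None:
        if self.tau <= 0.5:
            raise StabilityError(
                f"tau={self.tau} <= 0.5 implies non-positive viscosity"
            )


def relaxation_time(nu_p: float, dx: float, dt: float,
                    tau_max: float = 3.0) -> RelaxationSpec:
    """Convert a physical kinematic viscosity to a relaxation time.

    tau = 3 nu_p dt / dx^2 + 1/2. Values of tau outside (0.5, tau_max]
    are flagged (tau near 0.5 is unstable; large tau degrades accuracy).
    """
    if nu_p < 0:
        raise ValueError("physical viscosity must be non-negative")
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    nu_lbm = nu_p * dt / dx**2
    tau = 3.0 * nu_lbm + 0.5
    if tau <= 0.5 or tau > tau_max:
        warnings.warn(
            f"tau={tau:.4g} outside the stability window (0.5, {tau_max}]",
            RuntimeWarning, stacklevel=2,
        )
    return RelaxationSpec(tau=tau, nu_lbm=nu_lbm, nu_p=nu_p, dx=dx, dt=dt)


# ---------------------------------------------------------------------------
# fluid field
# ---------------------------------------------------------------------------

class FluidField:
    """Populations plus derived density/velocity/body-force fields.

    Arrays are laid out as ``f[(q, nx, ny, nz)]``, ``u[(3, nx, ny, nz)]``.
    ``rho`` and ``u`` are kept consistent with the moments of ``f`` by
    :func:`macroscopic_fields`, which every step calls.
    """

    def __init__(self, shape: tuple[int, int, int], vset: VelocitySet,
                 rho: float | np.ndarray = 1.0,
                 u: np.ndarray | None = None):
        self.vset = vset
        self.shape = tuple(shape)
        rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), self.shape).copy()
        if u is None:
            u_arr = np.zeros((3, *self.shape))
        else:
            u_arr = np.array(u, dtype=float).reshape((3, *self.shape))
        self.f = equilibrium_populations(rho_arr, u_arr, vset)
        self.body_force = np.zeros((3, *self.shape))
        self.rho = rho_arr
        self.u = u_arr

    def update_moments(self) -> None:
        self.rho, self.u = macroscopic_fields(self.f, self.body_force, self.vset)

    @property
    def total_mass(self) -> float:
        return float(self.f.sum())

    def momentum(self) -> np.ndarray:
        """Total macroscopic momentum (including the half-force shift)."""
        return (self.rho * self.u).sum(axis=(1, 2, 3))


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def equilibrium_populations(rho: np.ndarray, u: np.ndarray,
                            vset: VelocitySet) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium.

    f_i^eq = w_i rho [1 + c.u/cs^2 + (c.u)^2/(2 cs^4) - u.u/(2 cs^2)]
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite density or velocity field")
    cu = np.tensordot(vset.c.astype(float), u, axes=([1], [0]))  # (q, ...)
    usq = (u * u).sum(axis=0)
    feq = 1.0 + cu / CS2 + 0.5 * cu**2 / CS2**2 - 0.5 * usq / CS2
    feq *= rho[None]
    feq *= vset.w.reshape((-1,) + (1,) * rho.ndim)
    return feq


def macroscopic_fields(f: np.ndarray, body_force: np.ndarray,
                       vset: VelocitySet,
                       fluid_mask: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Zeroth/first moments of the populations.

    rho = sum_i f_i;  u = (sum_i f_i c_i + f/2) / rho  (Guo half-force shift).
    A non-positive density on a fluid node signals blow-up and is a hard
    error.
    """
    if not np.all(np.isfinite(f)):
        raise StabilityError("non-finite populations: simulation blow-up")
    rho = f.sum(axis=0)
    mom = np.tensordot(vset.c.astype(float).T, f, axes=([1], [0]))
    mom = mom + 0.5 * body_force
    check = rho if fluid_mask is None else rho[fluid_mask]
    if check.size and check.min() <= 0:
        raise StabilityError("non-positive density on a fluid node")
    u = mom / np.where(rho == 0, 1.0, rho)[None]
    return rho, u


def guo_forcing_term(u: np.ndarray, body_force: np.ndarray, tau: float,
                     vset: VelocitySet) -> np.ndarray:
    """Guo forcing contribution F_i (already includes the (1-1/2tau) factor)."""
    c = vset.c.astype(float)
    cu = np.tensordot(c, u, axes=([1], [0]))             # (q, ...)
    cf = np.tensordot(c, body_force, axes=([1], [0]))    # (q, ...)
    uf = (u * body_force).sum(axis=0)                    # (...)
    term = (cf - uf) / CS2 + cu * cf / CS2**2
    term *= vset.w.reshape((-1,) + (1,) * u[0].ndim)
    term *= (1.0 - 0.5 / tau)
    return term


def bgk_collision_step(field: FluidField, relax: RelaxationSpec,
                       vset: VelocitySet | None = None,
                       mach_cap: float = 0.1,
                       backend: str = "auto") -> FluidField:
    """BGK relaxation toward equilibrium plus Guo forcing (in place).

    Assumes ``field.rho``/``field.u`` are the current moments. Raises if
    tau <= 0.5 and warns when the Mach-number guard is exceeded. The
    fused compiled kernel ("numba") and the vectorized numpy path
    ("numpy") compute the identical update; "auto" prefers the former.
    """
    relax.require_stable()
    vset = vset or field.vset
    umax = np.sqrt((field.u**2).sum(axis=0)).max()
    if umax / np.sqrt(CS2) > mach_cap:
        logger.warning(
            "Mach guard exceeded: max |u|/c_s = %.3f > %.3f",
            umax / np.sqrt(CS2), mach_cap,
        )
    if backend == "auto":
        backend = "numba" if _HAVE_NUMBA else "numpy"
    if backend == "numba" and not all(
            a.flags.c_contiguous for a in
            (field.f, field.rho, field.u, field.body_force)):
        backend = "numpy"
    if backend == "numba":
        n = int(np.prod(field.shape))
        _collide_kernel(field.f.reshape(vset.q, n),
                        field.rho.reshape(n),
                        field.u.reshape(3, n),
                        field.body_force.reshape(3, n),
                        vset.c.astype(np.float64), vset.w, relax.tau)
    else:
        feq = equilibrium_populations(field.rho, field.u, vset)
        field.f += -(field.f - feq) / relax.tau
        field.f += guo_forcing_term(field.u, field.body_force, relax.tau, vset)
    return field


def streaming_step(field: FluidField, mask=None) -> FluidField:
    """Advect populations one link; apply bounce-back and periodic wrap.

    ``mask`` is a :class:`ctcflow.geometry.BoundaryMask` (or None for fully
    periodic). Halfway bounce-back: a post-collision population leaving a
    fluid node toward a solid node returns reversed to the same node, with
    the moving-wall momentum correction -2 w_i rho (c_i . u_w)/c_s^2 when
    the wall carries a velocity. np.roll provides the periodic wrap.
    """
    vset = field.vset
    f = field.f
    if mask is not None and mask.solid.shape != field.shape:
        raise ValueError("boundary mask shape does not match fluid grid")

    streamed = np.empty_like(f)
    for i in range(vset.q):
        ci = vset.c[i]
        streamed[i] = np.roll(f[i], shift=tuple(ci), axis=(0, 1, 2))

    if mask is not None and mask.solid.any():
        cache = _bounce_back_cache(mask, vset)
        rho_flat = f.sum(axis=0).ravel()
        f_flat = f.reshape(vset.q, -1)
        s_flat = streamed.reshape(vset.q, -1)
        for i, j, fix_idx, wall_coeff in cache:
            s_flat[i, fix_idx] = f_flat[j, fix_idx]
            if wall_coeff is not None:
                s_flat[i, fix_idx] += rho_flat[fix_idx] * wall_coeff
        # park solid-node populations at their weights (inert)
        streamed[:, mask.solid] = vset.w[:, None]
    field.f = streamed
    return field


def _bounce_back_cache(mask, vset: VelocitySet):
    """Precompute, per direction, which nodes receive bounced populations.

    The geometry and wall velocities are static, so the flat node indices
    and the moving-wall momentum coefficients 2 w_i (c_i . u_w)/c_s^2 are
    computed once and attached to the mask.
    """
    key = getattr(mask, "_bb_cache_key", None)
    if key == vset.name:
        return mask._bb_cache
    solid = mask.solid
    wall_u = mask.wall_velocity
    cache = []
    for i in range(vset.q):
        ci = vset.c[i]
        if not ci.any():
            continue
        src_solid = np.roll(solid, shift=tuple(ci), axis=(0, 1, 2))
        fix = src_solid & ~solid
        if not fix.any():
            continue
        j = int(vset.opposite[i])
        fix_idx = np.flatnonzero(fix.ravel())
        wall_coeff = None
        if wall_u is not None:
            uw = np.roll(wall_u, shift=tuple(ci), axis=(1, 2, 3))
            cdotu = np.tensordot(ci.astype(float),
                                 uw.reshape(3, -1)[:, fix_idx], axes=1)
            if np.any(cdotu):
                wall_coeff = 2.0 * vset.w[i] * cdotu / CS2
        cache.append((i, j, fix_idx, wall_coeff))
    mask._bb_cache = cache
    mask._bb_cache_key = vset.name
    return cache


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def lbm_step(field: FluidField, relax: RelaxationSpec, mask=None) -> FluidField:
    """One full collide-stream-moments cycle."""
    bgk_collision_step(field, relax)
    streaming_step(field, mask)
    fluid = None if mask is None else ~mask.solid
    field.rho, field.u = macroscopic_fields(field.f, field.body_force,
                                            field.vset, fluid_mask=fluid)
    if mask is not None:
        field.u[:, mask.solid] = 0.0
    return field
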