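"""Immersed-boundary coupling between membrane vertices and the fluid grid.

Membrane forces are spread to the lattice with a regularized discrete
delta, f(x) = sum_i F(X_i) delta(x - X_i); fluid velocities are
interpolated back with the same kernel, U(X_i) = sum_x u(x) delta(X_i - x);
vertices advect by forward Euler. All positions here are in lattice
coordinates (node i sits at coordinate i); the simulation layer owns the
physical <-> lattice transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MembraneState:
    """Lagrangian state: positions, velocities, forces per vertex (lattice units)."""

    X: np.ndarray   # (n, 3)
    U: np.ndarray   # (n, 3)
    F: np.ndarray   # (n, 3)

    def __post_init__(self):
        if not (self.X.shape == self.U.shape == self.F.shape):
            raise ValueError("membrane state arrays must be congruent")


def _phi_linear(r: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - np.abs(r))


def _phi_cosine(r: np.ndarray) -> np.ndarray:
    out = 0.25 * (1.0 + np.cos(np.pi * r / 2.0))
    return np.where(np.abs(r) < 2.0, out, 0.0)


@dataclass(frozen=True)
class DeltaKernel:
    """Separable discrete delta with compact support.

    "linear": 2-point hat (reproduces linear fields exactly);
    "cosine": 4-point Peskin cosine kernel (default, smoother).
    Both are non-negative and a partition of unity for any offset.
    """

    name: str = "cosine"

    @property
    def support(self) -> int:
        return {"linear": 2, "cosine": 4}[self.name]

    def phi(self, r: np.ndarray) -> np.ndarray:
        return {"linear": _phi_linear, "cosine": _phi_cosine}[self.name](r)

    def stencil(self, X: np.ndarray, shape: tuple[int, int, int]):
        """Node indices and weights covering each point.

        Returns ``idx``: (n, s, 3) wrapped integer indices per axis and
        ``w``: (n, s, 3) per-axis weights, with s the support width.
        """
        X = np.asarray(X, dtype=float)
        s = self.support
        base = np.floor(X).astype(np.int64) - (s // 2 - 1)
        offs = np.arange(s)
        idx = base[:, None, :] + offs[None, :, None]          # (n, s, 3)
        r = idx - X[:, None, :]
        w = self.phi(r)
        wrapped = np.mod(idx, np.array(shape)[None, None, :])
        return wrapped, w


def spread_membrane_forces(state: MembraneState, kernel: DeltaKernel,
                           grid_shape: tuple[int, int, int],
                           out: np.ndarray | None = None) -> np.ndarray:
    """Spread vertex forces onto the grid; conserves total force exactly.

    Returns a (3, nx, ny, nz) body-force field. Vertices are assumed
    inside the (periodic image of the) domain; the caller clips or wraps
    beforehand and decides what to do about force landing in solid nodes.
    """
    nx, ny, nz = grid_shape
    if out is None:
        out = np.zeros((3, nx, ny, nz))
    if not np.all(np.isfinite(state.X)):
        raise ValueError("membrane vertex left the domain (non-finite position)")
    idx, w = kernel.stencil(state.X, grid_shape)
    s = kernel.support
    # combined weights (n, s, s, s) and flat node index
    W = np.einsum("na,nb,nc->nabc", w[:, :, 0], w[:, :, 1], w[:, :, 2])
    flat = (idx[:, :, 0][:, :, None, None] * ny * nz
            + idx[:, :, 1][:, None, :, None] * nz
            + idx[:, :, 2][:, None, None, :])
    flat = np.broadcast_to(flat, (len(state.X), s, s, s)).ravel()
    for comp in range(3):
        np.add.at(out[comp].ravel(), flat,
                  (W * state.F[:, comp, None, None, None]).ravel())
    return out


def interpolate_velocities(u: np.ndarray, positions: np.ndarray,
                           kernel: DeltaKernel) -> np.ndarray:
    """Interpolate the grid velocity field at the given vertex positions."""
    grid_shape = u.shape[1:]
    idx, w = kernel.stencil(positions, grid_shape)
    W = np.einsum("na,nb,nc->nabc", w[:, :, 0], w[:, :, 1], w[:, :, 2])
    ny, nz = grid_shape[1], grid_shape[2]
    flat = (idx[:, :, 0][:, :, None, None] * ny * nz
            + idx[:, :, 1][:, None, :, None] * nz
            + idx[:, :, 2][:, None, None, :])
    flat = np.broadcast_to(flat, W.shape)
    out = np.empty((len(positions), 3))
    for comp in range(3):
        out[:, comp] = (u[comp].ravel()[flat] * W).sum(axis=(1, 2, 3))
    return out


def advect_membrane(state: MembraneState, dt: float = 1.0,
                    periodic_shape: tuple[int, int, int] | None = None,
                    periodic_axes: tuple[bool, bool, bool] = (True, True, True),
                    max_step: float = 1.0) -> np.ndarray:
    """Forward-Euler vertex update X <- X + dt U, with periodic wrap.

    Displacements above ``max_step`` lattice units degrade IBM accuracy
    and are logged.
    """
    disp = dt * state.U
    dmax = np.abs(disp).max() if disp.size else 0.0
    if dmax > max_step:
        logger.warning("IBM advection step %.3g lattice units exceeds %.3g",
                       dmax, max_step)
    state.X = state.X + disp
    if periodic_shape is not None:
        for ax in range(3):
            if periodic_axes[ax]:
                state.X[:, ax] = np.mod(state.X[:, ax], periodic_shape[ax])
    return state.X
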