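"""Domain construction and voxelization for the microfluidic geometries.

Supported scenes: rectangular boxes with periodic / resting-wall /
moving-wall faces, a cylindrical pipe bore, wedge (ramp) obstructions,
and cylindrical micropost arrays (generated or loaded from a plain-text
layout file).

Conventions: lattice node ``(i, j, k)`` has its center at physical
position ``((i + 1/2) dx, (j + 1/2) dx, (k + 1/2) dx)``; a node is solid
iff its center lies inside an obstacle or outside the channel interior.
Wall faces are realized by one layer of solid nodes appended on that
face, so a declared fluid extent of L keeps a gap of exactly L between
the two halfway bounce-back wall planes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class FaceBC:
    kind: str                      # "periodic" | "wall" | "moving_wall"
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)  # m/s, for moving walls

    def __post_init__(self):
        if self.kind not in ("periodic", "wall", "moving_wall"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "moving_wall" and not any(self.velocity):
            logger.warning("moving wall declared with zero velocity")


@dataclass
class DomainSpec:
    """Fluid region extents (m), lattice spacing (m), per-face boundaries."""

    size: tuple[float, float, float]
    dx: float
    bc: dict[str, FaceBC] = field(default_factory=dict)
    pipe_radius: float | None = None   # cylindrical bore about the x-axis
    label: str = "box"

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        for L in self.size:
            n = L / self.dx
            if L <= 0 or abs(n - round(n)) > 1e-6:
                raise ValueError("domain extents must be positive multiples of dx")
        for f in FACES:
            self.bc.setdefault(f, FaceBC("periodic"))
        for f, b in self.bc.items():
            if f not in FACES:
                raise ValueError(f"unknown face {f!r}")
        # opposite faces must agree on periodicity
        for a in ("x", "y", "z"):
            pa = self.bc[a + "-"].kind == "periodic"
            pb = self.bc[a + "+"].kind == "periodic"
            if pa != pb:
                raise ValueError(f"periodic faces must be paired on axis {a}")

    @property
    def fluid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(L / self.dx)) for L in self.size)

    def wall_pad(self, face: str) -> bool:
        return self.bc[face].kind in ("wall", "moving_wall")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        n = list(self.fluid_shape)
        for ax, a in enumerate("xyz"):
            n[ax] += int(self.wall_pad(a + "-")) + int(self.wall_pad(a + "+"))
        return tuple(n)

    def node_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis (solid pads included).

        Coordinates are anchored so that the fluid region spans [0, L]
        on each axis; pad layers sit outside that interval.
        """
        out = []
        for ax, a in enumerate("xyz"):
            lo = int(self.wall_pad(a + "-"))
            n = self.grid_shape[ax]
            idx = np.arange(n)
            out.append((idx - lo + 0.5) * self.dx)
        return tuple(out)


# ---------------------------------------------------------------------------
# obstacles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderPost:
    """Solid cylindrical post, axis-aligned (default z)."""

    center: tuple[float, float]   # in-plane center (m)
    radius: float                 # m
    axis: str = "z"
    z0: float = -np.inf           # extent along the axis (m)
    z1: float = np.inf

    def contains(self, x, y, z):
        ax = {"x": (y, z, x), "y": (x, z, y), "z": (x, y, z)}[self.axis]
        p, q, h = ax
        inside = (p - self.center[0]) ** 2 + (q - self.center[1]) ** 2 <= self.radius**2
        return inside & (h >= self.z0) & (h <= self.z1)


@dataclass(frozen=True)
class BoxObstacle:
    corner: tuple[float, float, float]
    extents: tuple[float, float, float]

    def contains(self, x, y, z):
        c, e = self.corner, self.extents
        return ((x >= c[0]) & (x < c[0] + e[0])
                & (y >= c[1]) & (y < c[1] + e[1])
                & (z >= c[2]) & (z < c[2] + e[2]))


@dataclass(frozen=True)
class WedgeObstacle:
    """Flat-topped obstruction with a linear leading ramp, spanning y.

    Rises from the floor over ``ramp`` along +x to ``height``, stays flat
    for ``flat``, then ends with a vertical trailing face. The flat top is
    the surface-stress measurement patch.
    """

    x0: float
    ramp: float
    flat: float
    height: float

    def contains(self, x, y, z):
        xr = x - self.x0
        h = np.where(
            xr < 0, -np.inf,
            np.where(xr < self.ramp, self.height * xr / max(self.ramp, 1e-300),
                     np.where(xr < self.ramp + self.flat, self.height, -np.inf)),
        )
        return z < h

    def top_patch(self, dx: float) -> tuple[float, float, float]:
        """(x_start, x_end, z_top) of the flat top in physical units."""
        return self.x0 + self.ramp, self.x0 + self.ramp + self.flat, self.height


@dataclass
class ObstacleSet:
    posts: list[CylinderPost] = field(default_factory=list)
    boxes: list[BoxObstacle] = field(default_factory=list)
    wedges: list[WedgeObstacle] = field(default_factory=list)
    source: str = "generated"

    def __iter__(self):
        yield from self.posts
        yield from self.boxes
        yield from self.wedges

    def __len__(self):
        return len(self.posts) + len(self.boxes) + len(self.wedges)


# ---------------------------------------------------------------------------
# boundary mask
# ---------------------------------------------------------------------------

@dataclass
class BoundaryMask:
    """Per-node classification of the lattice.

    ``solid`` marks bounce-back nodes; ``wall_velocity`` (3, grid) is
    nonzero on moving-wall nodes. Fluid nodes are ``~solid``.
    """

    solid: np.ndarray
    wall_velocity: np.ndarray | None = None
    domain: DomainSpec | None = None

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())


def voxelize_scene(domain: DomainSpec, obstacles: ObstacleSet | None = None,
                   converter=None) -> BoundaryMask:
    """Voxelize the domain + obstacles into a BoundaryMask.

    ``converter`` (a UnitConverter) supplies the lattice velocity scale for
    moving walls; if omitted, wall velocities are assumed to already be in
    lattice units.
    """
    xs, ys, zs = domain.node_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    solid = np.zeros(domain.grid_shape, dtype=bool)

    # wall pads
    for ax, a in enumerate("xyz"):
        if domain.wall_pad(a + "-"):
            solid[(slice(None),) * ax + (0,)] = True
        if domain.wall_pad(a + "+"):
            solid[(slice(None),) * ax + (-1,)] = True

    # pipe bore (about x-axis through the cross-section center)
    if domain.pipe_radius is not None:
        cy, cz = domain.size[1] / 2, domain.size[2] / 2
        solid |= (Y - cy) ** 2 + (Z - cz) ** 2 > domain.pipe_radius**2

    if obstacles is not None:
        for obs in obstacles:
            solid |= obs.contains(X, Y, Z)

    if not (~solid).any():
        raise ValueError("voxelization produced no fluid nodes")

    # moving-wall velocities on the pad layers
    wall_u = None
    scale = 1.0 if converter is None else converter.velocity_scale
    for ax, a in enumerate("xyz"):
        for side, sl in ((a + "-", 0), (a + "+", -1)):
            bc = domain.bc[side]
            if bc.kind == "moving_wall":
                if wall_u is None:
                    wall_u = np.zeros((3, *domain.grid_shape))
                idx = (slice(None),) * ax + (sl,)
                for comp in range(3):
                    wall_u[(comp, *idx)] = bc.velocity[comp] / scale
    return BoundaryMask(solid=solid, wall_velocity=wall_u, domain=domain)


# ---------------------------------------------------------------------------
# micropost layouts
# ---------------------------------------------------------------------------

def _lloyd_relax(pts: np.ndarray, extents, rng, iters: int = 4,
                 n_samples: int = 4000) -> np.ndarray:
    """Lloyd-style relaxation toward uniform coarse density.

    Monte-Carlo Lloyd: dense uniform samples are assigned to their nearest
    post and each post moves to the centroid of its catchment.
    """
    lo = np.array([e[0] for e in extents])
    hi = np.array([e[1] for e in extents])
    for _ in range(iters):
        samples = lo + rng.random((n_samples, 2)) * (hi - lo)
        _, owner = cKDTree(pts).query(samples)
        for k in range(len(pts)):
            mine = samples[owner == k]
            if len(mine):
                pts[k] = 0.5 * pts[k] + 0.5 * mine.mean(axis=0)
    return np.clip(pts, lo, hi)


def _enforce_gap(pts: np.ndarray, dmin: float, extents,
                 iters: int = 100) -> np.ndarray:
    """Symmetrically separate point pairs closer than dmin (clipped to
    the region); leaves already-valid layouts untouched."""
    lo = np.array([e[0] for e in extents])
    hi = np.array([e[1] for e in extents])
    for _ in range(iters):
        if len(pts) < 2:
            break
        d, j = cKDTree(pts).query(pts, k=2)
        bad = np.flatnonzero(d[:, 1] < dmin)
        if len(bad) == 0:
            break
        for i in bad:
            k = j[i, 1]
            sep = pts[i] - pts[k]
            dist = np.linalg.norm(sep)
            direction = sep / dist if dist > 0 else np.array([1.0, 0.0])
            push = 0.5 * (dmin * 1.02 - dist)
            pts[i] += push * direction
            pts[k] -= push * direction
        np.clip(pts, lo, hi, out=pts)
    return pts


def micropost_layout(region, n_posts: int, radius: float, min_gap: float,
                     seed=None, z0: float = -np.inf, z1: float = np.inf,
                     lloyd_iters: int = 4, max_retries: int = 200) -> ObstacleSet:
    """Generate (or load) a micropost arrangement.

    ``region`` is ((x0, x1), (y0, y1)) in metres, or a path to a text file
    (one ``x y radius`` triple per line, micrometres) loaded verbatim.
    Generated layouts are a hyperuniform-like surrogate: random sequential
    addition under a surface-gap constraint, then Lloyd-style relaxation
    toward uniform coarse density, with the gap re-enforced afterwards.
    Deterministic for a fixed integer seed.
    """
    if isinstance(region, (str, Path)):
        return load_post_layout(region, z0=z0, z1=z1)

    (x0, x1), (y0, y1) = region
    area = (x1 - x0) * (y1 - y0)
    if n_posts * np.pi * radius**2 > 0.5 * area:
        raise ValueError("packing infeasible: posts would cover most of the region")
    rng = np.random.default_rng(seed)
    dmin = 2 * radius + min_gap

    for attempt in range(max_retries):
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n_posts and tries < 200 * n_posts:
            p = np.array([x0 + rng.random() * (x1 - x0),
                          y0 + rng.random() * (y1 - y0)])
            tries += 1
            if all(np.linalg.norm(p - q) >= dmin for q in pts):
                pts.append(p)
        if len(pts) < n_posts:
            continue
        arr = np.array(pts)
        if lloyd_iters:
            arr = _lloyd_relax(arr, ((x0, x1), (y0, y1)), rng, iters=lloyd_iters)
            # relaxation can shrink a gap below the constraint; push the
            # offending pairs apart again, and only then re-check
            arr = _enforce_gap(arr, dmin, ((x0, x1), (y0, y1)))
            d = cKDTree(arr).query(arr, k=2)[0][:, 1] if len(arr) > 1 else np.array([np.inf])
            if d.min() < dmin * (1 - 1e-9):
                continue
        posts = [CylinderPost(center=(float(x), float(y)), radius=radius,
                              axis="z", z0=z0, z1=z1) for x, y in arr]
        return ObstacleSet(posts=posts, source="generated")
    raise RuntimeError(f"could not place {n_posts} posts after {max_retries} retries")


def load_post_layout(path, z0: float = -np.inf, z1: float = np.inf) -> ObstacleSet:
    """Load posts from a whitespace-delimited text file (x y radius, in um)."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 3:
        raise ValueError("layout file must have three columns: x y radius (um)")
    posts = [CylinderPost(center=(x * 1e-6, y * 1e-6), radius=r * 1e-6,
                          axis="z", z0=z0, z1=z1)
             for x, y, r in data]
    return ObstacleSet(posts=posts, source="file")


def save_post_layout(obstacles: ObstacleSet, path) -> None:
    rows = [(p.center[0] * 1e6, p.center[1] * 1e6, p.radius * 1e6)
            for p in obstacles.posts]
    np.savetxt(path, np.array(rows), fmt="%.8f",
               header="x[um] y[um] radius[um]")
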