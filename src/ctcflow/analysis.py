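"""Post-processing statistics for the benchmark scenarios.

Deformation index, motion-regime classification of a sheared cell
(tank-treading / rolling / tumbling / mixed), wedge-surface shear
stress, and the post-edge distance histogram used to compare phenotype
trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

logger = logging.getLogger(__name__)


def deformation_index(h: float | np.ndarray, h0: float) -> float | np.ndarray:
    """Relative deformation index eps = |h - h0| / h0."""
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("cross-section length h cannot be negative")
    eps = np.abs(h - h0) / h0
    return float(eps) if eps.ndim == 0 else eps


# ---------------------------------------------------------------------------
# motion-regime classification
# ---------------------------------------------------------------------------

@dataclass
class RegimeLabel:
    label: str  # tank_treading | rolling | tumbling | mixed | inconclusive
    inclination: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    marker_phase: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    roll_phase: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    diagnostics: dict = dc_field(default_factory=dict)


def _principal_axis_series(vertices_history: list[np.ndarray]) -> np.ndarray:
    axes = []
    prev = None
    for verts in vertices_history:
        c = verts - verts.mean(axis=0)
        _, vecs = np.linalg.eigh(c.T @ c)
        a = vecs[:, -1]
        if prev is not None and a @ prev < 0:
            a = -a  # keep a continuous orientation of the headless axis
        axes.append(a)
        prev = a
    return np.array(axes)


def _unwrapped_angle(x, y):
    return np.unwrap(np.arctan2(y, x))


def classify_motion_regime(times, vertices_history, marker_index: int = 0,
                           flow_axis: int = 0, gradient_axis: int = 2,
                           inclination_band_deg: float = 15.0,
                           min_treading_turns: float = 2.0) -> RegimeLabel:
    """Label the motion of a sheared cell from its membrane history.

    Operational rules (thresholds configurable; the band default is
    +-15 degrees and sustained treading means >= ``min_treading_turns``
    full turns of the marker phase):

    * tank_treading: the marker vertex's phase in the body frame (its
      shear-plane angle minus the principal-axis inclination) advances
      by >= 2 pi while the inclination stays inside the band;
    * tumbling: the principal axis itself turns end-over-end (>= pi of
      continuous advance) in the shear plane without body-frame
      circulation;
    * rolling: sustained rotation about the flow axis (marker phase in
      the plane perpendicular to the flow advances >= 2 pi) with the
      in-shear-plane inclination stable;
    * mixed: simultaneous treading and axis flipping, or none cleanly.
    """
    times = np.asarray(times, dtype=float)
    if len(vertices_history) < 8:
        return RegimeLabel("inconclusive",
                           diagnostics={"reason": "history too short"})
    vorticity_axis = 3 - flow_axis - gradient_axis
    axes = _principal_axis_series(vertices_history)
    incl = _unwrapped_angle(axes[:, flow_axis], axes[:, gradient_axis])
    coms = np.array([v.mean(axis=0) for v in vertices_history])
    rel = np.array([v[marker_index] for v in vertices_history]) - coms
    marker_lab = _unwrapped_angle(rel[:, flow_axis], rel[:, gradient_axis])
    marker = marker_lab - (incl - incl[0])   # body-frame treading phase
    roll = _unwrapped_angle(rel[:, vorticity_axis], rel[:, gradient_axis])

    band = np.deg2rad(inclination_band_deg)
    incl_stable = (incl.max() - incl.min()) <= 2 * band
    marker_adv = marker[-1] - marker[0]
    roll_adv = roll[-1] - roll[0]
    axis_adv = np.abs(incl[-1] - incl[0])
    treads = abs(marker_adv) >= min_treading_turns * 2 * np.pi
    one_circulation = abs(marker_adv) >= 2 * np.pi
    tumbles = axis_adv >= np.pi
    rolls = abs(roll_adv) >= 2 * np.pi and axis_adv < np.pi

    diagnostics = {"marker_advance": float(marker_adv),
                   "roll_advance": float(roll_adv),
                   "axis_advance": float(axis_adv),
                   "inclination_range": float(incl.max() - incl.min())}
    if incl_stable and (treads or one_circulation) and not rolls:
        label = "tank_treading"
    elif tumbles and not one_circulation:
        label = "tumbling"
    elif rolls and incl_stable:
        label = "rolling"
    elif tumbles or one_circulation or rolls:
        label = "mixed"
    else:
        label = "inconclusive" if (times[-1] - times[0]) <= 0 else "mixed"
        diagnostics["reason"] = "no sustained rotation detected"
    return RegimeLabel(label, inclination=incl, marker_phase=marker,
                       roll_phase=roll, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# surface shear stress
# ---------------------------------------------------------------------------

def surface_shear_stress(u: np.ndarray, patch, mu: float, dx: float,
                         flow_axis: int = 0, normal_axis: int = 2):
    """Shear stress tau = mu * du_x/dz on an upward-facing flat patch.

    ``u`` is the physical velocity field (3, nx, ny, nz); ``patch`` is
    ``(i_slice, j_slice, k_surface)`` giving the in-plane extent and the
    index of the first fluid layer above the surface (normal must be the
    z axis). The derivative is a one-sided finite difference using the
    first two fluid layers.
    """
    if normal_axis != 2:
        raise ValueError("patch normal must be the z axis")
    i_sl, j_sl, k = patch
    if k + 1 >= u.shape[3]:
        raise ValueError("patch too close to the domain top for a one-sided FD")
    ux1 = u[flow_axis][i_sl, j_sl, k]
    ux2 = u[flow_axis][i_sl, j_sl, k + 1]
    stress = mu * (ux2 - ux1) / dx
    if stress.size == 0:
        raise ValueError("empty surface patch")
    return stress, float(stress.mean())


def wedge_top_patch(wedge, domain, dx: float):
    """Index patch (i_slice, j_slice, k_first_fluid) for a wedge's flat top."""
    x0, x1, ztop = wedge.top_patch(dx)
    lo_x = int(domain.wall_pad("x-"))
    lo_y = int(domain.wall_pad("y-"))
    lo_z = int(domain.wall_pad("z-"))
    i0 = int(np.ceil(x0 / dx)) + lo_x
    i1 = int(np.floor(x1 / dx)) + lo_x
    k = int(np.floor(ztop / dx + 0.5)) + lo_z  # first node center above ztop
    ny = domain.grid_shape[1]
    return slice(i0, i1), slice(lo_y, ny - int(domain.wall_pad("y+"))), k


# ---------------------------------------------------------------------------
# post-edge distance histogram
# ---------------------------------------------------------------------------

def post_edge_distance_histogram(records, layout, window, bins=20):
    """Histogram of trajectory-point distances to the nearest post surface.

    ``records`` is an iterable of TrajectoryRecord (or (x, y) pairs);
    ``window`` is ((x0, x1), (y0, y1)) in metres; ``bins`` as for
    numpy.histogram. Returns (counts, edges, distances).
    """
    (x0, x1), (y0, y1) = window
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty analysis window")
    pts = []
    for r in records:
        x, y = (r.x, r.y) if hasattr(r, "x") else (r[0], r[1])
        if x0 <= x <= x1 and y0 <= y <= y1:
            pts.append((x, y))
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    posts = getattr(layout, "posts", [])
    if not posts:
        logger.warning("no posts in layout: distances are all infinite")
        counts, edges = np.histogram(np.empty(0), bins=bins)
        return counts, edges, np.full(len(pts), np.inf)
    centers = np.array([p.center for p in posts])
    radii = np.array([p.radius for p in posts])
    if len(pts) == 0:
        counts, edges = np.histogram(np.empty(0), bins=bins)
        return counts, edges, np.empty(0)
    d = np.linalg.norm(pts[:, None, :] - centers[None], axis=2) - radii[None]
    dist = np.maximum(d.min(axis=1), 0.0)
    counts, edges = np.histogram(dist, bins=bins)
    return counts, edges, dist
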