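"""Field, mesh and checkpoint writers.

Fluid fields export as legacy-VTK structured points; membranes as
legacy-VTK polydata or OFF/PLY (through trimesh); the simulation state
checkpoints to an HDF5 container holding the populations with grid
metadata plus every membrane's vertices and reference state.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_structured_vtk(path, fields: dict, dx: float = 1.0,
                         origin=(0.0, 0.0, 0.0)) -> None:
    """Write scalar/vector fields on a regular grid as legacy VTK.

    ``fields`` maps name -> array of shape (nx, ny, nz) for scalars or
    (3, nx, ny, nz) for vectors. Legacy VTK is x-fastest, hence the
    Fortran-order ravel.
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {f.shape[-3:] for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid shape")
    nx, ny, nz = shapes.pop()
    lines = [
        "# vtk DataFile Version 3.0", "ctcflow field export", "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
        f"SPACING {dx} {dx} {dx}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in arr.ravel(order="F"))
        elif arr.ndim == 4 and arr.shape[0] == 3:
            lines.append(f"VECTORS {name} double")
            flat = arr.reshape(3, -1, order="A")
            vec = np.stack([arr[c].ravel(order="F") for c in range(3)], axis=1)
            lines.extend(" ".join(f"{v:.9g}" for v in row) for row in vec)
            del flat
        else:
            raise ValueError(f"field {name!r} has unsupported shape {arr.shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_polydata_vtk(path, vertices: np.ndarray, faces: np.ndarray,
                       point_data: dict | None = None) -> None:
    """Write a triangulated surface as legacy VTK polydata."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0", "ctcflow membrane export", "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} double",
    ]
    lines.extend(" ".join(f"{v:.9g}" for v in row) for row in vertices)
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines.extend("3 " + " ".join(str(i) for i in row) for row in faces)
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def export_mesh(cell, path) -> None:
    """Export a membrane mesh as OFF/PLY (by extension) or VTK polydata."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        write_polydata_vtk(path, cell.vertices, cell.faces)
    else:
        cell.as_trimesh().export(path)


def import_mesh(path):
    """Load an OFF/PLY surface as a (vertices, faces) pair."""
    import trimesh
    mesh = trimesh.load_mesh(path)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, simulation, extra_meta: dict | None = None) -> None:
    import h5py
    with h5py.File(path, "w") as h5:
        g = h5.create_group("fluid")
        g.create_dataset("f", data=simulation.field.f)
        g.create_dataset("body_force", data=simulation.field.body_force)
        g.attrs["grid_shape"] = simulation.domain.grid_shape
        g.attrs["dx"] = simulation.conv.dx
        g.attrs["dt"] = simulation.conv.dt
        g.attrs["tau"] = simulation.relax.tau
        g.attrs["velocity_set"] = simulation.vset.name
        h5.create_dataset("solid_mask", data=simulation.mask.solid)
        h5.attrs["time"] = simulation.time
        h5.attrs["step_count"] = simulation.step_count
        for k, cell in enumerate(simulation.cells):
            cg = h5.create_group(f"cell_{k:04d}")
            cg.create_dataset("vertices", data=cell.vertices)
            cg.create_dataset("faces", data=cell.faces)
            cg.create_dataset("rest_lengths", data=cell.rest_lengths)
            cg.create_dataset("rest_areas", data=cell.rest_areas)
            cg.create_dataset("rest_angles", data=cell.rest_angles)
            cg.attrs["rest_volume"] = cell.rest_volume
            cg.attrs["phenotype"] = cell.phenotype
        for key, val in (extra_meta or {}).items():
            h5.attrs[key] = val


def load_checkpoint(path) -> dict:
    """Read a checkpoint back as plain arrays (no live objects)."""
    import h5py
    out = {"cells": []}
    with h5py.File(path, "r") as h5:
        out["f"] = np.asarray(h5["fluid/f"])
        out["body_force"] = np.asarray(h5["fluid/body_force"])
        out["solid_mask"] = np.asarray(h5["solid_mask"])
        out["meta"] = dict(h5["fluid"].attrs) | dict(h5.attrs)
        for key in sorted(k for k in h5 if k.startswith("cell_")):
            cg = h5[key]
            out["cells"].append({
                "vertices": np.asarray(cg["vertices"]),
                "faces": np.asarray(cg["faces"]),
                "phenotype": cg.attrs["phenotype"],
            })
    return out
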