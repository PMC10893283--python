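"""Isosurface extraction, scaffold measurement, and printable file IO.

The zero level set of a sampled field grid is extracted with marching
cubes into a watertight triangle mesh (the grid's void padding layer
guarantees closure), measured against the analytic envelope cylinder
(porosity, bounding box, connectivity, largest-inscribed-sphere pore
size), and written as STL or PLY for DLP printing.  STL is unitless; all
coordinates here are mm and the JSON report records that.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as sk_measure

from .fields import Cylinder, ScalarFieldGrid

__all__ = [
    "ScaffoldReport",
    "extract_mesh",
    "measure_scaffold",
    "pore_radius_from_grid",
    "write_mesh",
    "read_mesh",
    "default_resolution",
]


def default_resolution(tau: float, shell_thickness: float = 0.0, floor: float = 10.0) -> float:
    """Default sampling resolution in voxels per mm.

    At least 8 voxels per TPMS period and 20 voxels across the shell
    thickness, with a floor (default 10 voxels/mm) so that volume and
    pore-size measurements on coarse-period designs stay accurate.
    """
    res = max(floor, 8.0 * tau)
    if shell_thickness > 0:
        res = max(res, 20.0 / shell_thickness)
    return res


@dataclass
class ScaffoldReport:
    """Measured properties of one extracted scaffold mesh."""

    porosity: float
    solid_volume: float
    envelope_volume: float
    bounding_box: list
    pore_radius: float | None
    component_count: int
    watertight: bool
    resolution: float | None = None
    design: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["units"] = "mm"
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value"):
        return obj.value
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


def extract_mesh(grid: ScalarFieldGrid, level: float = 0.0) -> trimesh.Trimesh:
    """Extract the ``phi = level`` isosurface as a closed, outward-oriented mesh.

    Vertices are mm coordinates in the scaffold frame.  A field with no
    sign change on the grid is rejected ("empty or fully solid part")
    rather than producing an empty file.
    """
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if vmin >= level or vmax <= level:
        kind = "empty (all void)" if vmin >= level else "fully solid (no void padding)"
        raise ValueError(
            f"field has no {level}-crossing on the grid: part would be {kind}"
        )
    verts, faces, _, _ = sk_measure.marching_cubes(
        grid.values, level=level, spacing=tuple(grid.spacing)
    )
    # marching_cubes indexes voxel nodes; node i sits at origin + (i + 1/2)*spacing
    verts = verts + (grid.origin + 0.5 * grid.spacing)
    # process+validate merges coincident vertices and drops the degenerate
    # slivers marching cubes emits near plateau values; both are needed for
    # a manifold (watertight) surface at fine resolutions
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=True)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = {
        "grid_shape": list(grid.shape),
        "spacing_mm": grid.spacing.tolist(),
        "level": level,
        **{k: str(v) for k, v in grid.meta.items()},
    }
    return mesh


def pore_radius_from_grid(grid: ScalarFieldGrid, envelope: Cylinder) -> float:
    """Largest inscribed-sphere radius (mm) of the interior void phase.

    The void phase is split into exterior and pores by the envelope
    cylinder: void voxels outside the envelope (and anything connected to
    the grid boundary through them) are exterior.  The pore radius is the
    maximum Euclidean distance from an interior void voxel to the nearest
    non-pore voxel (solid or exterior), i.e. the radius of the largest
    sphere that fits inside the pore network.
    """
    void = ~grid.solid_mask()
    centers = grid.voxel_centers()
    inside = envelope.contains(centers.reshape(-1, 3)).reshape(grid.shape)
    interior_void = void & inside
    if not interior_void.any():
        return 0.0
    dist = ndimage.distance_transform_edt(
        interior_void, sampling=tuple(grid.spacing)
    )
    return float(dist.max())


def measure_scaffold(
    mesh: trimesh.Trimesh,
    envelope: Cylinder,
    *,
    grid: ScalarFieldGrid | None = None,
    design: dict | None = None,
) -> ScaffoldReport:
    """Measure the scaffold mesh against its analytic design envelope.

    Solid volume comes from the signed-volume sum of the watertight mesh;
    porosity is ``1 - solid / envelope``.  A non-watertight mesh gets no
    volume (porosity NaN, flag set).  If the sampled ``grid`` is passed,
    the pore radius is estimated by the inscribed-sphere metric.
    """
    watertight = bool(mesh.is_watertight)
    env_vol = envelope.volume
    if watertight:
        solid = float(mesh.volume)
        porosity = 1.0 - solid / env_vol
    else:
        solid = math.nan
        porosity = math.nan
    pore_r = pore_radius_from_grid(grid, envelope) if grid is not None else None
    resolution = None
    if grid is not None:
        resolution = float(grid.meta.get("resolution", 1.0 / grid.spacing[0]))
    return ScaffoldReport(
        porosity=porosity,
        solid_volume=solid,
        envelope_volume=env_vol,
        bounding_box=mesh.bounds.tolist(),
        pore_radius=pore_r,
        component_count=int(mesh.body_count),
        watertight=watertight,
        resolution=resolution,
        design=dict(design or {}),
    )


_FORMATS = {"stl": "stl", "stl-binary": "stl", "stl-ascii": "stl_ascii", "ply": "ply"}


def write_mesh(mesh: trimesh.Trimesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write STL (binary/ascii) or PLY.  Output bytes are deterministic for a fixed mesh."""
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "stl"
    key = fmt.lower()
    if key not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; choose from {sorted(_FORMATS)}")
    data = mesh.export(file_type=_FORMATS[key])
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path} does not contain a triangle mesh")
    return mesh
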