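"""Implicit scalar fields for TPMS scaffold design.

A scaffold is the sublevel set ``Omega = {p : phi(p) <= 0}`` of an implicit
function ``phi``: points with non-positive field value are solid, positive
values are void, and the zero level set is the printable surface.  Two
triply periodic minimal surface (TPMS) families are provided — gyroid (G)
and diamond (D) — in their standard trigonometric approximations

    phi_G = sin(2*pi*tau*x) cos(2*pi*tau*y)
          + sin(2*pi*tau*z) cos(2*pi*tau*x)
          + sin(2*pi*tau*y) cos(2*pi*tau*z) - c

    phi_D = cos(2*pi*tau*x) cos(2*pi*tau*y) cos(2*pi*tau*z)
          - sin(2*pi*tau*x) sin(2*pi*tau*y) sin(2*pi*tau*z) - c

where ``tau`` (cycles per mm) sets the pore scale and ``c`` offsets the
level set, trading solid for void volume.  Alongside the TPMS fields the
module provides the solid cylindrical shell (a signed-distance-like field),
a straight-pore reference scaffold, and uniform grid sampling with a void
padding layer so extracted meshes always close.

All evaluators are vectorized: ``points`` may be a single 3-vector or an
``(..., 3)`` array of mm coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

__all__ = [
    "Family",
    "TPMSParams",
    "Cylinder",
    "ScalarFieldGrid",
    "eval_gyroid",
    "eval_diamond",
    "eval_shell",
    "eval_straight_pore_reference",
    "tpms_field",
    "sample_grid",
    "DEFAULT_C_RANGE",
    "DEFAULT_MAX_VOXELS",
]

# Calibration range for the level constant c used throughout the package.
DEFAULT_C_RANGE = (-0.9, 0.9)

# Memory budget for sampled grids (number of voxels, ~0.6 GB of float64).
DEFAULT_MAX_VOXELS = 80_000_000


class Family(str, Enum):
    """TPMS family: gyroid (G) or diamond (D)."""

    GYROID = "G"
    DIAMOND = "D"

    @classmethod
    def coerce(cls, value: "Family | str") -> "Family":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown TPMS family {value!r}; expected 'G' or 'D'"
            ) from None


@dataclass(frozen=True)
class TPMSParams:
    """One periodic field instance.

    Parameters
    ----------
    family : Family or str
        ``'G'`` (gyroid) or ``'D'`` (diamond).
    tau : float
        Spatial frequency in cycles per mm; the unit cell edge is ``1/tau``.
    c : float
        Level-set constant (dimensionless).  Must lie inside ``c_range``,
        the interval over which the linear porosity calibration is trusted.
    """

    family: Family
    tau: float
    c: float
    c_range: tuple[float, float] = DEFAULT_C_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family.coerce(self.family))
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")
        lo, hi = self.c_range
        if not (lo <= self.c <= hi):
            raise ValueError(
                f"level constant c={self.c} outside calibration range [{lo}, {hi}]"
            )

    @property
    def period(self) -> float:
        """Unit-cell edge length in mm."""
        return 1.0 / self.tau


@dataclass(frozen=True)
class Cylinder:
    """Cylindrical design envelope centered on the z-axis, z in [-h/2, h/2]."""

    height: float
    diameter: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.diameter <= 0:
            raise ValueError("cylinder height and diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = _as_points(points)
        r2 = p[..., 0] ** 2 + p[..., 1] ** 2
        return (r2 <= self.radius**2) & (np.abs(p[..., 2]) <= self.height / 2.0)


def _as_points(points) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError(f"points must have trailing dimension 3, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("points contain non-finite coordinates")
    return p


def eval_gyroid(points, params: TPMSParams) -> np.ndarray:
    """Gyroid field value(s); range ``[-3 - c, 3 - c]``."""
    if params.family is not Family.GYROID:
        raise ValueError(f"eval_gyroid requires family G, got {params.family.value}")
    p = _as_points(points)
    w = 2.0 * np.pi * params.tau
    x, y, z = w * p[..., 0], w * p[..., 1], w * p[..., 2]
    return (
        np.sin(x) * np.cos(y)
        + np.sin(z) * np.cos(x)
        + np.sin(y) * np.cos(z)
        - params.c
    )


def eval_diamond(points, params: TPMSParams) -> np.ndarray:
    """Diamond field value(s); range ``[-2 - c, 2 - c]``."""
    if params.family is not Family.DIAMOND:
        raise ValueError(f"eval_diamond requires family D, got {params.family.value}")
    p = _as_points(points)
    w = 2.0 * np.pi * params.tau
    x, y, z = w * p[..., 0], w * p[..., 1], w * p[..., 2]
    return np.cos(x) * np.cos(y) * np.cos(z) - np.sin(x) * np.sin(y) * np.sin(z) - params.c


def tpms_field(params: TPMSParams) -> Callable[[np.ndarray], np.ndarray]:
    """Return the vectorized evaluator for ``params``' family."""
    if params.family is Family.GYROID:
        return lambda pts: eval_gyroid(pts, params)
    return lambda pts: eval_diamond(pts, params)


def eval_shell(points, R: float, half_height: float) -> np.ndarray:
    """Signed field of a solid cylinder: ``max(sqrt(x^2+y^2) - R, |z| - h_bar)``.

    Negative inside the solid cylinder of radius ``R`` and half-height
    ``half_height``, zero on its boundary, positive outside; values are mm
    (signed-distance-like, exact on the lateral face and caps).
    """
    if R <= 0 or half_height <= 0:
        raise ValueError("shell radius and half-height must be positive")
    p = _as_points(points)
    radial = np.hypot(p[..., 0], p[..., 1]) - R
    axial = np.abs(p[..., 2]) - half_height
    return np.maximum(radial, axial)


def eval_straight_pore_reference(
    points,
    envelope: Cylinder,
    pore_radius: float,
    pore_pitch: float,
) -> np.ndarray:
    """Reference scaffold: solid cylinder pierced by a square lattice of straight pores.

    Channels of radius ``pore_radius`` run parallel to the z-axis at the
    centers of a square lattice of pitch ``pore_pitch`` (channel axes at
    ``((i + 1/2) p, (j + 1/2) p)``, so the scaffold axis sits mid-way
    between four channels).  Negative values are solid.
    """
    if pore_radius <= 0:
        raise ValueError("pore_radius must be positive")
    if not pore_radius < pore_pitch / 2.0:
        raise ValueError(
            f"pore_radius={pore_radius} must be < pitch/2={pore_pitch / 2}; "
            "channels would merge and leave no solid"
        )
    p = _as_points(points)
    cyl = eval_shell(p, envelope.radius, envelope.height / 2.0)
    # distance (in xy) to the nearest channel axis of the lattice
    ux = np.mod(p[..., 0], pore_pitch) - pore_pitch / 2.0
    uy = np.mod(p[..., 1], pore_pitch) - pore_pitch / 2.0
    d = np.hypot(ux, uy)
    # inside a channel: pore_radius - d > 0 -> void
    return np.maximum(cyl, pore_radius - d)


@dataclass
class ScalarFieldGrid:
    """Uniform voxel grid of field samples (voxel-center convention).

    ``values[i, j, k]`` is the field evaluated at
    ``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive on every axis")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite field values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape ``(*shape, 3)``."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def solid_mask(self) -> np.ndarray:
        """Boolean mask of solid voxels (field <= 0)."""
        return self.values <= 0.0


def sample_grid(
    field_fn: Callable[[np.ndarray], np.ndarray],
    envelope: Cylinder,
    resolution: float,
    *,
    tau: float | None = None,
    max_voxels: int = DEFAULT_MAX_VOXELS,
    pad_value: float = 1.0,
) -> ScalarFieldGrid:
    """Sample ``field_fn`` over the envelope bounding box plus one padding voxel.

    The outermost voxel layer is forced to ``pad_value`` (void) so that any
    isosurface extracted from the grid is closed.  ``resolution`` is voxels
    per mm.  If ``tau`` is given, the sampling must resolve the TPMS period
    with at least 8 voxels.

    Raises
    ------
    ValueError
        If the resolution under-samples the TPMS period or the grid would
        exceed ``max_voxels`` (the message reports the admissible resolution).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive (voxels per mm)")
    if tau is not None and resolution < 8.0 * tau:
        raise ValueError(
            f"resolution {resolution} voxels/mm gives fewer than 8 voxels per "
            f"TPMS period (1/tau = {1.0 / tau:.4g} mm); need >= {8.0 * tau:.4g}"
        )
    spacing = 1.0 / resolution
    half = np.array([envelope.radius, envelope.radius, envelope.height / 2.0])
    n = np.ceil(2.0 * half / spacing).astype(int) + 2  # +1 padding voxel per side
    total = int(np.prod(n))
    if total > max_voxels:
        admissible = resolution * (max_voxels / total) ** (1.0 / 3.0)
        raise ValueError(
            f"grid of {n.tolist()} = {total} voxels exceeds the budget of "
            f"{max_voxels}; reduce resolution to <= {admissible:.3g} voxels/mm "
            "or raise max_voxels"
        )
    origin = -(n * spacing) / 2.0
    grid = ScalarFieldGrid(
        origin=origin,
        spacing=np.full(3, spacing),
        values=np.zeros(n),
        meta={"resolution": resolution, "envelope": envelope},
    )
    pts = grid.voxel_centers()
    values = np.asarray(field_fn(pts.reshape(-1, 3)), dtype=float).reshape(pts.shape[:3])
    # void padding layer: strictly positive on every boundary voxel
    pad = np.zeros(values.shape, dtype=bool)
    pad[0, :, :] = pad[-1, :, :] = True
    pad[:, 0, :] = pad[:, -1, :] = True
    pad[:, :, 0] = pad[:, :, -1] = True
    values[pad] = np.maximum(values[pad], pad_value)
    grid.values = values
    return grid
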