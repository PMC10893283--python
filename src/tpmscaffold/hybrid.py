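"""Shell hybridization: blending a TPMS core with a solid cylindrical shell.

A printable scaffold needs a closed outer wall.  The wall is added by
blending the TPMS field with the solid-cylinder field through a smooth
spatial weight ``gamma(x, y, z)`` built from a tapered window

    Pi(xi; c) = 0.5 * exp((1 - xi/c) / s)        for xi > c
              = 1 - 0.5 * exp(-(1 - xi/c) / s)   for xi < c

with sharpness ``s = 0.03``: ``Pi`` is ~1 deep inside the cutoff ``c``,
0.5 exactly at the knee ``xi = c``, and decays to ~0 outside.  The weight
is the product of a radial and an axial window,

    gamma = Pi(sqrt(x^2 + y^2); R - t) * Pi(|z|; h/2 - t)

so ``gamma ~ 1`` in the scaffold core and ``~ 0`` in the shell band of
thickness ``t`` and beyond.  The default blend

    phi_h = gamma * phi_TPMS + (1 - gamma) * phi_shell

lets the TPMS govern the core and the solid shell govern the rim and caps
(``orientation='shell_outside'``); the transposed weighting
(``orientation='as_printed'``) is kept selectable.  The shell field is
divided by the shell thickness before blending so both components are
O(1) near the transition, and the result is clamped to void outside the
envelope cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fields import Cylinder, TPMSParams, eval_shell, tpms_field

__all__ = ["ShellSpec", "tapered_window", "gamma", "hybrid_field", "make_hybrid_field"]

DEFAULT_SMOOTHING = 0.03


@dataclass(frozen=True)
class ShellSpec:
    """Cylindrical envelope + shell geometry for hybridization.

    ``R`` and ``h`` are the envelope radius and height (mm); ``t`` is the
    shell thickness (mm, may be 0); ``smoothing`` is the window sharpness
    constant.  Derived quantities: ``R_bar = R - t`` (radial knee) and
    ``h_bar = h/2 - t`` (axial knee).
    """

    R: float
    h: float
    t: float = 0.0
    smoothing: float = DEFAULT_SMOOTHING
    orientation: str = "shell_outside"

    def __post_init__(self) -> None:
        if self.R <= 0 or self.h <= 0:
            raise ValueError("envelope radius and height must be positive")
        if not 0 <= self.t < self.R:
            raise ValueError(f"shell thickness t={self.t} must satisfy 0 <= t < R={self.R}")
        if self.t >= self.h / 2:
            raise ValueError(f"shell thickness t={self.t} must be < h/2={self.h / 2}")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")
        if self.orientation not in ("shell_outside", "as_printed"):
            raise ValueError(
                f"orientation must be 'shell_outside' or 'as_printed', got {self.orientation!r}"
            )

    @property
    def R_bar(self) -> float:
        return self.R - self.t

    @property
    def h_bar(self) -> float:
        return self.h / 2.0 - self.t

    @property
    def envelope(self) -> Cylinder:
        return Cylinder(height=self.h, diameter=2.0 * self.R)


def tapered_window(xi, c: float, smoothing: float = DEFAULT_SMOOTHING) -> np.ndarray:
    """Smooth near-binary window: 1 deep inside ``xi << c``, 0.5 at ``xi = c``, 0 far outside.

    Continuous and strictly decreasing in ``xi >= 0``; values in (0, 1).
    """
    if c <= 0:
        raise ValueError("window cutoff c must be positive")
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("window argument xi must be non-negative")
    u = (1.0 - xi / c) / smoothing  # >0 inside the knee, <0 outside
    outside = 0.5 * np.exp(np.minimum(u, 0.0))
    inside = 1.0 - 0.5 * np.exp(np.minimum(-u, 0.0))
    return np.where(u > 0.0, inside, outside)


def gamma(points, spec: ShellSpec) -> np.ndarray:
    """Spatial blend weight: product of the radial and axial tapered windows."""
    p = np.asarray(points, dtype=float)
    radial = np.hypot(p[..., 0], p[..., 1])
    axial = np.abs(p[..., 2])
    return tapered_window(radial, spec.R_bar, spec.smoothing) * tapered_window(
        axial, spec.h_bar, spec.smoothing
    )


def hybrid_field(points, tpms: TPMSParams, spec: ShellSpec) -> np.ndarray:
    """Blended field value(s); negative = solid, clamped to void outside the envelope."""
    return make_hybrid_field(tpms, spec)(points)


def make_hybrid_field(
    tpms: TPMSParams, spec: ShellSpec
) -> Callable[[np.ndarray], np.ndarray]:
    """Return a vectorized evaluator of the hybrid field.

    With ``t = 0`` no shell band exists: the TPMS field is simply clamped
    to the envelope (void outside), which is the smoothing-free limit of
    the blend.
    """
    phi_tpms = tpms_field(tpms)
    # normalize the mm-scaled shell field to O(1) near the transition
    scale = spec.t if spec.t > 0 else 1.0

    def field_fn(points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        envelope_sdf = eval_shell(p, spec.R, spec.h / 2.0)
        tpms_vals = phi_tpms(p)
        if spec.t == 0:
            blended = tpms_vals
        else:
            shell_vals = envelope_sdf / scale  # solid envelope cylinder
            g = gamma(p, spec)
            if spec.orientation == "shell_outside":
                blended = g * tpms_vals + (1.0 - g) * shell_vals
            else:  # as_printed: literal transposed weighting
                blended = g * shell_vals + (1.0 - g) * tpms_vals
        # clamp: void outside the envelope cylinder; sign preserved inside
        return np.maximum(blended, envelope_sdf / scale)

    return field_fn
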