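"""End-to-end scaffold design: target -> (tau, c) -> hybrid field -> mesh -> report."""

from __future__ import annotations

from dataclasses import dataclass

import trimesh

from .calibration import (
    DEFAULT_CALIBRATION_SEED,
    DesignTarget,
    PorosityFit,
    TPMSParams,
    fit_porosity_line,
    pore_radius,
    solve_design,
)
from .fields import ScalarFieldGrid, sample_grid
from .hybrid import ShellSpec, make_hybrid_field
from .mesh import ScaffoldReport, default_resolution, extract_mesh, measure_scaffold

__all__ = ["DesignResult", "design_scaffold"]


@dataclass
class DesignResult:
    """Everything produced by one design run."""

    params: TPMSParams
    fit: PorosityFit
    shell: ShellSpec
    grid: ScalarFieldGrid
    mesh: trimesh.Trimesh
    report: ScaffoldReport


def design_scaffold(
    target: DesignTarget,
    *,
    fit: PorosityFit | None = None,
    resolution: float | None = None,
    seed: int = DEFAULT_CALIBRATION_SEED,
    smoothing: float | None = None,
    orientation: str = "shell_outside",
    calibration_n: int | None = None,
) -> DesignResult:
    """Run the full design chain for one target.

    Calibrates the porosity line for the target family (unless a ``fit``
    is supplied), solves ``(tau, c)``, samples the hybrid field over the
    envelope at ``resolution`` voxels per mm (default from
    :func:`default_resolution`), extracts the mesh, and measures it.
    """
    if fit is None:
        kwargs = {"seed": seed}
        if calibration_n is not None:
            kwargs["n"] = calibration_n
        fit = fit_porosity_line(target.family, **kwargs)
    params = solve_design(target, fit)

    shell_kwargs = {}
    if smoothing is not None:
        shell_kwargs["smoothing"] = smoothing
    shell = ShellSpec(
        R=target.envelope.radius,
        h=target.envelope.height,
        t=target.shell_thickness,
        orientation=orientation,
        **shell_kwargs,
    )
    field_fn = make_hybrid_field(params, shell)

    if resolution is None:
        resolution = default_resolution(params.tau, target.shell_thickness)
    grid = sample_grid(field_fn, target.envelope, resolution, tau=params.tau)
    mesh = extract_mesh(grid)
    design_echo = {
        "family": params.family.value,
        "target_porosity": target.porosity,
        "target_pore_radius_mm": target.pore_radius,
        "envelope_height_mm": target.envelope.height,
        "envelope_diameter_mm": target.envelope.diameter,
        "shell_thickness_mm": target.shell_thickness,
        "tau_per_mm": params.tau,
        "c": params.c,
        "design_pore_radius_mm": pore_radius(params),
        "porosity_fit": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "c_range": list(fit.c_range),
            "residual_rms": fit.residual_rms,
            "settings": fit.settings,
        },
        "orientation": orientation,
        "calibration_seed": seed,
    }
    report = measure_scaffold(mesh, target.envelope, grid=grid, design=design_echo)
    return DesignResult(params=params, fit=fit, shell=shell, grid=grid, mesh=mesh, report=report)
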