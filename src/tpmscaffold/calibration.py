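"""Porosity calibration and design solving for TPMS scaffolds.

The level constant ``c`` controls porosity almost linearly over the useful
range, so the design chain is: (1) measure the void fraction of a TPMS
field at several ``c`` values over one full-period cube, (2) fit the line
``rho = m*c + b`` by ordinary least squares, (3) invert it together with
the pore-radius relation

    r = (1 - c) / (a * tau),   a = 4 (gyroid), a = 8 (diamond)

to obtain ``(tau, c)`` from a target ``(rho, r)``.  Porosity of a periodic
field over a full period cube is independent of ``tau``, so the
calibration is performed once per family at ``tau = 1`` and reused for any
pore size.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .fields import (
    DEFAULT_C_RANGE,
    Cylinder,
    Family,
    TPMSParams,
    tpms_field,
)

__all__ = [
    "DesignTarget",
    "PorosityFit",
    "PorosityEstimate",
    "PORE_COEFFICIENT",
    "DEFAULT_CALIBRATION_SEED",
    "estimate_porosity",
    "fit_line",
    "fit_porosity_line",
    "pore_radius",
    "tau_from_pore",
    "solve_design",
    "save_fit",
    "load_fit",
]

# Pore-radius coefficient a in r = (1 - c) / (a * tau).
PORE_COEFFICIENT = {Family.GYROID: 4.0, Family.DIAMOND: 8.0}

DEFAULT_CALIBRATION_SEED = 20240472
DEFAULT_C_GRID = tuple(np.linspace(-0.6, 0.6, 9))
DEFAULT_MC_SAMPLES = 200_000

# Floors below which an estimate is too noisy to be meaningful.
MIN_MC_SAMPLES = 1_000
MIN_GRID_RESOLUTION = 8  # voxels per region edge


@dataclass(frozen=True)
class DesignTarget:
    """Scaffold design targets: what the solver must hit.

    Parameters
    ----------
    family : Family or str
        TPMS family, ``'G'`` or ``'D'``.
    porosity : float
        Target void fraction in (0, 1).
    pore_radius : float
        Target pore radius in mm; must be smaller than the envelope radius.
    envelope : Cylinder
        Cylindrical design envelope (height, diameter in mm).
    shell_thickness : float
        Solid shell thickness t in mm (0 disables the shell).
    """

    family: Family
    porosity: float
    pore_radius: float
    envelope: Cylinder
    shell_thickness: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family.coerce(self.family))
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")
        if self.pore_radius >= self.envelope.radius:
            raise ValueError(
                f"pore_radius {self.pore_radius} mm must be smaller than the "
                f"envelope radius {self.envelope.radius} mm"
            )
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")


@dataclass(frozen=True)
class PorosityEstimate:
    value: float
    stderr: float
    n: int
    method: str


@dataclass(frozen=True)
class PorosityFit:
    """Calibrated linear map ``rho = slope * c + intercept`` for one family."""

    family: Family
    slope: float
    intercept: float
    c_range: tuple[float, float]
    residual_rms: float
    n_points: int
    settings: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family.coerce(self.family))
        if self.slope >= 0:
            raise ValueError(
                "porosity must decrease with c under the solid sublevel-set "
                f"convention; got slope {self.slope}"
            )

    def predict(self, c) -> np.ndarray:
        return self.slope * np.asarray(c, dtype=float) + self.intercept

    def invert(self, porosity: float) -> float:
        """Level constant achieving the given porosity on the fitted line."""
        return (porosity - self.intercept) / self.slope


def _period_cube_sampler(tau: float):
    period = 1.0 / tau
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.random((n, 3)) * period
    return sample, period**3


def estimate_porosity(
    field_fn: Callable[[np.ndarray], np.ndarray],
    region: "Cylinder | float",
    *,
    method: str = "monte_carlo",
    n: int = DEFAULT_MC_SAMPLES,
    resolution: int = 64,
    seed: int | None = None,
) -> PorosityEstimate:
    """Void fraction ``measure{phi > 0} / measure(region)``.

    ``region`` is either a :class:`Cylinder` envelope or a float ``tau``
    meaning the full-period cube ``[0, 1/tau)^3``.  ``method='grid'``
    samples voxel centers at ``resolution`` voxels per region edge;
    ``method='monte_carlo'`` draws ``n`` uniform points (reproducible
    given ``seed``) and reports a binomial standard error.
    """
    if method not in ("grid", "monte_carlo"):
        raise ValueError(f"unknown porosity method {method!r}")

    if isinstance(region, Cylinder):
        def in_region(p):
            return region.contains(p)
        half = np.array([region.radius, region.radius, region.height / 2.0])
        lo, hi = -half, half
    else:
        tau = float(region)
        if tau <= 0:
            raise ValueError("period-cube region requires tau > 0")
        period = 1.0 / tau
        lo, hi = np.zeros(3), np.full(3, period)
        in_region = None  # whole box

    if method == "grid":
        if resolution < MIN_GRID_RESOLUTION:
            raise ValueError(
                f"grid resolution {resolution} below floor {MIN_GRID_RESOLUTION}"
            )
        axes = [lo[a] + (np.arange(resolution) + 0.5) * (hi[a] - lo[a]) / resolution
                for a in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        if in_region is not None:
            pts = pts[in_region(pts)]
        if pts.shape[0] == 0:
            raise ValueError("no grid points fall inside the region")
        void = np.asarray(field_fn(pts)) > 0.0
        m = void.size
        frac = float(np.count_nonzero(void)) / m
        return PorosityEstimate(frac, math.sqrt(max(frac * (1 - frac), 0.0) / m), m, "grid")

    if n < MIN_MC_SAMPLES:
        raise ValueError(f"monte_carlo n={n} below floor {MIN_MC_SAMPLES}")
    rng = np.random.default_rng(seed)
    kept = []
    remaining = n
    # rejection-sample into the region (box regions accept everything)
    while remaining > 0:
        draw = lo + rng.random((max(remaining, 1024), 3)) * (hi - lo)
        if in_region is not None:
            draw = draw[in_region(draw)]
        kept.append(draw[:remaining])
        remaining -= len(draw[:remaining])
    pts = np.concatenate(kept, axis=0)
    void = np.asarray(field_fn(pts)) > 0.0
    frac = float(np.count_nonzero(void)) / n
    return PorosityEstimate(
        frac, math.sqrt(max(frac * (1 - frac), 0.0) / n), n, "monte_carlo"
    )


def fit_line(c_values, porosities) -> tuple[float, float, float]:
    """Unweighted OLS line through (c, porosity) points: (slope, intercept, residual RMS)."""
    c = np.asarray(c_values, dtype=float)
    rho = np.asarray(porosities, dtype=float)
    slope, intercept = np.polyfit(c, rho, 1)
    rms = float(np.sqrt(np.mean((rho - (slope * c + intercept)) ** 2)))
    return float(slope), float(intercept), rms


def fit_porosity_line(
    family: Family | str,
    *,
    tau: float = 1.0,
    c_values: Sequence[float] = DEFAULT_C_GRID,
    method: str = "monte_carlo",
    n: int = DEFAULT_MC_SAMPLES,
    resolution: int = 64,
    seed: int = DEFAULT_CALIBRATION_SEED,
    residual_warn: float = 0.01,
) -> PorosityFit:
    """Measure porosity at each ``c`` over a full-period cube and fit the OLS line.

    Measured porosities must decrease monotonically in ``c``; estimator
    noise large enough to break monotonicity is rejected with advice to
    raise ``n``.  A residual RMS above ``residual_warn`` triggers a
    warning that the linear model is strained on this range.
    """
    family = Family.coerce(family)
    c_values = np.asarray(sorted(c_values), dtype=float)
    if len(np.unique(c_values)) < 5:
        raise ValueError("need at least 5 distinct c values to fit the porosity line")

    porosities = np.empty_like(c_values)
    for i, c in enumerate(c_values):
        params = TPMSParams(family, tau, float(c))
        est = estimate_porosity(
            tpms_field(params), tau,
            method=method, n=n, resolution=resolution,
            seed=None if seed is None else seed + i,
        )
        porosities[i] = est.value

    if not np.all(np.diff(porosities) < 0):
        raise ValueError(
            "measured porosities are not strictly decreasing in c; estimator "
            "noise is too high — raise n (monte_carlo) or resolution (grid)"
        )

    slope, intercept, rms = fit_line(c_values, porosities)
    if rms > residual_warn:
        import warnings

        warnings.warn(
            f"porosity line residual RMS {rms:.4f} exceeds {residual_warn}; "
            "the linear rho(c) model is strained on this c range",
            stacklevel=2,
        )
    return PorosityFit(
        family=family,
        slope=float(slope),
        intercept=float(intercept),
        c_range=(float(c_values[0]), float(c_values[-1])),
        residual_rms=rms,
        n_points=len(c_values),
        settings={"tau": tau, "method": method, "n": n,
                  "resolution": resolution, "seed": seed},
    )


def pore_radius(params: TPMSParams) -> float:
    """Design pore radius ``r = (1 - c) / (a * tau)`` in mm."""
    if params.c >= 1.0:
        raise ValueError(f"c={params.c} >= 1 gives a non-positive pore radius")
    a = PORE_COEFFICIENT[params.family]
    return (1.0 - params.c) / (a * params.tau)


def tau_from_pore(r: float, c: float, family: Family | str) -> float:
    """Invert the pore-radius relation: ``tau = (1 - c) / (a * r)``."""
    if r <= 0:
        raise ValueError("pore radius must be positive")
    if c >= 1.0:
        raise ValueError(f"c={c} >= 1 gives a non-positive pore radius")
    a = PORE_COEFFICIENT[Family.coerce(family)]
    return (1.0 - c) / (a * r)


def solve_design(target: DesignTarget, fit: PorosityFit) -> TPMSParams:
    """Solve ``(tau, c)`` from the design target via the calibrated line.

    ``c = (rho - b) / m`` then ``tau = (1 - c) / (a * r)``.  Extrapolation
    outside the calibrated ``c`` range is refused.
    """
    if fit.family is not Family.coerce(target.family):
        raise ValueError(
            f"fit is for family {fit.family.value}, target is {Family.coerce(target.family).value}"
        )
    c = fit.invert(target.porosity)
    lo, hi = fit.c_range
    if not lo <= c <= hi:
        rho_lo, rho_hi = sorted((fit.predict(lo), fit.predict(hi)))
        raise ValueError(
            f"target porosity {target.porosity} maps to c={c:.4f}, outside the "
            f"calibrated range [{lo}, {hi}] (porosities [{rho_lo:.3f}, {rho_hi:.3f}]); "
            "refusing to extrapolate"
        )
    tau = tau_from_pore(target.pore_radius, c, target.family)
    return TPMSParams(target.family, tau, c)


# ---------------------------------------------------------------------------
# Plain-text persistence so `design` runs are reproducible without refitting.

def save_fit(fit: PorosityFit, path: str | Path) -> None:
    """Write the fit as a plain-text key=value file."""
    lines = [
        f"family={fit.family.value}",
        f"slope={fit.slope!r}",
        f"intercept={fit.intercept!r}",
        f"c_min={fit.c_range[0]!r}",
        f"c_max={fit.c_range[1]!r}",
        f"residual_rms={fit.residual_rms!r}",
        f"n_points={fit.n_points}",
    ]
    for k, v in fit.settings.items():
        lines.append(f"setting.{k}={v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_fit(path: str | Path) -> PorosityFit:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    settings = {}
    for k, v in kv.items():
        if k.startswith("setting."):
            try:
                settings[k[8:]] = ast.literal_eval(v)
            except (ValueError, SyntaxError):
                settings[k[8:]] = v
    try:
        return PorosityFit(
            family=Family.coerce(kv["family"]),
            slope=float(kv["slope"]),
            intercept=float(kv["intercept"]),
            c_range=(float(kv["c_min"]), float(kv["c_max"])),
            residual_rms=float(kv["residual_rms"]),
            n_points=int(kv["n_points"]),
            settings=settings,
        )
    except KeyError as exc:
        raise ValueError(f"calibration file {path} is missing key {exc}") from None
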