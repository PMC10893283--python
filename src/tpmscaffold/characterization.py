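"""Resin and print characterization math.

Covers the desk-side analysis of a DLP resin workflow:

* vinyl-bond conversion from Raman C=C band areas,
  ``Cv = 1 - (I_C=C)_printed / (I_C=C)_liquid``;
* band-area integration (trapezoid above a linear endpoint baseline);
* axial stretch ``lambda = (L0 + Delta) / L0`` and engineering stress
  ``sigma = F / (pi * R0^2)`` from compression records, with Young's
  modulus extracted from the initial linear window and fracture detection;
* printability gates: dynamic viscosity <= 5000 mPa*s, Bond number
  ``Bo = delta_rho * g * L^2 / gamma_surface < 1`` (surface tension
  dominates gravity, stable liquid bridge), contact angle < 30 deg.

Synthetic fixture generators (Gaussian Raman bands, stress-strain curves
with a linear region, plateau and fracture drop) live here too, so every
operation is testable without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

__all__ = [
    "RamanBandAreas",
    "CompressionRecord",
    "FluidProperties",
    "GateReport",
    "vinyl_conversion",
    "integrate_band",
    "stretch_and_stress",
    "young_modulus",
    "bond_number",
    "printability_gates",
    "synthetic_raman_spectrum",
    "synthetic_compression_curve",
    "read_two_column",
    "VISCOSITY_LIMIT_MPA_S",
    "CONTACT_ANGLE_LIMIT_DEG",
    "BOND_NUMBER_LIMIT",
    "STANDARD_GRAVITY",
]

VISCOSITY_LIMIT_MPA_S = 5.0e3
CONTACT_ANGLE_LIMIT_DEG = 30.0
BOND_NUMBER_LIMIT = 1.0
STANDARD_GRAVITY = 9.81  # m/s^2

DEFAULT_BAND_WINDOW = (1620.0, 1660.0)  # cm^-1, C=C vinyl stretch ~1645


@dataclass(frozen=True)
class RamanBandAreas:
    """Integrated C=C band areas before (liquid) and after (printed) curing."""

    area_liquid: float
    area_printed: float
    band_window: tuple[float, float] = DEFAULT_BAND_WINDOW

    def __post_init__(self) -> None:
        if self.area_liquid <= 0:
            raise ValueError("liquid-resin band area must be positive")
        if self.area_printed < 0:
            raise ValueError("printed band area must be non-negative")


@dataclass(frozen=True)
class CompressionRecord:
    """Raw compression test: specimen geometry plus (displacement, load) samples.

    ``L0`` initial length mm, ``R0`` initial radius mm; ``displacement``
    is the crosshead travel Delta in mm (negative in compression after
    preload zeroing, first sample at 0), ``load`` in N.
    """

    L0: float
    R0: float
    displacement: np.ndarray
    load: np.ndarray

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.R0 <= 0:
            raise ValueError("L0 and R0 must be positive")
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.load, dtype=float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("displacement and load must be equal-length 1-D series")
        if d[0] != 0.0:
            raise ValueError("first sample must be at zero displacement (preload zeroed)")
        if not np.all(np.diff(np.abs(d)) >= 0):
            raise ValueError("samples must be ordered by |displacement|")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "load", f)


@dataclass(frozen=True)
class FluidProperties:
    """Inputs for the Bond number: all SI."""

    density_difference: float  # kg/m^3, fluid minus air
    surface_tension: float  # N/m
    characteristic_length: float  # m

    def __post_init__(self) -> None:
        for name in ("density_difference", "surface_tension", "characteristic_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def vinyl_conversion(bands: RamanBandAreas) -> float:
    """Fraction of vinyl C=C bonds consumed during curing.

    A printed band area larger than the liquid one would give a negative
    conversion; that signals inconsistent band integration and is an
    error, never silently clamped.
    """
    if bands.area_printed > bands.area_liquid:
        raise ValueError(
            f"printed band area {bands.area_printed} exceeds liquid area "
            f"{bands.area_liquid}: negative conversion indicates inconsistent "
            "band integration (check baselines and windows)"
        )
    return 1.0 - bands.area_printed / bands.area_liquid


def integrate_band(
    wavenumber,
    intensity,
    window: tuple[float, float] = DEFAULT_BAND_WINDOW,
) -> float:
    """Trapezoidal band area above a straight baseline between the window endpoints.

    The baseline is the chord through the spectrum values at the window
    edges (interpolated); a net-negative area is reported as 0 with a
    warning.  Requires >= 5 samples inside the window.
    """
    wn = np.asarray(wavenumber, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if wn.shape != y.shape or wn.ndim != 1:
        raise ValueError("wavenumber and intensity must be equal-length 1-D arrays")
    order = np.argsort(wn)
    wn, y = wn[order], y[order]
    lo, hi = sorted(window)
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(
            f"integration window [{lo}, {hi}] extends outside the spectrum "
            f"range [{wn[0]}, {wn[-1]}]"
        )
    sel = (wn >= lo) & (wn <= hi)
    if np.count_nonzero(sel) < 5:
        raise ValueError("fewer than 5 spectral points inside the integration window")
    y_lo = float(np.interp(lo, wn, y))
    y_hi = float(np.interp(hi, wn, y))
    xs = np.concatenate([[lo], wn[sel], [hi]])
    ys = np.concatenate([[y_lo], y[sel], [y_hi]])
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    baseline = y_lo + (y_hi - y_lo) * (xs - lo) / (hi - lo)
    area = float(np.trapezoid(ys - baseline, xs))
    if area < 0:
        import warnings

        warnings.warn(
            f"band area {area:.4g} is negative after baseline subtraction; "
            "reporting 0 (check the window placement)",
            stacklevel=2,
        )
        return 0.0
    return area


def stretch_and_stress(record: CompressionRecord) -> dict[str, np.ndarray]:
    """Axial stretch, engineering stress (MPa) and compressive strain series.

    ``lambda_i = (L0 + Delta_i) / L0`` (compressive Delta < 0 gives
    lambda < 1) and ``sigma_i = F_i / (pi R0^2)`` — MPa when F is in N
    and R0 in mm.  Strain is reported as ``1 - lambda`` so compression is
    positive.  A non-positive stretch (crush-through) is rejected.
    """
    lam = (record.L0 + record.displacement) / record.L0
    if np.any(lam <= 0):
        raise ValueError("non-physical stretch <= 0: displacement exceeds specimen length")
    sigma = record.load / (math.pi * record.R0**2)
    return {"stretch": lam, "stress": sigma, "strain": 1.0 - lam}


@dataclass(frozen=True)
class ModulusResult:
    modulus: float  # MPa
    window: tuple[float, float]  # strain bounds used for the fit
    r_squared: float
    n_points: int
    fracture_strain: float | None
    fracture_stress: float | None


def young_modulus(
    strain,
    stress,
    *,
    window: tuple[float, float] = (0.005, 0.025),
    r2_floor: float = 0.995,
    min_points: int = 10,
    drop_fraction: float = 0.20,
) -> ModulusResult:
    """Young's modulus from the initial linear region, plus the fracture point.

    Fits OLS over the default strain window (0.5-2.5%); if that window is
    not linear enough (R^2 below ``r2_floor``) it is shrunk from the
    right until it is.  Fewer than ``min_points`` admissible samples, or
    no window reaching the R^2 floor, signals a non-linear toe region.
    Fracture is the first sample whose stress drops more than
    ``drop_fraction`` below its running maximum.
    """
    eps = np.asarray(strain, dtype=float)
    sig = np.asarray(stress, dtype=float)
    if eps.shape != sig.shape or eps.ndim != 1:
        raise ValueError("strain and stress must be equal-length 1-D arrays")

    sel = np.flatnonzero((eps >= window[0]) & (eps <= window[1]))
    if sel.size < min_points:
        raise ValueError(
            f"only {sel.size} samples in the elastic window {window}; need >= {min_points}"
        )

    def fit(idx):
        slope, intercept = np.polyfit(eps[idx], sig[idx], 1)
        pred = slope * eps[idx] + intercept
        ss_res = float(np.sum((sig[idx] - pred) ** 2))
        ss_tot = float(np.sum((sig[idx] - np.mean(sig[idx])) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, r2

    idx = sel
    slope, r2 = fit(idx)
    while r2 < r2_floor and idx.size > min_points:
        idx = idx[:-1]
        slope, r2 = fit(idx)
    if r2 < r2_floor:
        raise ValueError(
            f"no leading window within strain {window} reaches R^2 >= {r2_floor} "
            f"(best {r2:.4f}); the toe region is non-linear"
        )

    frac_strain = frac_stress = None
    running_max = np.maximum.accumulate(sig)
    dropped = np.flatnonzero(sig < (1.0 - drop_fraction) * running_max)
    if dropped.size:
        k = int(dropped[0])
        peak = int(np.argmax(sig[: k + 1]))
        frac_strain = float(eps[peak])
        frac_stress = float(sig[peak])

    return ModulusResult(
        modulus=float(slope),
        window=(float(eps[idx[0]]), float(eps[idx[-1]])),
        r_squared=float(r2),
        n_points=int(idx.size),
        fracture_strain=frac_strain,
        fracture_stress=frac_stress,
    )


def bond_number(fluid: FluidProperties, g: float = STANDARD_GRAVITY) -> float:
    """Bond number ``Bo = delta_rho * g * L^2 / gamma``: gravity vs surface tension."""
    return (
        fluid.density_difference
        * g
        * fluid.characteristic_length**2
        / fluid.surface_tension
    )


@dataclass
class GateReport:
    """Independent pass/fail printability gates; ``None`` = not evaluated."""

    viscosity_mpa_s: float | None = None
    viscosity_pass: bool | None = None
    contact_angle_deg: float | None = None
    contact_angle_pass: bool | None = None
    bond: float | None = None
    bond_pass: bool | None = None
    notes: list = dc_field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        evaluated = [p for p in (self.viscosity_pass, self.contact_angle_pass, self.bond_pass)
                     if p is not None]
        return bool(evaluated) and all(evaluated)


def printability_gates(
    viscosity_mpa_s: float | None = None,
    contact_angle_deg: float | None = None,
    fluid: FluidProperties | None = None,
) -> GateReport:
    """Check a resin against the DLP printability thresholds.

    Viscosity passes at or below 5000 mPa*s (inclusive); the Bond number
    and contact angle gates are strict (< 1 and < 30 deg).  Gates without
    inputs are reported as not evaluated.
    """
    report = GateReport()
    if viscosity_mpa_s is not None:
        if viscosity_mpa_s <= 0:
            raise ValueError("viscosity must be positive")
        report.viscosity_mpa_s = float(viscosity_mpa_s)
        report.viscosity_pass = viscosity_mpa_s <= VISCOSITY_LIMIT_MPA_S
    else:
        report.notes.append("viscosity gate not evaluated (no input)")
    if contact_angle_deg is not None:
        if not 0 < contact_angle_deg < 180:
            raise ValueError("contact angle must be in (0, 180) degrees")
        report.contact_angle_deg = float(contact_angle_deg)
        report.contact_angle_pass = contact_angle_deg < CONTACT_ANGLE_LIMIT_DEG
    else:
        report.notes.append("contact-angle gate not evaluated (no input)")
    if fluid is not None:
        report.bond = bond_number(fluid)
        report.bond_pass = report.bond < BOND_NUMBER_LIMIT
    else:
        report.notes.append("Bond-number gate not evaluated (no fluid properties)")
    return report


# ---------------------------------------------------------------------------
# Synthetic fixture generators

def synthetic_raman_spectrum(
    *,
    amplitude: float = 1.0,
    center: float = 1645.0,
    sigma: float = 8.0,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    noise: float = 0.0,
    wn_range: tuple[float, float] = (1500.0, 1800.0),
    n: int = 601,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian C=C band on a linear baseline; analytic area ``amplitude*sigma*sqrt(2*pi)``."""
    rng = np.random.default_rng(seed)
    wn = np.linspace(*wn_range, n)
    y = amplitude * np.exp(-0.5 * ((wn - center) / sigma) ** 2)
    y += baseline_offset + baseline_slope * (wn - wn_range[0])
    if noise > 0:
        y = y + rng.normal(0.0, noise, size=n)
    return wn, y


def synthetic_compression_curve(
    *,
    modulus: float = 1.0,  # MPa
    L0: float = 10.0,  # mm
    R0: float = 5.0,  # mm
    fracture_strain: float = 0.15,
    yield_strain: float = 0.08,
    noise: float = 0.0,  # relative stress noise
    n: int = 400,
    max_strain: float = 0.20,
    seed: int | None = None,
) -> CompressionRecord:
    """Linear elastic region, softening plateau, then a sharp post-fracture drop.

    Stress follows ``sigma = E * eps`` up to ``yield_strain``, continues
    at one third the slope to ``fracture_strain``, then collapses to 10 %
    of the peak.  Multiplicative Gaussian noise (relative std ``noise``)
    is applied with the given seed.  Returned as a raw
    :class:`CompressionRecord` (displacement = -eps * L0, load =
    sigma * pi * R0^2).
    """
    if not 0 < yield_strain < fracture_strain < max_strain:
        raise ValueError("require 0 < yield_strain < fracture_strain < max_strain")
    rng = np.random.default_rng(seed)
    eps = np.linspace(0.0, max_strain, n)
    sigma_y = modulus * yield_strain
    sigma = np.where(
        eps <= yield_strain,
        modulus * eps,
        sigma_y + (modulus / 3.0) * (eps - yield_strain),
    )
    peak = sigma_y + (modulus / 3.0) * (fracture_strain - yield_strain)
    sigma = np.where(eps > fracture_strain, 0.1 * peak, sigma)
    if noise > 0:
        sigma = sigma * (1.0 + rng.normal(0.0, noise, size=n))
        sigma[0] = 0.0
    return CompressionRecord(
        L0=L0,
        R0=R0,
        displacement=-eps * L0,
        load=sigma * math.pi * R0**2,
    )


def read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited two-column text file with a one-line header."""
    data = np.genfromtxt(Path(path), delimiter=None, skip_header=1)
    if data.ndim != 2 or data.shape[1] < 2:
        # retry comma-delimited
        data = np.genfromtxt(Path(path), delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited numeric columns after a header line")
    return data[:, 0], data[:, 1]
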