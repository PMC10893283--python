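"""Vinyl conversion, band integration, stress-strain processing, printability gates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpmscaffold import (
    CompressionRecord,
    FluidProperties,
    RamanBandAreas,
    bond_number,
    integrate_band,
    printability_gates,
    stretch_and_stress,
    vinyl_conversion,
    young_modulus,
)
from tpmscaffold.characterization import (
    read_two_column,
    synthetic_compression_curve,
    synthetic_raman_spectrum,
)


class TestVinylConversion:
    @pytest.mark.parametrize(
        "liquid, printed, expected",
        [(5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (1.0, 0.27, 0.73)],
    )
    def test_band_ratio(self, liquid, printed, expected):
        cv = vinyl_conversion(RamanBandAreas(liquid, printed))
        assert cv == pytest.approx(expected, abs=1e-12)

    def test_negative_conversion_is_an_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            vinyl_conversion(RamanBandAreas(1.0, 1.5))

    def test_invalid_areas(self):
        with pytest.raises(ValueError):
            RamanBandAreas(0.0, 0.5)
        with pytest.raises(ValueError):
            RamanBandAreas(1.0, -0.1)

    @settings(deadline=None, max_examples=50)
    @given(k=st.floats(1e-3, 1e3), ratio=st.floats(0.0, 1.0))
    def test_scale_invariance(self, k, ratio):
        """Multiplying both band areas by k leaves the conversion unchanged."""
        base = vinyl_conversion(RamanBandAreas(1.0, ratio))
        scaled = vinyl_conversion(RamanBandAreas(k, k * ratio))
        assert scaled == pytest.approx(base, abs=1e-9)


class TestIntegrateBand:
    def test_rectangle_gives_window_width(self):
        wn = np.linspace(1600, 1680, 801)
        y = np.where((wn >= 1620) & (wn <= 1660), 1.0, 0.0)
        # endpoints at exactly 1 -> chord baseline at 1; use interior rectangle
        y_rect = np.ones_like(wn)
        area = integrate_band(wn, y_rect, window=(1620, 1660))
        assert area == pytest.approx(0.0, abs=1e-9)  # flat chord subtracts it
        area2 = integrate_band(wn, y, window=(1610, 1670))
        assert area2 == pytest.approx(40.0, abs=0.2)  # half-sample edge trapezoids

    def test_linear_ramp_integrates_to_zero(self):
        wn = np.linspace(1600, 1700, 501)
        y = 0.02 * (wn - 1600.0)
        assert integrate_band(wn, y, window=(1620, 1660)) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_band_matches_analytic_area(self):
        wn, y = synthetic_raman_spectrum(
            amplitude=2.0, sigma=6.0, baseline_slope=0.001, baseline_offset=0.3
        )
        area = integrate_band(wn, y, window=(1645 - 30, 1645 + 30))
        analytic = 2.0 * 6.0 * math.sqrt(2 * math.pi)
        assert area == pytest.approx(analytic, rel=0.01)

    def test_window_outside_spectrum_rejected(self):
        wn = np.linspace(1600, 1700, 101)
        with pytest.raises(ValueError, match="window"):
            integrate_band(wn, np.ones_like(wn), window=(1500, 1650))

    def test_net_negative_area_warns_and_clamps(self):
        wn = np.linspace(1600, 1700, 101)
        y = -np.exp(-0.5 * ((wn - 1650) / 5) ** 2)  # inverted band
        with pytest.warns(UserWarning, match="negative"):
            assert integrate_band(wn, y, window=(1620, 1680)) == 0.0


class TestStretchAndStress:
    def test_hand_values(self):
        rec = CompressionRecord(
            L0=10.0, R0=1.0,
            displacement=np.array([0.0, -1.0]),
            load=np.array([0.0, math.pi]),
        )
        out = stretch_and_stress(rec)
        assert out["stretch"][0] == pytest.approx(1.0)
        assert out["stress"][0] == pytest.approx(0.0)
        assert out["stretch"][1] == pytest.approx(0.9)
        assert out["stress"][1] == pytest.approx(1.0)  # pi N / (pi * 1 mm^2) = 1 MPa
        assert out["strain"][1] == pytest.approx(0.1)

    def test_stress_linear_in_load(self):
        rec1 = CompressionRecord(10.0, 2.0, np.array([0.0, -0.5]), np.array([0.0, 3.0]))
        rec2 = CompressionRecord(10.0, 2.0, np.array([0.0, -0.5]), np.array([0.0, 6.0]))
        s1 = stretch_and_stress(rec1)["stress"][1]
        s2 = stretch_and_stress(rec2)["stress"][1]
        assert s2 == pytest.approx(2 * s1)

    def test_crush_through_rejected(self):
        rec = CompressionRecord(10.0, 1.0, np.array([0.0, -10.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="stretch"):
            stretch_and_stress(rec)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="zero displacement"):
            CompressionRecord(10.0, 1.0, np.array([-0.1, -0.2]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="ordered"):
            CompressionRecord(10.0, 1.0, np.array([0.0, -0.5, -0.2]), np.array([0.0, 1, 2]))
        with pytest.raises(ValueError, match="positive"):
            CompressionRecord(-1.0, 1.0, np.array([0.0]), np.array([0.0]))


class TestYoungModulus:
    def test_exact_line_recovered(self):
        eps = np.linspace(0.0, 0.05, 200)
        res = young_modulus(eps, 0.94 * eps)
        assert res.modulus == pytest.approx(0.94, abs=1e-9)
        assert res.fracture_strain is None

    def test_noisy_curve_within_three_percent(self):
        rec = synthetic_compression_curve(modulus=1.0, noise=0.01, n=200, seed=42)
        out = stretch_and_stress(rec)
        res = young_modulus(out["strain"], out["stress"])
        assert res.modulus == pytest.approx(1.0, rel=0.03)

    def test_median_recovery_error_under_two_percent(self):
        """Across 100 seeds and moduli {0.5, 1, 2} MPa with 1% noise."""
        for E in (0.5, 1.0, 2.0):
            errors = []
            for seed in range(100):
                rec = synthetic_compression_curve(modulus=E, noise=0.01, n=200, seed=seed)
                out = stretch_and_stress(rec)
                res = young_modulus(out["strain"], out["stress"])
                errors.append(abs(res.modulus - E) / E)
            assert np.median(errors) < 0.02

    def test_bilinear_curve_returns_leading_slope(self):
        """A stiffness change mid-curve must not contaminate the elastic fit."""
        eps = np.linspace(0.0, 0.08, 500)
        E = 2.0
        knee = 0.03  # past the 0.5-2.5% elastic window
        sig = np.where(eps <= knee, E * eps, E * knee + (E / 3) * (eps - knee))
        res = young_modulus(eps, sig)
        assert res.modulus == pytest.approx(E, rel=1e-9)
        assert res.window[1] <= knee

    def test_fracture_detection(self):
        rec = synthetic_compression_curve(modulus=1.0, fracture_strain=0.15, seed=0)
        out = stretch_and_stress(rec)
        res = young_modulus(out["strain"], out["stress"])
        assert res.fracture_strain == pytest.approx(0.15, abs=0.01)
        assert res.fracture_stress is not None and res.fracture_stress > 0

    def test_nonlinear_toe_rejected(self):
        eps = np.linspace(0.0, 0.05, 300)
        sig = eps**3  # no linear leading window
        with pytest.raises(ValueError, match="non-linear"):
            young_modulus(eps, sig, r2_floor=0.99999)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            young_modulus(np.linspace(0, 0.05, 8), np.linspace(0, 0.05, 8))


class TestPrintabilityGates:
    def test_viscosity_boundary(self):
        assert printability_gates(viscosity_mpa_s=4999.0).viscosity_pass
        assert printability_gates(viscosity_mpa_s=5000.0).viscosity_pass  # inclusive
        assert not printability_gates(viscosity_mpa_s=5001.0).viscosity_pass

    def test_contact_angle_strict_threshold(self):
        assert printability_gates(contact_angle_deg=29.9).contact_angle_pass
        assert not printability_gates(contact_angle_deg=30.0).contact_angle_pass

    def test_bond_number_arithmetic(self):
        """delta_rho = 1000 kg/m^3, L = 1 mm, gamma = 0.05 N/m -> Bo ~ 0.196."""
        fluid = FluidProperties(1000.0, 0.05, 1e-3)
        assert bond_number(fluid) == pytest.approx(0.1962, abs=1e-4)
        rep = printability_gates(fluid=fluid)
        assert rep.bond_pass

    def test_bond_gate_trips_at_one(self):
        # L chosen so Bo slightly exceeds 1
        fluid = FluidProperties(1000.0, 0.05, 2.26e-3)
        assert bond_number(fluid) > 1.0
        assert not printability_gates(fluid=fluid).bond_pass

    def test_bond_monotone_in_length_and_density(self):
        base = bond_number(FluidProperties(1000.0, 0.05, 1e-3))
        assert bond_number(FluidProperties(1000.0, 0.05, 2e-3)) == pytest.approx(4 * base)
        assert bond_number(FluidProperties(2000.0, 0.05, 1e-3)) == pytest.approx(2 * base)

    def test_missing_inputs_not_evaluated(self):
        rep = printability_gates()
        assert rep.viscosity_pass is None
        assert rep.bond_pass is None
        assert not rep.all_pass
        assert len(rep.notes) == 3


def test_read_two_column(tmp_path):
    path = tmp_path / "curve.csv"
    path.write_text("displacement_mm,load_N\n0.0,0.0\n-0.5,12.5\n-1.0,25.0\n")
    x, y = read_two_column(path)
    assert x.tolist() == [0.0, -0.5, -1.0]
    assert y.tolist() == [0.0, 12.5, 25.0]
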