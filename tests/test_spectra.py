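"""Spectrum container, I/O, unit conversion and band integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photodose.spectra import (
    PAR,
    UV,
    UVA,
    UVB,
    AbsorbanceSpectrum,
    SpectralIrradiance,
    Waveband,
    energy_to_photon,
    extract_band_summary,
    integrate_band,
    read_spectrum,
    resample,
    write_spectrum,
)

from .conftest import flat_spectrum, smooth_random_spectrum

# CODATA constants, written out independently of scipy.constants
_H = 6.62607015e-34
_C = 299792458.0
_NA = 6.02214076e23


class TestContainer:
    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            SpectralIrradiance(np.array([300.0, 299.0, 301.0]), np.ones(3))

    def test_negative_values_clipped_and_counted(self):
        s = SpectralIrradiance(np.array([300.0, 301.0, 302.0]),
                               np.array([1.0, -0.01, 2.0]))
        assert s.values[1] == 0.0
        assert s.clip_count == 1

    def test_waveband_requires_lower_below_upper(self):
        with pytest.raises(ValueError):
            Waveband("bad", 400.0, 400.0)

    def test_roundtrip_identity(self, tmp_path):
        s = flat_spectrum(1.2345, meta={"stand": "betula_old", "doy": 115,
                                        "position": "shade", "point": "2"})
        path = tmp_path / "s.csv"
        write_spectrum(s, path)
        back = read_spectrum(path)
        np.testing.assert_array_equal(back.wavelengths_nm, s.wavelengths_nm)
        np.testing.assert_array_equal(back.values, s.values)
        assert back.unit == s.unit
        assert back.meta["stand"] == "betula_old"
        assert back.meta["doy"] == 115

    def test_read_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# unit=photon\nlambda,flux\n300,1\n301,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_spectrum(path)


class TestUnitConversion:
    @pytest.mark.parametrize("lam", [400.0, 500.0])
    def test_energy_to_photon_matches_hc_lambda_oracle(self, lam):
        s = SpectralIrradiance(np.array([lam, lam + 1]), np.array([1.0, 1.0]),
                               unit="energy")
        out = energy_to_photon(s)
        expected = (lam * 1e-9) / (_H * _C * _NA) * 1e6  # µmol m-2 s-1 nm-1
        assert out.values[0] == pytest.approx(expected, rel=1e-6)
        assert out.unit == "photon"

    def test_zero_energy_gives_zero_photons(self):
        s = flat_spectrum(0.0, unit="energy")
        assert np.all(energy_to_photon(s).values == 0.0)

    def test_wrong_unit_flag_rejected(self):
        with pytest.raises(ValueError, match="energy"):
            energy_to_photon(flat_spectrum(1.0, unit="photon"))

    def test_photon_yield_doubles_between_400_and_800(self):
        s = SpectralIrradiance(np.array([400.0, 800.0]), np.array([1.0, 1.0]),
                               unit="energy")
        out = energy_to_photon(s)
        assert out.values[1] / out.values[0] == pytest.approx(2.0, rel=1e-12)


class TestResample:
    def test_identity_on_same_grid(self):
        s = smooth_random_spectrum(np.random.default_rng(0))
        out = resample(s, s.wavelengths_nm)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_midpoint(self):
        s = SpectralIrradiance(np.array([400.0, 402.0]), np.array([1.0, 3.0]))
        assert resample(s, np.array([400.0, 401.0, 402.0])).values[1] == 2.0

    def test_no_extrapolation(self):
        s = flat_spectrum(1.0, lo=300, hi=400)
        with pytest.raises(ValueError, match="does not contain"):
            resample(s, np.array([250.0, 350.0]))

    def test_superset_grid_preserves_band_integrals(self):
        s = smooth_random_spectrum(np.random.default_rng(3))
        superset = np.union1d(s.wavelengths_nm,
                              np.arange(280.25, 900.0, 0.5))
        fine = resample(s, superset)
        for band in (UVB, UVA, PAR):
            a, b = integrate_band(s, band), integrate_band(fine, band)
            assert b == pytest.approx(a, rel=1e-6)


class TestIntegration:
    def test_flat_spectrum_band_values_exact(self):
        s = flat_spectrum(1.0)
        assert integrate_band(s, UVB) == pytest.approx(35.0, abs=1e-9)
        assert integrate_band(s, UVA) == pytest.approx(85.0, abs=1e-9)
        assert integrate_band(s, PAR) == pytest.approx(300.0, abs=1e-9)

    def test_quadratic_matches_analytic_antiderivative(self):
        a, b, c = 1.0, 1e-3, 1e-6
        grid = np.arange(280.0, 900.25, 0.5)
        s = SpectralIrradiance(grid, a + b * grid + c * grid ** 2)
        lo, hi = PAR.lower_nm, PAR.upper_nm
        exact = (a * (hi - lo) + b / 2 * (hi ** 2 - lo ** 2)
                 + c / 3 * (hi ** 3 - lo ** 3))
        assert integrate_band(s, PAR) == pytest.approx(exact, rel=1e-6)

    def test_energy_units_rejected(self):
        with pytest.raises(ValueError, match="photon"):
            integrate_band(flat_spectrum(1.0, unit="energy"), PAR)

    def test_insufficient_coverage(self):
        with pytest.raises(ValueError, match="does not contain"):
            integrate_band(flat_spectrum(1.0, lo=400, hi=900), UVB)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_band_partition_uvb_plus_uva_is_uv(self, seed):
        s = smooth_random_spectrum(np.random.default_rng(seed))
        total = integrate_band(s, UV)
        parts = integrate_band(s, UVB) + integrate_band(s, UVA)
        assert parts == pytest.approx(total, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=0.1, max_value=10))
    def test_integration_is_linear(self, seed, a, b):
        rng = np.random.default_rng(seed)
        s1 = smooth_random_spectrum(rng)
        s2 = smooth_random_spectrum(rng)
        combo = SpectralIrradiance(s1.wavelengths_nm,
                                   a * s1.values + b * s2.values)
        expected = a * integrate_band(s1, PAR) + b * integrate_band(s2, PAR)
        assert integrate_band(combo, PAR) == pytest.approx(expected, rel=1e-10)


class TestExtractSummary:
    def test_constant_absorbance(self):
        grid = np.arange(190.0, 900.5, 1.0)
        a = AbsorbanceSpectrum(grid, np.full(grid.size, 0.5))
        out = extract_band_summary(a)
        for key in ("A375", "mean_UVB", "mean_UVA", "mean_UV"):
            assert out[key] == pytest.approx(0.5, rel=1e-12)

    def test_linear_ramp_mean_is_band_midpoint_value(self):
        grid = np.arange(190.0, 900.5, 1.0)
        ramp = 0.001 * grid
        out = extract_band_summary(AbsorbanceSpectrum(grid, ramp))
        assert out["mean_UVA"] == pytest.approx(0.001 * 357.5, rel=1e-9)

    def test_normalization_arithmetic(self):
        grid = np.arange(190.0, 900.5, 1.0)
        a = AbsorbanceSpectrum(grid, np.ones(grid.size), dilution=2.0,
                               volume_ml=3.0, fresh_weight_g=0.05)
        out = extract_band_summary(a)
        assert out["mean_UV_normalized"] == pytest.approx(120.0, rel=1e-9)

    def test_nonpositive_fresh_weight_rejected(self):
        grid = np.arange(190.0, 900.5, 1.0)
        a = AbsorbanceSpectrum(grid, np.ones(grid.size))
        a.fresh_weight_g = 0.0
        with pytest.raises(ValueError, match="fresh weight"):
            extract_band_summary(a)
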