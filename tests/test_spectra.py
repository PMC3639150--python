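"""Spectrum container, CSV I/O and grid arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zerocross as zc
from zerocross.errors import GridError, ParseError, RangeError

from conftest import gaussian_spectrum


class TestSpectrumInvariants:
    def test_rejects_decreasing_grid(self):
        with pytest.raises(GridError):
            zc.Spectrum([3.0, 2.0, 1.0], [0.1, 0.2, 0.3])

    def test_rejects_non_uniform_grid(self):
        with pytest.raises(GridError):
            zc.Spectrum([200.0, 200.5, 201.2], [0.1, 0.2, 0.3])

    def test_rejects_length_mismatch_and_nonfinite(self):
        with pytest.raises(GridError):
            zc.Spectrum([200.0, 200.5], [0.1])
        with pytest.raises(ParseError):
            zc.Spectrum([200.0, 200.5], [0.1, np.nan])

    def test_spacing(self):
        s = zc.Spectrum([200.0, 200.5, 201.0], [0.1, 0.2, 0.3])
        assert s.spacing_nm == pytest.approx(0.5)
        assert len(s) == 3


class TestCsvIO:
    def test_headerless_read(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("200,0.1\n200.5,0.2\n201,0.3\n")
        s = zc.read_spectrum_csv(p, "x")
        assert len(s) == 3
        assert s.spacing_nm == pytest.approx(0.5)
        assert s.sample_id == "x"

    def test_rows_sorted_by_wavelength(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,absorbance\n201,0.3\n200,0.1\n200.5,0.2\n")
        s = zc.read_spectrum_csv(p)
        assert np.allclose(s.absorbance, [0.1, 0.2, 0.3])

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("250,0.1\n250,0.2\n251,0.3\n")
        with pytest.raises(ParseError, match="250"):
            zc.read_spectrum_csv(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,absorbance\n200,0.1\n200.5,oops\n")
        with pytest.raises(ParseError, match="oops"):
            zc.read_spectrum_csv(p)

    def test_roundtrip_identity(self, tmp_path):
        s = gaussian_spectrum()
        p = tmp_path / "g.csv"
        zc.write_spectrum_csv(s, p)
        back = zc.read_spectrum_csv(p, s.sample_id)
        assert np.array_equal(back.wavelengths_nm, s.wavelengths_nm)
        assert np.array_equal(back.absorbance, s.absorbance)

    def test_spectrum_set_roundtrip(self, tmp_path, clin_calib_spectra):
        p = tmp_path / "set.csv"
        zc.write_spectrum_set_csv(clin_calib_spectra, p)
        back = zc.read_spectrum_set_csv(p)
        assert back.sample_ids == clin_calib_spectra.sample_ids
        for a, b in zip(back, clin_calib_spectra):
            assert np.array_equal(a.absorbance, b.absorbance)

    def test_design_roundtrip(self, tmp_path, clin_design):
        p = tmp_path / "d.csv"
        zc.write_design_csv(clin_design, p)
        back = zc.read_design_csv(p)
        assert back.analytes == clin_design.analytes
        assert np.array_equal(
            back.concentrations("clindamycin"),
            clin_design.concentrations("clindamycin"),
        )

    def test_design_duplicate_sample_id_rejected(self):
        with pytest.raises(ParseError):
            zc.design_from_rows([("a", {"x": 1.0}), ("a", {"x": 2.0})])


class TestBlankSubtract:
    def test_self_subtraction_is_zero(self, pure_tretinoin):
        out = zc.blank_subtract(pure_tretinoin, pure_tretinoin)
        assert np.all(out.absorbance == 0.0)
        assert out.sample_id == pure_tretinoin.sample_id

    def test_constant_difference(self, grid):
        sample = zc.Spectrum(grid, np.full(grid.size, 0.5), "s")
        blank = zc.Spectrum(grid, np.full(grid.size, 0.2), "b")
        assert np.allclose(zc.blank_subtract(sample, blank).absorbance, 0.3)

    def test_grid_mismatch_rejected(self, grid):
        sample = zc.Spectrum(grid, np.zeros(grid.size))
        blank = zc.Spectrum(grid[:-1], np.zeros(grid.size - 1))
        with pytest.raises(GridError):
            zc.blank_subtract(sample, blank)

    def test_baseline_blank_recovers_pure_mixture(self, grid):
        """Subtracting an excipient-only baseline from a noiseless mixture
        measured over the same baseline recovers the pure analyte sum."""
        drift = zc.NoiseModel(additive_sd=0, multiplicative_sd=0, baseline_drift=0.02)
        mix = zc.mixture_spectrum(
            [(zc.CLINDAMYCIN_LIKE, 600.0), (zc.TRETINOIN_LIKE, 12.5)],
            noise=drift, grid=grid, sample_id="gel",
        )
        blank = zc.mixture_spectrum([], noise=drift, grid=grid, sample_id="blank")
        pure_sum = (
            zc.species_spectrum(zc.CLINDAMYCIN_LIKE, 600.0, grid).absorbance
            + zc.species_spectrum(zc.TRETINOIN_LIKE, 12.5, grid).absorbance
        )
        out = zc.blank_subtract(mix, blank)
        assert np.max(np.abs(out.absorbance - pure_sum)) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-2, 2), st.floats(-1, 1))
    def test_subtract_then_add_restores(self, a, b):
        g = np.arange(200.0, 210.0, 0.5)
        sample = zc.Spectrum(g, np.full(g.size, a))
        blank = zc.Spectrum(g, np.full(g.size, b))
        out = zc.blank_subtract(sample, blank)
        assert np.max(np.abs(out.absorbance + blank.absorbance - sample.absorbance)) < 1e-12


class TestResample:
    def test_identity_grid(self, pure_tretinoin):
        out = zc.resample_to_grid(pure_tretinoin, pure_tretinoin.wavelengths_nm)
        assert np.allclose(out.absorbance, pure_tretinoin.absorbance)

    def test_linear_function_exact_on_finer_grid(self):
        g = np.arange(200.0, 301.0, 1.0)
        s = zc.Spectrum(g, 0.01 * g)
        fine = np.arange(200.0, 300.25, 0.25)
        out = zc.resample_to_grid(s, fine)
        assert np.max(np.abs(out.absorbance - 0.01 * fine)) < 1e-12

    @pytest.mark.parametrize("width", [10.0, 20.0, 30.0])
    def test_gaussian_band_interpolation_error(self, width):
        """Linear interpolation error for a 1.0 -> 0.5 nm resample of a
        Gaussian band is bounded by h^2/8 * max|A''| = h^2/(8*width^2)."""
        g = np.arange(200.0, 501.0, 1.0)
        s = gaussian_spectrum(center=364.0, width=width, grid=g)
        fine = np.arange(200.0, 500.5, 0.5)
        out = zc.resample_to_grid(s, fine)
        analytic = np.exp(-((fine - 364.0) ** 2) / (2 * width**2))
        assert np.max(np.abs(out.absorbance - analytic)) < 1.0 / (8 * width**2)

    def test_twice_equals_once_for_piecewise_linear(self):
        g = np.arange(200.0, 241.0, 1.0)
        s = zc.Spectrum(g, np.abs(g - 220.0))
        mid = np.arange(200.0, 240.5, 0.5)
        final = np.arange(200.0, 240.25, 0.25)
        once = zc.resample_to_grid(s, final)
        twice = zc.resample_to_grid(zc.resample_to_grid(s, mid), final)
        assert np.max(np.abs(once.absorbance - twice.absorbance)) < 1e-12

    def test_extrapolation_rejected(self, pure_tretinoin):
        bad = np.arange(150.0, 300.0, 0.5)
        with pytest.raises(RangeError):
            zc.resample_to_grid(pure_tretinoin, bad)
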