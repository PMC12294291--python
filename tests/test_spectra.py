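"""Spectrum model, CSV I/O, Savitzky-Golay smoothing and band extraction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copigmentation.spectra import (
    SampleMeta,
    Spectrum,
    absorbance_at,
    band_ratio,
    find_lambda_max,
    read_metadata,
    read_spectra,
    smooth_savitzky_golay,
    write_metadata,
    write_spectra,
)


class TestSpectrumModel:
    def test_rejects_non_monotonic_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([500.0, 502.0, 501.0]), np.zeros(3))

    def test_rejects_length_mismatch_and_nan(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError, match="finite"):
            Spectrum(np.array([1.0, 2.0]), np.array([0.1, np.nan]))

    def test_baseline_tolerance(self):
        wl = np.array([500.0, 501.0])
        Spectrum(wl, np.array([-0.004, 0.1]))  # within tolerance
        with pytest.raises(ValueError, match="baseline"):
            Spectrum(wl, np.array([-0.02, 0.1]))

    def test_meta_validates_ph_and_concentration_consistency(self):
        with pytest.raises(ValueError, match="pH"):
            SampleMeta(pH=5.0)
        with pytest.raises(ValueError, match="inconsistent"):
            SampleMeta(molar_ratio=20, pigment_conc=5e-5, copigment_conc=2e-3)
        m = SampleMeta(molar_ratio=20, pigment_conc=5e-5, copigment_conc=1e-3)
        assert m.copigment_conc == pytest.approx(1e-3)


class TestIO:
    def test_long_format_minimal(self):
        csv = "sample_id,wavelength_nm,absorbance\ns1,500,0.1\ns1,501,0.2\ns1,502,0.1\n"
        out = read_spectra(io.StringIO(csv))
        assert list(out) == ["s1"] and len(out["s1"]) == 3

    def test_long_format_unordered_names_offending_row(self):
        csv = "sample_id,wavelength_nm,absorbance\ns1,502,0.1\ns1,500,0.2\ns1,501,0.1\n"
        with pytest.raises(ValueError, match="non-monotonic.*row 3"):
            read_spectra(io.StringIO(csv))

    def test_duplicate_wavelength_rejected(self):
        csv = "sample_id,wavelength_nm,absorbance\ns1,500,0.1\ns1,500,0.2\ns1,501,0.1\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra(io.StringIO(csv))

    def test_missing_metadata_rejected(self):
        csv = "sample_id,wavelength_nm,absorbance\ns1,500,0.1\ns1,501,0.2\n"
        with pytest.raises(ValueError, match="missing from metadata"):
            read_spectra(io.StringIO(csv), metadata={})

    def test_wide_roundtrip_bitwise(self, tmp_path, grid, rng):
        spectra = {
            f"s{i}": Spectrum(grid, rng.uniform(0.0, 1.5, size=grid.size))
            for i in range(2)
        }
        path = tmp_path / "wide.csv"
        write_spectra(spectra, path, fmt="wide")
        back = read_spectra(path)
        assert set(back) == set(spectra)
        for sid in spectra:
            assert len(back[sid]) == 401
            np.testing.assert_array_equal(back[sid].absorbance, spectra[sid].absorbance)
            np.testing.assert_array_equal(back[sid].wavelengths, grid)

    def test_long_roundtrip_with_metadata(self, tmp_path, grid):
        meta = SampleMeta(copigment="CAF", pH=3.6, molar_ratio=20,
                          copigment_conc=1e-3, replicate=2, timepoint="T12")
        spectra = {"a": Spectrum(grid, np.full(grid.size, 0.3), meta)}
        write_spectra(spectra, tmp_path / "s.csv", fmt="long")
        write_metadata(spectra, tmp_path / "m.csv")
        back = read_spectra(tmp_path / "s.csv", metadata=read_metadata(tmp_path / "m.csv"))
        assert back["a"].meta.copigment == "CAF"
        assert back["a"].meta.molar_ratio == 20
        np.testing.assert_array_equal(back["a"].absorbance, spectra["a"].absorbance)


class TestSavitzkyGolay:
    def test_preserves_constants(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.5))
        out = smooth_savitzky_golay(s)
        np.testing.assert_allclose(out.absorbance, 0.5, atol=1e-12)

    def test_preserves_cubic_exactly(self, grid):
        s = Spectrum(grid, 1e-6 * grid**3)
        out = smooth_savitzky_golay(s, window=9, order=3)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-8)

    def test_reduces_white_noise_variance(self, grid, rng):
        noise = rng.normal(0.0, 0.01, size=grid.size)
        s = Spectrum(grid, 0.5 + noise)
        out = smooth_savitzky_golay(s)
        assert np.var(out.absorbance) < np.var(s.absorbance)

    @pytest.mark.parametrize("window,order", [(8, 3), (9, 9), (9, 10), (1, 0)])
    def test_invalid_parameters(self, grid, window, order):
        s = Spectrum(grid, np.full(grid.size, 0.5))
        with pytest.raises(ValueError):
            smooth_savitzky_golay(s, window=window, order=order)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(-2, 2), st.floats(-2, 2))
    def test_linearity(self, seed, a, b):
        grid = np.arange(300.0, 351.0)
        r = np.random.default_rng(seed)
        s1 = Spectrum(grid, r.uniform(0, 1, grid.size), baseline_tol=-np.inf)
        s2 = Spectrum(grid, r.uniform(0, 1, grid.size), baseline_tol=-np.inf)
        combo = Spectrum(grid, a * s1.absorbance + b * s2.absorbance,
                         baseline_tol=-np.inf)
        lhs = smooth_savitzky_golay(combo).absorbance
        rhs = (a * smooth_savitzky_golay(s1).absorbance
               + b * smooth_savitzky_golay(s2).absorbance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_provenance_note_recorded(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.5))
        out = smooth_savitzky_golay(s, window=9, order=3)
        assert any("savgol" in note for note in out.meta.provenance)


class TestAbsorbanceAt:
    def test_exact_grid_hit_and_midpoint(self):
        s = Spectrum(np.array([522.0, 523.0, 524.0]), np.array([0.10, 0.20, 0.10]))
        assert absorbance_at(s, 523.0) == pytest.approx(0.20)
        assert absorbance_at(s, 522.5) == pytest.approx(0.15)

    def test_out_of_span(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.2))
        with pytest.raises(ValueError, match="outside"):
            absorbance_at(s, 299.0)

    def test_monotone_on_monotone_segment(self):
        s = Spectrum(np.array([500.0, 501.0, 502.0]), np.array([0.1, 0.2, 0.4]))
        q = [absorbance_at(s, w) for w in np.linspace(500, 502, 17)]
        assert np.all(np.diff(q) > 0)


class TestFindLambdaMax:
    def test_noiseless_parabola_recovers_analytic_centre(self, grid):
        centre = 523.37
        ab = 1.0 - 1e-4 * (grid - centre) ** 2
        s = Spectrum(grid, np.clip(ab, 0, None))
        peak = find_lambda_max(s, (500.0, 550.0))
        assert peak.refined
        assert peak.wavelength == pytest.approx(centre, abs=1e-9)

    @pytest.mark.parametrize("centre,tol", [(523.0, 0.05), (524.3, 0.1)])
    def test_gaussian_band_centre(self, gaussian_spectrum, centre, tol):
        s = gaussian_spectrum(centre=centre)
        peak = find_lambda_max(s, (500.0, 550.0))
        assert peak.wavelength == pytest.approx(centre, abs=tol)

    def test_monotone_ramp_flags_unrefined_edge(self, grid):
        s = Spectrum(grid, (grid - 300.0) / 400.0)
        peak = find_lambda_max(s, (500.0, 550.0))
        assert not peak.refined
        assert peak.wavelength == 550.0

    def test_window_validation(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.2))
        with pytest.raises(ValueError):
            find_lambda_max(s, (200.0, 550.0))
        with pytest.raises(ValueError, match="3 grid points"):
            find_lambda_max(s, (500.0, 501.0))


class TestBandRatio:
    def test_flat_spectrum_gives_unity(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.3))
        assert band_ratio(s) == pytest.approx(1.0)

    def test_denominator_floor(self, grid):
        ab = np.full(grid.size, 0.3)
        ab[grid >= 500] = 1e-6
        s = Spectrum(grid, ab)
        with pytest.raises(ValueError, match="baseline"):
            band_ratio(s)
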