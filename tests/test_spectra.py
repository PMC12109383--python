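"""Spectral container, CSV round-trips, peak detection and shift arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchlab.exceptions import (
    DataError,
    DegeneratePeakWarning,
    DomainError,
    FormatError,
    PeakTieWarning,
)
from quenchlab.spectra import (
    PeakCall,
    Spectrum,
    find_peak,
    peak_shift,
    percent_change,
    read_spectra_long,
    read_spectrum_csv,
    resample,
    shift_label,
    write_spectra_long,
    write_spectrum_csv,
)


def gaussian_spectrum(center, grid=None, amp=1000.0, width=20.0, meta=None):
    wl = np.arange(300.0, 500.5, 1.0) if grid is None else grid
    return Spectrum(wl, amp * np.exp(-0.5 * ((wl - center) / width) ** 2), meta or {})


class TestSpectrumInvariants:
    def test_rejects_short_and_nonmonotone(self):
        with pytest.raises(DataError):
            Spectrum([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataError):
            Spectrum([1.0, 3.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            Spectrum([1.0, 2.0, 3.0], [1.0, np.nan, 3.0])

    def test_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        s = Spectrum(
            np.sort(rng.uniform(300, 500, 57)) + np.arange(57) * 1e-6,
            rng.uniform(0.1, 5000, 57),
            {"sample": "wp", "temperature_K": "298"},
        )
        path = tmp_path / "s.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        assert np.array_equal(back.wavelengths, s.wavelengths)
        assert np.array_equal(back.intensities, s.intensities)
        assert back.meta == s.meta

    def test_long_format_round_trip(self, tmp_path):
        spectra = {
            "a": gaussian_spectrum(345, meta={"ligand_conc_M": "0.0"}),
            "b": gaussian_spectrum(347, meta={"ligand_conc_M": "1e-05"}),
        }
        path = tmp_path / "long.csv"
        write_spectra_long(spectra, path)
        back = read_spectra_long(path)
        assert set(back) == {"a", "b"}
        for key in spectra:
            assert np.array_equal(back[key].intensities, spectra[key].intensities)
            assert back[key].meta == spectra[key].meta

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wl,counts\n300,1\n301,2\n302,3\n")
        with pytest.raises(FormatError, match="wavelength_nm"):
            read_spectrum_csv(path)
        # a dialect remapping the headers makes the same file readable
        s = read_spectrum_csv(path, dialect={"wavelength": "wl", "intensity": "counts"})
        assert len(s) == 3

    def test_duplicate_wavelength_names_the_offender(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("wavelength_nm,intensity\n300,1\n301,2\n301,3\n302,4\n")
        with pytest.raises(DataError, match="301"):
            read_spectrum_csv(path)


class TestFindPeak:
    def test_symmetric_gaussian_refined(self):
        call = find_peak(gaussian_spectrum(345.0), refine=True)
        assert call.lambda_max == pytest.approx(345.0, abs=0.01)

    def test_offgrid_center_refined_matches_dense_oracle(self):
        # oracle: argmax on a 0.001-nm grid of the same analytic band
        center = 345.4
        dense = np.arange(340.0, 350.0, 0.001)
        oracle = dense[np.argmax(np.exp(-0.5 * ((dense - center) / 20.0) ** 2))]
        call = find_peak(gaussian_spectrum(center), refine=True)
        assert call.lambda_max == pytest.approx(oracle, abs=0.1)
        assert call.method == "parabolic"

    def test_tie_returns_smaller_wavelength_with_warning(self):
        wl = np.arange(330.0, 361.0, 1.0)
        it = np.ones_like(wl)
        it[wl == 340] = 5.0
        it[wl == 350] = 5.0
        with pytest.warns(PeakTieWarning):
            call = find_peak(Spectrum(wl, it))
        assert call.lambda_max == 340.0

    def test_flat_spectrum_degenerate(self):
        with pytest.warns(DegeneratePeakWarning):
            call = find_peak(Spectrum([300.0, 301.0, 302.0], [2.0, 2.0, 2.0]))
        assert call.lambda_max == 300.0

    def test_refine_off_equals_argmax_on_random_spectra(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(3, 80)
            wl = np.sort(rng.uniform(200, 500, n))
            wl += np.arange(n) * 1e-9  # enforce strict monotonicity
            it = rng.uniform(0.0, 100.0, n)
            s = Spectrum(wl, it)
            call = find_peak(s, refine=False)
            assert call.lambda_max == wl[np.argmax(it)]
            assert call.intensity == it.max()


class TestShiftAndPercent:
    @pytest.mark.parametrize(
        "ref, sample, shift, label",
        [(274.0, 270.0, -4.0, "blue"), (345.0, 347.0, 2.0, "red"), (345.0, 345.0, 0.0, "none")],
    )
    def test_peak_shift_sign_convention(self, ref, sample, shift, label):
        s = peak_shift(PeakCall(ref, 1.0), PeakCall(sample, 1.0))
        assert s == shift
        assert shift_label(s) == label

    @pytest.mark.parametrize(
        "ref, sample, expected",
        [(3311.0, 1592.0, 51.92), (746.0, 400.0, 46.38), (100.0, 100.0, 0.0)],
    )
    def test_percent_change_worked_examples(self, ref, sample, expected):
        assert round(percent_change(ref, sample), 2) == expected

    def test_percent_change_domain_error(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 10.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=1e-6, max_value=1e9),
        b=st.floats(min_value=0.0, max_value=1e9),
    )
    def test_percent_change_identity(self, a, b):
        assert percent_change(a, b) == pytest.approx(100.0 - 100.0 * b / a, rel=1e-9)


def test_resample_interpolates_and_checks_range():
    s = gaussian_spectrum(345.0)
    r = resample(s, np.arange(320.0, 380.0, 0.5))
    assert r.intensities[0] == pytest.approx(
        np.interp(320.0, s.wavelengths, s.intensities)
    )
    with pytest.raises(DomainError):
        resample(s, np.arange(100.0, 200.0, 1.0))
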