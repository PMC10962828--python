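"""Spectrum ingestion, unit handling, resampling and band statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floravis.spectra import (
    FloralPart,
    ReflectanceSpectrum,
    WavelengthGrid,
    assign_spectral_bins,
    mean_reflectance_in_band,
    normalize_units,
    parse_spectrum_table,
    resample_to_grid,
    spectra_to_long_frame,
)
from floravis.synth import NoiseModel, add_measurement_noise, make_archetype


class TestParseSpectrumTable:
    def test_percent_table_becomes_fraction_spectrum(self):
        spectra = parse_spectrum_table("wavelength_nm,R\n300,50\n301,52\n302,54\n")
        assert len(spectra) == 1
        assert np.allclose(spectra[0].reflectance, [0.50, 0.52, 0.54])

    def test_part_codes_inferred_from_headers(self):
        text = "nm,P,L\n300,40,5\n301,41,6\n302,42,7\n"
        spectra = parse_spectrum_table(text)
        assert [s.part for s in spectra] == [FloralPart.PETAL, FloralPart.LEAF_UPPER]

    def test_descending_rows_sorted_to_same_spectrum(self):
        asc = parse_spectrum_table("nm,R\n300,50\n301,52\n302,54\n")[0]
        desc = parse_spectrum_table("nm,R\n302,54\n301,52\n300,50\n")[0]
        assert np.array_equal(asc.grid.values, desc.grid.values)
        assert np.array_equal(asc.reflectance, desc.reflectance)

    @pytest.mark.parametrize(
        "text,match",
        [
            ("nm,R\n300,50\n300,52\n301,54\n", "duplicate"),
            ("nm,R\n300,50\n301,oops\n302,54\n", "non-numeric"),
            ("", "empty"),
        ],
    )
    def test_malformed_tables_rejected(self, text, match):
        with pytest.raises(ValueError, match=match):
            parse_spectrum_table(text)

    def test_wavelength_column_detected_among_noisy_columns(self):
        # the reflectance column here is non-monotone, so wavelength wins
        text = "R,wavelength\n50,300\n48,301\n52,302\n"
        (s,) = parse_spectrum_table(text)
        assert np.array_equal(s.grid.values, [300, 301, 302])


class TestNormalizeUnits:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((50, 52, 54), (0.50, 0.52, 0.54)),
            ((0.50, 0.52), (0.50, 0.52)),
            ((-0.01, 101), (0.0, 1.0)),
        ],
    )
    def test_unit_rules(self, raw, expected):
        assert np.allclose(normalize_units(raw), expected)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=120.0, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, values):
        once = normalize_units(values)
        assert np.allclose(normalize_units(once), once)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_units([0.1, np.nan])


class TestResample:
    def test_identity_on_own_grid(self, grid, white_petal):
        out = resample_to_grid(white_petal, grid)
        assert np.array_equal(out.reflectance, white_petal.reflectance)

    def test_linear_midpoint(self):
        g = WavelengthGrid(np.array([400.0, 402.0]))
        s = ReflectanceSpectrum(grid=g, reflectance=np.array([0.0, 1.0]))
        out = resample_to_grid(s, WavelengthGrid(np.array([400.0, 401.0, 402.0])))
        assert out.reflectance[1] == pytest.approx(0.5)

    def test_extrapolation_rejected_naming_wavelengths(self, grid, white_petal):
        wide = WavelengthGrid.regular(250.0, 700.0, 1.0)
        with pytest.raises(ValueError, match="250"):
            resample_to_grid(white_petal, wide)

    def test_coarse_spectrum_band_average_survives_resampling(self):
        # 5-nm sampled noisy petal: band averages on the 1-nm resampled curve
        # must match averages taken directly on the coarse piecewise-linear
        # curve, since linear interpolation adds no new information.
        coarse_grid = WavelengthGrid.regular(300.0, 700.0, 5.0)
        petal = add_measurement_noise(
            make_archetype("white_petal", coarse_grid), NoiseModel(sd=0.01, seed=7)
        )
        fine = resample_to_grid(petal, WavelengthGrid.regular(300.0, 700.0, 1.0))
        for lo, hi in [(300, 380), (381, 520), (430, 585)]:
            assert mean_reflectance_in_band(fine, lo, hi) == pytest.approx(
                mean_reflectance_in_band(petal, lo, hi), abs=1e-6
            )


class TestBandMean:
    def test_constant_spectrum(self, grid):
        s = ReflectanceSpectrum(grid=grid, reflectance=np.full(len(grid), 0.4))
        assert mean_reflectance_in_band(s, 330, 600) == pytest.approx(0.4)

    def test_symmetric_step(self, grid):
        wl = grid.values
        r = np.where(wl < 500, 0.0, np.where(wl > 500, 1.0, 0.5))
        s = ReflectanceSpectrum(grid=grid, reflectance=r)
        assert mean_reflectance_in_band(s, 400, 600) == pytest.approx(0.5)

    def test_against_fine_riemann_oracle(self, leaf):
        lo, hi = 521.0, 625.0
        x = np.arange(lo, hi + 1e-9, 0.1)
        y = np.interp(x, leaf.grid.values, leaf.reflectance)
        oracle = np.sum(0.5 * (y[1:] + y[:-1]) * np.diff(x)) / (hi - lo)
        assert mean_reflectance_in_band(leaf, lo, hi) == pytest.approx(oracle, abs=1e-4)

    def test_band_outside_span_rejected(self, white_petal):
        with pytest.raises(ValueError):
            mean_reflectance_in_band(white_petal, 200, 400)

    @given(lo=st.floats(min_value=310, max_value=450), width=st.floats(min_value=10, max_value=80))
    @settings(max_examples=50, deadline=None)
    def test_union_of_adjacent_bands_is_length_weighted_mean(self, lo, width, leaf):
        mid = lo + width
        hi = min(mid + 2 * width, 700.0)
        whole = mean_reflectance_in_band(leaf, lo, hi)
        left = mean_reflectance_in_band(leaf, lo, mid)
        right = mean_reflectance_in_band(leaf, mid, hi)
        weighted = (left * (mid - lo) + right * (hi - mid)) / (hi - lo)
        assert whole == pytest.approx(weighted, abs=1e-9)


class TestSpectralBins:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (350, 400, {"near_UV", "blue"}),
            (374, 1020, {"near_UV", "blue", "green", "red_IR"}),
            (300, 800, {"near_UV", "blue", "green", "red_IR"}),
            (380, 381, {"near_UV", "blue"}),
            (626, 2500, {"red_IR"}),
        ],
    )
    def test_examples(self, lo, hi, expected):
        assert set(assign_spectral_bins(lo, hi)) == expected

    @given(
        st.floats(min_value=300, max_value=1500),
        st.floats(min_value=0, max_value=1000),
        st.floats(min_value=0, max_value=500),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonempty_and_monotone_under_widening(self, lo, width, grow):
        narrow = set(assign_spectral_bins(lo, lo + width))
        wide = set(assign_spectral_bins(max(200.0, lo - grow), lo + width + grow))
        assert narrow  # any query intersecting [300, inf) hits a bin
        assert narrow <= wide


def test_long_frame_round_trips_values(leaf):
    frame = spectra_to_long_frame([leaf])
    assert list(frame.columns) == [
        "specimen_id", "part", "wavelength_nm", "reflectance_fraction",
    ]
    assert np.array_equal(frame["reflectance_fraction"].to_numpy(), leaf.reflectance)
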