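"""Grid/spectrum containers, CSV round trips, windowing, resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ftirdose.errors import (
    DataError,
    ExtrapolationError,
    FormatError,
    GridError,
    WindowError,
)
from ftirdose.spectra import (
    Spectrum,
    SpectrumCollection,
    WavenumberGrid,
    default_grid,
    extract_window,
    read_spectra,
    resample,
    write_spectra,
)


class TestWavenumberGrid:
    def test_default_grid_has_2001_points_at_unit_spacing(self):
        g = default_grid()
        assert len(g) == 2001
        assert g.spacing == 1.0
        assert g.values[0] == 1000.0 and g.values[-1] == 3000.0

    @pytest.mark.parametrize("values", [
        [1000.0, 1002.0, 1003.0],      # non-uniform
        [1000.0, 1000.0, 1001.0],      # non-monotone
        [1002.0, 1001.0, 1000.0],      # decreasing
        [300.0, 301.0, 302.0],         # below instrument range
        [3999.0, 4000.0, 4001.0],      # above instrument range
    ])
    def test_invalid_axes_rejected(self, values):
        with pytest.raises(GridError):
            WavenumberGrid(np.array(values))

    def test_equality_is_value_based(self):
        a = default_grid(1000, 1010)
        b = default_grid(1000, 1010)
        assert a == b and a is not b
        assert a != default_grid(1000, 1011)


class TestSpectrum:
    def test_length_mismatch_rejected(self, small_grid):
        with pytest.raises(DataError):
            Spectrum(small_grid, np.zeros(3))

    def test_metadata_validated(self, small_grid):
        with pytest.raises(DataError):
            Spectrum(small_grid, np.zeros(5), dose=-1.0)
        with pytest.raises(DataError):
            Spectrum(small_grid, np.zeros(5), replicate_id=0)

    def test_collection_requires_shared_grid_and_unique_replicates(self, small_grid):
        s1 = Spectrum(small_grid, np.zeros(5), dose=0.0, replicate_id=1)
        s2 = Spectrum(default_grid(1000, 1008, spacing=2.0), np.zeros(5), dose=1.0,
                      replicate_id=1)
        with pytest.raises(GridError):
            SpectrumCollection([s1, s2])
        with pytest.raises(DataError):
            SpectrumCollection([s1, Spectrum(small_grid, np.ones(5), dose=0.0, replicate_id=1)])


class TestIO:
    @pytest.mark.parametrize("dialect", ["wide", "long"])
    def test_round_trip_is_lossless(self, tmp_path, dialect, tiny_collection):
        path = tmp_path / f"spectra_{dialect}.csv"
        write_spectra(tiny_collection, path, dialect=dialect)
        back = read_spectra(path, dialect=dialect)
        assert len(back) == len(tiny_collection)
        orig = {(s.dose, s.replicate_id): s for s in tiny_collection}
        for s in back:
            ref = orig[(s.dose, s.replicate_id)]  # doses/replicates exact
            np.testing.assert_allclose(s.absorbance, ref.absorbance, rtol=0, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=10, allow_nan=False,
                              width=32), min_size=5, max_size=5),
           st.sampled_from(["wide", "long"]))
    def test_round_trip_property_random_values(self, tmp_path_factory, values, dialect):
        grid = WavenumberGrid(1500.0 + np.arange(5.0))
        coll = SpectrumCollection([Spectrum(grid, np.array(values), dose=0.5)])
        path = tmp_path_factory.mktemp("io") / "s.csv"
        write_spectra(coll, path, dialect=dialect)
        back = read_spectra(path, dialect=dialect)
        np.testing.assert_allclose(back[0].absorbance, values, rtol=0, atol=1e-12)

    def test_wide_file_shape(self, tmp_path, small_grid):
        grid3 = WavenumberGrid(small_grid.values[:3])
        coll = SpectrumCollection([Spectrum(grid3, np.array([1.0, 2.0, 3.0]), dose=1.0)])
        path = tmp_path / "one.csv"
        write_spectra(coll, path, dialect="wide")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows
        assert lines[0] == "wavenumber,1:1"

    def test_wide_reader_builds_collection(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("wavenumber,0:1,2:1\n1000,0.1,0.2\n1001,0.3,0.4\n"
                        "1002,0.5,0.6\n1003,0.7,0.8\n1004,0.9,1.0\n")
        coll = read_spectra(path, dialect="wide")
        assert len(coll) == 2 and len(coll.grid) == 5
        assert coll[1].dose == 2.0

    def test_non_uniform_wavenumber_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavenumber,0:1\n1000,0.1\n1002,0.2\n1003,0.3\n")
        with pytest.raises(GridError):
            read_spectra(path, dialect="wide")

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad_long.csv"
        path.write_text("wavenumber,absorbance\n1000,0.1\n")
        with pytest.raises(FormatError):
            read_spectra(path, dialect="long")

    def test_bad_wide_header_rejected(self, tmp_path):
        path = tmp_path / "bad_header.csv"
        path.write_text("wavenumber,spectrumA\n1000,0.1\n1001,0.2\n")
        with pytest.raises(FormatError):
            read_spectra(path, dialect="wide")

    def test_empty_collection_refused(self, tmp_path):
        with pytest.raises(DataError):
            write_spectra(SpectrumCollection([]), tmp_path / "x.csv")


class TestWindowing:
    def test_full_window_is_identity(self, noise_free_design):
        s = noise_free_design[0]
        w = extract_window(s, 1000, 3000)
        np.testing.assert_array_equal(w.absorbance, s.absorbance)
        assert w.grid == s.grid

    def test_closed_interval_point_count(self, noise_free_design):
        # 2500..3000 inclusive on a 1 cm^-1 grid
        w = extract_window(noise_free_design[0], 2500, 3000)
        assert len(w.grid) == 501

    def test_idempotent(self, noise_free_design):
        s = noise_free_design[0]
        once = extract_window(s, 1500, 2000)
        twice = extract_window(once, 1500, 2000)
        np.testing.assert_array_equal(once.absorbance, twice.absorbance)

    def test_empty_overlap_rejected(self, noise_free_design):
        with pytest.raises(WindowError):
            extract_window(noise_free_design[0], 100, 200)

    def test_metadata_preserved(self, noise_free_design):
        s = noise_free_design[-1]
        w = extract_window(s, 1200, 1300)
        assert w.dose == s.dose and w.replicate_id == s.replicate_id


class TestResample:
    def test_identity_on_own_grid(self, noise_free_design):
        s = noise_free_design[0]
        r = resample(s, s.grid)
        np.testing.assert_array_equal(r.absorbance, s.absorbance)

    def test_midpoint_interpolation(self):
        grid = WavenumberGrid(np.array([1000.0, 1002.0]))
        s = Spectrum(grid, np.array([0.0, 2.0]))
        r = resample(s, WavenumberGrid(np.array([1000.0, 1001.0, 1002.0])))
        assert r.absorbance[1] == pytest.approx(1.0)

    def test_extrapolation_rejected(self, small_grid):
        s = Spectrum(small_grid, np.arange(5.0))
        with pytest.raises(ExtrapolationError):
            resample(s, default_grid(999, 1004))

    @given(st.integers(min_value=0, max_value=1000))
    def test_exact_on_piecewise_linear_input(self, seed):
        # a piecewise-linear trace is recovered exactly on any interior grid
        rng = np.random.default_rng(seed)
        knots = np.array([1000.0, 1010.0, 1020.0, 1030.0])
        kv = rng.uniform(0, 5, size=4)
        src = WavenumberGrid(1000.0 + np.arange(31.0))
        values = np.interp(src.values, knots, kv)
        s = Spectrum(src, values)
        tgt = WavenumberGrid(1000.0 + 0.5 * np.arange(61.0))
        r = resample(s, tgt)
        np.testing.assert_allclose(r.absorbance, np.interp(tgt.values, knots, kv),
                                   rtol=0, atol=1e-12)
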