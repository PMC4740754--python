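import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfirscreen.core import FrequencyAxis, HyperCube, Spectrum, SpotLayout, build_axis
from dfirscreen.qc import LABEL_BACKGROUND, LABEL_GOOD, PixelMask, QCParams
from dfirscreen.spots import (
    assign_spots,
    extract_spot_spectra,
    mean_spot_spectrum,
    min_max_scale,
    truncate_spectrum,
)


def _mask(labels):
    return PixelMask(labels=labels.astype(np.int16),
                     provenance=np.zeros_like(labels, dtype=np.int16),
                     params=QCParams())


def _layout_2x2(n):
    half = n // 2
    return SpotLayout(2, 2, np.array([0, half, n]), np.array([0, half, n]),
                      ("a", "b", "c", "d"), ("x", "x", "y", "y"))


@pytest.fixture
def small_cube(df14_axis, rng):
    return HyperCube(rng.random((8, 8, 14)), df14_axis)


class TestAssignSpots:
    def test_centered_spots_disjoint(self, small_cube):
        labels = np.full((8, 8), LABEL_BACKGROUND)
        centers = [(1, 1), (1, 5), (5, 1), (5, 5)]
        for r, c in centers:
            labels[r:r + 2, c:c + 2] = LABEL_GOOD
        spots, empty = assign_spots(small_cube, _mask(labels), _layout_2x2(8))
        assert empty == []
        seen = set()
        for spot in spots:
            assert spot.n_pixels == 4
            pix = set(zip(spot.rows.tolist(), spot.cols.tolist()))
            assert not (pix & seen)
            seen |= pix
        assert len(seen) == 16

    def test_union_covers_all_good_pixels(self, small_cube, rng):
        labels = rng.integers(0, 4, size=(8, 8))
        spots, _ = assign_spots(small_cube, _mask(labels), _layout_2x2(8))
        union = set()
        for spot in spots:
            union |= set(zip(spot.rows.tolist(), spot.cols.tolist()))
        good = set(zip(*np.nonzero(labels == LABEL_GOOD)))
        assert union == good

    def test_boundary_straddling_flagged(self, small_cube):
        labels = np.full((8, 8), LABEL_BACKGROUND)
        labels[2:6, 2:6] = LABEL_GOOD  # crosses the 2x2 cell boundary at 4
        spots, _ = assign_spots(small_cube, _mask(labels), _layout_2x2(8))
        assert all(s.boundary_flag for s in spots if s.n_pixels)

    def test_shape_mismatch_rejected(self, small_cube):
        labels = np.zeros((6, 6))
        with pytest.raises(ValueError):
            assign_spots(small_cube, _mask(labels), _layout_2x2(8))


class TestMeanSpotSpectrum:
    def test_identical_pixels(self, df14_axis):
        data = np.tile(np.linspace(0, 1, 14), (6, 6, 1))
        cube = HyperCube(data, df14_axis)
        labels = np.full((6, 6), LABEL_GOOD)
        spots, _ = assign_spots(cube, _mask(labels),
                                SpotLayout(1, 1, np.array([0, 6]), np.array([0, 6]),
                                           ("s",), ("x",)))
        ss = mean_spot_spectrum(spots[0], cube, min_pixels=1)
        np.testing.assert_allclose(ss.spectrum.absorbance, np.linspace(0, 1, 14))
        assert ss.qc_pass_fraction == 1.0

    def test_two_pixel_mean(self):
        axis = build_axis([1500.0, 1600.0])
        data = np.array([[[1.0, 3.0], [3.0, 1.0]]])
        cube = HyperCube(data, axis)
        labels = np.full((1, 2), LABEL_GOOD)
        spots, _ = assign_spots(cube, _mask(labels),
                                SpotLayout(1, 1, np.array([0, 1]), np.array([0, 2]),
                                           ("s",), ("x",)))
        ss = mean_spot_spectrum(spots[0], cube, min_pixels=1)
        np.testing.assert_allclose(ss.spectrum.absorbance, [2.0, 2.0])

    def test_too_few_pixels_excluded(self, small_cube):
        labels = np.full((8, 8), LABEL_BACKGROUND)
        labels[0, 0] = LABEL_GOOD
        spots, _ = assign_spots(small_cube, _mask(labels),
                                SpotLayout(1, 1, np.array([0, 8]), np.array([0, 8]),
                                           ("s",), ("x",)))
        with pytest.raises(ValueError, match="excluded"):
            mean_spot_spectrum(spots[0], small_cube, min_pixels=25)

    def test_mean_noise_suppression(self, df14_axis, rng):
        # Monte-Carlo oracle: residual SD of a 400-pixel mean ~ sigma/20
        sigma, n = 0.05, 400
        truth = np.linspace(0.2, 1.0, 14)
        data = truth[None, None, :] + rng.normal(0, sigma, size=(20, 20, 14))
        cube = HyperCube(data, df14_axis)
        labels = np.full((20, 20), LABEL_GOOD)
        spots, _ = assign_spots(cube, _mask(labels),
                                SpotLayout(1, 1, np.array([0, 20]), np.array([0, 20]),
                                           ("s",), ("x",)))
        ss = mean_spot_spectrum(spots[0], cube)
        resid_sd = np.std(ss.spectrum.absorbance - truth)
        assert resid_sd == pytest.approx(sigma / np.sqrt(n), rel=0.5)

    def test_mean_permutation_invariant(self, small_cube, rng):
        labels = np.full((8, 8), LABEL_GOOD)
        spots, _ = assign_spots(small_cube, _mask(labels),
                                SpotLayout(1, 1, np.array([0, 8]), np.array([0, 8]),
                                           ("s",), ("x",)))
        spot = spots[0]
        perm = rng.permutation(spot.n_pixels)
        from dataclasses import replace
        shuffled = replace(spot, rows=spot.rows[perm], cols=spot.cols[perm])
        a = mean_spot_spectrum(spot, small_cube, min_pixels=1).spectrum.absorbance
        b = mean_spot_spectrum(shuffled, small_cube, min_pixels=1).spectrum.absorbance
        np.testing.assert_allclose(a, b, atol=1e-15)


class TestScaling:
    def test_example(self):
        s = Spectrum(build_axis([1.0, 2.0, 3.0]), [0.2, 0.5, 0.8])
        np.testing.assert_allclose(min_max_scale(s).absorbance, [0, 0.5, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=30, unique=True))
    def test_contract_and_idempotence(self, values):
        axis = build_axis(np.arange(1, len(values) + 1, dtype=float))
        scaled = min_max_scale(Spectrum(axis, np.asarray(values)))
        assert scaled.absorbance.min() == 0.0
        assert scaled.absorbance.max() == 1.0
        again = min_max_scale(scaled)
        np.testing.assert_allclose(again.absorbance, scaled.absorbance, atol=1e-15)

    def test_flat_spectrum_rejected(self, df14_axis):
        with pytest.raises(ValueError):
            min_max_scale(Spectrum(df14_axis, np.full(14, 0.3)))


class TestTruncation:
    def test_df14_amide_region_count(self, df14_axis):
        s = Spectrum(df14_axis, np.arange(14.0))
        out = truncate_spectrum(s, 1482, 1770)
        assert len(out.axis) == 11  # drops the 1000/1030/1080 baseline points
        np.testing.assert_allclose(out.absorbance, np.arange(3.0, 14.0))

    def test_full_range_identity(self, df14_axis):
        s = Spectrum(df14_axis, np.arange(14.0))
        out = truncate_spectrum(s, 1000, 1770)
        assert out.axis == df14_axis
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_composition(self, full_axis, rng):
        s = Spectrum(full_axis, rng.random(199))
        twice = truncate_spectrum(truncate_spectrum(s, 1200, 1700), 1400, 1600)
        once = truncate_spectrum(s, 1400, 1600)
        assert twice.axis == once.axis
        np.testing.assert_array_equal(twice.absorbance, once.absorbance)

    def test_empty_intersection_rejected(self, df14_axis):
        with pytest.raises(ValueError):
            truncate_spectrum(Spectrum(df14_axis, np.ones(14)), 1801, 1900)


def test_extraction_scale_then_truncate_order(df14_axis, rng):
    # scaling before truncation: the retained values keep their full-range
    # scaled levels, so min/max inside the window are generally not 0/1
    data = np.abs(rng.random((8, 8, 14))) + 0.1
    cube = HyperCube(data, df14_axis)
    labels = np.full((8, 8), LABEL_GOOD)
    layout = SpotLayout(1, 1, np.array([0, 8]), np.array([0, 8]), ("s",), ("x",))
    kept, _ = extract_spot_spectra(cube, _mask(labels), layout, min_pixels=1,
                                   scale=True, truncate=(1482, 1770))
    spec = kept[0].spectrum
    assert len(spec.axis) == 11
    raw_mean = data.reshape(-1, 14).mean(axis=0)
    scaled = (raw_mean - raw_mean.min()) / (raw_mean.max() - raw_mean.min())
    np.testing.assert_allclose(spec.absorbance, scaled[3:], atol=1e-12)
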