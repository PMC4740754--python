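from dataclasses import replace

import numpy as np
import pytest

from dfirscreen.core import FrequencyAxis, HyperCube, PRESET_SIM, build_axis
from dfirscreen.qc import (
    LABEL_BACKGROUND,
    LABEL_GOOD,
    LABEL_SATURATED,
    QCParams,
    baseline_fit,
    flag_background,
    flag_saturated,
    flag_scatter,
    kmeans_segment,
    qc_pipeline,
)
from dfirscreen.synth import SpotConfig, component_spectrum, simulate_spot, thickness_map


def _random_cube(rng, rows=6, cols=6, n_freq=8):
    axis = FrequencyAxis(np.sort(rng.uniform(1000, 1800, n_freq)))
    return HyperCube(rng.random((rows, cols, n_freq)), axis)


class TestBackground:
    def test_exterior_of_clean_spot_flagged(self, quiet_spot_config, df14_axis):
        cube = simulate_spot(quiet_spot_config, df14_axis)
        t = thickness_map(quiet_spot_config, PRESET_SIM)
        flagged = flag_background(cube, QCParams())
        # zero-thickness pixels have exactly zero signal
        assert np.all(flagged[t == 0])
        assert not flagged[t > 0.5].any()

    def test_uniform_cube_unflagged(self, df14_axis):
        cube = HyperCube(np.ones((5, 5, 14)), df14_axis)
        assert not flag_background(cube, QCParams()).any()

    def test_threshold_sweep_monotone(self, rng):
        cube = _random_cube(rng)
        counts = []
        for frac in np.linspace(0.01, 0.99, 25):
            counts.append(flag_background(cube, QCParams(background_fraction=frac)).sum())
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_all_zero_cube_warns(self, df14_axis):
        cube = HyperCube(np.zeros((3, 3, 14)), df14_axis)
        with pytest.warns(UserWarning):
            flagged = flag_background(cube, QCParams())
        assert flagged.all()


class TestSaturated:
    def test_clipped_ring_flagged(self, quiet_spot_config, df14_axis):
        cfg = replace(quiet_spot_config, center_thickness=2.0, ring_thickness=3.2,
                      saturation_limit=2.0)
        cube = simulate_spot(cfg, df14_axis)
        t = thickness_map(cfg, PRESET_SIM)
        eps_max = component_spectrum(list(cfg.bands), df14_axis).absorbance.max()
        clipped = t * eps_max > cfg.saturation_limit
        flagged = flag_saturated(cube, QCParams(saturation_limit_au=2.0))
        np.testing.assert_array_equal(flagged, clipped)

    def test_low_cube_unflagged(self, rng):
        cube = _random_cube(rng)
        cube.data /= cube.data.max()  # max exactly 1.0, no plateau
        assert not flag_saturated(cube, QCParams(saturation_limit_au=1.8)).any()

    def test_limit_sweep_monotone(self, rng):
        cube = _random_cube(rng)
        cube.data *= 2.5
        counts = [flag_saturated(cube, QCParams(saturation_limit_au=lim)).sum()
                  for lim in np.linspace(2.4, 0.1, 20)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_plateau_rule_catches_clip_below_limit(self, df14_axis):
        data = np.full((2, 2, 14), 0.5)
        data[0, 0, 4:9] = 1.2  # clipped plateau at the cube's global max
        cube = HyperCube(data, df14_axis)
        flagged = flag_saturated(cube, QCParams(saturation_limit_au=5.0))
        assert flagged[0, 0] and flagged.sum() == 1


class TestScatter:
    def test_injected_slope_flagged(self, quiet_spot_config, full_axis):
        params = QCParams()
        cube = simulate_spot(quiet_spot_config, full_axis)
        dnu = full_axis.values - full_axis.values[0]
        cube.data[3, 3] += 2 * params.max_abs_slope * dnu
        flagged = flag_scatter(cube, params)
        assert flagged[3, 3]

    def test_clean_pixels_unflagged(self, quiet_spot_config, full_axis):
        cube = simulate_spot(quiet_spot_config, full_axis)
        assert not flag_scatter(cube, QCParams()).any()

    def test_baseline_fit_matches_normal_equations(self, rng):
        # closed-form oracle on a 5-point window
        axis = FrequencyAxis(np.array([1000.0, 1010, 1030, 1050, 1080]))
        cube = HyperCube(rng.random((3, 2, 5)), axis)
        offset, slope = baseline_fit(cube, (1000, 1080))
        x = axis.values - 1000
        sx, sxx, n = x.sum(), (x * x).sum(), x.size
        for i in range(3):
            for j in range(2):
                y = cube.data[i, j]
                det = n * sxx - sx**2
                b = (n * (x * y).sum() - sx * y.sum()) / det
                a = (y.sum() - b * sx) / n
                assert offset[i, j] == pytest.approx(a, abs=1e-10)
                assert slope[i, j] == pytest.approx(b, abs=1e-12)

    def test_window_needs_two_points(self, df9_axis):
        cube = HyperCube(np.ones((2, 2, 9)), df9_axis)
        with pytest.raises(ValueError, match="< 2 points"):
            flag_scatter(cube, QCParams())  # DF_9 has no points <= 1080


class TestKMeans:
    def test_two_populations_separated(self, df14_axis):
        data = np.zeros((4, 4, 14))
        data[:2] = [0.1] * 7 + [0.9] * 7
        data[2:] = [0.9] * 7 + [0.1] * 7
        cube = HyperCube(data, df14_axis)
        labels, means = kmeans_segment(cube, QCParams(kmeans_k=2))
        assert len(np.unique(labels[:2])) == 1
        assert len(np.unique(labels[2:])) == 1
        assert labels[0, 0] != labels[2, 0]
        assert len(means) == 2

    def test_deterministic_given_seed(self, rng):
        cube = _random_cube(rng, 8, 8, 10)
        l1, _ = kmeans_segment(cube, QCParams(kmeans_k=3, kmeans_seed=5))
        l2, _ = kmeans_segment(cube, QCParams(kmeans_k=3, kmeans_seed=5))
        np.testing.assert_array_equal(l1, l2)

    def test_beats_random_assignments(self, rng):
        # within-cluster sum of squares (on scaled spectra) <= 1000 random labelings
        cube = _random_cube(rng, 5, 6, 7)
        params = QCParams(kmeans_k=2)
        labels, _ = kmeans_segment(cube, params)
        X = cube.pixel_spectra()
        lo = X.min(1, keepdims=True)
        Xs = (X - lo) / (X.max(1, keepdims=True) - lo)

        def wcss(lab):
            total = 0.0
            for c in np.unique(lab):
                grp = Xs[lab == c]
                total += ((grp - grp.mean(0)) ** 2).sum()
            return total

        ours = wcss(labels.ravel())
        rand = min(wcss(rng.integers(0, 2, size=30)) for _ in range(1000))
        assert ours <= rand + 1e-9

    def test_k_exceeding_pixels_rejected(self, df14_axis, rng):
        cube = HyperCube(rng.random((1, 3, 14)), df14_axis)
        with pytest.raises(ValueError):
            kmeans_segment(cube, QCParams(kmeans_k=4))


class TestPipeline:
    def test_clean_spot_partition(self, quiet_spot_config, df14_axis):
        cube = simulate_spot(quiet_spot_config, df14_axis)
        t = thickness_map(quiet_spot_config, PRESET_SIM)
        eps_max = component_spectrum(list(quiet_spot_config.bands),
                                     df14_axis).absorbance.max()
        mask = qc_pipeline(cube, QCParams(cluster_rule=False))
        assert np.all(mask.labels[t == 0] == LABEL_BACKGROUND)
        # in-spot pixels below the saturation limit are all good; the
        # thickest ring pixels legitimately trip the saturation flag
        interior = (t > 0.5) & (t * eps_max < 1.8)
        assert np.all(mask.labels[interior] == LABEL_GOOD)
        assert np.all(mask.labels[t * eps_max >= 1.8] == LABEL_SATURATED)

    def test_saturated_ring_labelled(self, quiet_spot_config, df14_axis):
        cfg = replace(quiet_spot_config, center_thickness=1.0, ring_thickness=2.0,
                      saturation_limit=2.0)
        cube = simulate_spot(cfg, df14_axis)
        t = thickness_map(cfg, PRESET_SIM)
        eps_max = component_spectrum(list(cfg.bands), df14_axis).absorbance.max()
        mask = qc_pipeline(cube, QCParams(cluster_rule=False, saturation_limit_au=2.0))
        clipped = t * eps_max > 2.0
        assert clipped.any()
        assert np.all(mask.labels[clipped] == LABEL_SATURATED)
        interior = (t > 0.5) & (t * eps_max < 1.9)
        assert np.all(mask.labels[interior] == LABEL_GOOD)

    def test_counts_partition_fifty_random_cubes(self, rng):
        # exhaustive count oracle: label counts always partition the pixels
        for _ in range(50):
            cube = _random_cube(rng, rows=int(rng.integers(3, 7)),
                                cols=int(rng.integers(3, 7)),
                                n_freq=int(rng.integers(4, 9)))
            mask = qc_pipeline(cube, QCParams(kmeans_k=2))
            assert sum(mask.counts.values()) == mask.n_pixels

    def test_determinism(self, df14_axis):
        cube = simulate_spot(SpotConfig(), df14_axis, seed=9)
        m1 = qc_pipeline(cube, QCParams())
        m2 = qc_pipeline(cube, QCParams())
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_array_equal(m1.provenance, m2.provenance)

    def test_good_fraction_decreases_with_noise(self, df14_axis):
        fracs = []
        for sd in (0.01, 0.2, 0.6):
            cfg = SpotConfig(noise_sd=sd)
            cube = simulate_spot(cfg, df14_axis, seed=2)
            mask = qc_pipeline(cube, QCParams(cluster_rule=False))
            t = thickness_map(cfg, PRESET_SIM)
            fracs.append(mask.good[t > 0.5].mean())
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[0] > fracs[2]

    def test_df9_skips_scatter_with_warning(self, df9_axis):
        cube = simulate_spot(SpotConfig(), df9_axis, seed=1)
        with pytest.warns(UserWarning, match="scatter rule skipped"):
            mask = qc_pipeline(cube, QCParams())
        assert mask.scatter_skipped
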