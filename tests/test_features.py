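"""Radiomics feature battery: physical, histogram, GLSZM, gradient, assembly."""

import numpy as np
import pytest

from dectgrade import (
    DerivedChannels,
    EmptyRoiError,
    FeatureConfig,
    MomentUndefinedError,
    PhantomConfig,
    RoiMask,
    decompose_three_material,
    extract_all_channels,
    glszm_build,
    glszm_features,
    gradient_magnitude,
    histogram_features,
    physical_features,
    quantize,
    simulate_nodule_phantom,
    uniformity_entropy,
)


def _cube_mask(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0)):
    return RoiMask(mask=np.ones(shape, dtype=bool), spacing=spacing)


class TestPhysicalFeatures:
    def test_water_cube_identity(self):
        mask = _cube_mask()
        out = physical_features(np.zeros((10, 10, 10)), mask)
        assert out["volume_cm3"] == pytest.approx(1.0)
        assert out["density"] == pytest.approx(1.0)
        assert out["mass_g"] == pytest.approx(1.0)

    def test_density_formula(self):
        out = physical_features(np.full((10, 10, 10), -500.0), _cube_mask())
        assert out["density"] == pytest.approx(0.5)

    def test_sphere_diameter_recovered(self):
        # radius 5 mm at 1 mm spacing: axial diameter 10 +/- 1 mm
        ax = np.arange(21) - 10.0
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        sphere = xx**2 + yy**2 + zz**2 <= 5.0**2
        mask = RoiMask(mask=sphere, spacing=(1.0, 1.0, 1.0))
        out = physical_features(np.zeros(sphere.shape), mask)
        assert out["size_lung_mm"] == pytest.approx(10.0, abs=1.0)

    @pytest.mark.parametrize(
        "solid_frac, expected",
        [(0.0, "non-solid"), (0.5, "part-solid"), (1.0, "solid")],
    )
    def test_solidity_classes(self, solid_frac, expected):
        channel = np.full((10, 10, 10), -600.0)
        n_solid = int(round(solid_frac * 1000))
        channel.ravel()[:n_solid] = 100.0
        out = physical_features(channel, _cube_mask())
        assert out["solidity_class"] == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRoiError):
            RoiMask(mask=np.zeros((4, 4, 4), dtype=bool))


class TestHistogramFeatures:
    def test_symmetric_sample_has_zero_skewness(self):
        out = histogram_features(np.array([-1.0, 0.0, 1.0]))
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self):
        # Pearson (non-excess) convention: standard normal -> 3
        x = np.random.default_rng(1).standard_normal(10**6)
        out = histogram_features(x)
        assert out["kurtosis"] == pytest.approx(3.0, abs=0.05)

    def test_percentiles_linear_interpolation(self):
        out = histogram_features(np.arange(101.0))
        assert out["p75"] == pytest.approx(75.0)
        assert out["p975"] == pytest.approx(97.5)

    def test_constant_sample_moments_undefined(self):
        with pytest.raises(MomentUndefinedError):
            histogram_features(np.full(10, 7.0))
        out = histogram_features(np.full(10, 7.0), on_constant="nan")
        assert np.isnan(out["skewness"]) and out["p75"] == pytest.approx(7.0)


class TestUniformityEntropy:
    def test_constant_roi_degenerate_histogram(self):
        out = uniformity_entropy(np.full(50, 12.0))
        assert out["uniformity"] == pytest.approx(1.0)
        assert out["entropy_bits"] == pytest.approx(0.0)

    @pytest.mark.parametrize("k, entropy", [(4, 2.0), (256, 8.0)])
    def test_equally_occupied_bins(self, k, entropy):
        # k bin centers one bin_width apart; the top value sits mid-bin so
        # the histogram spans exactly k unit-width bins.
        values = np.repeat(np.arange(k, dtype=float), 10)
        values[values == k - 1] = k - 0.5
        out = uniformity_entropy(values, bin_width=1.0)
        assert out["uniformity"] == pytest.approx(1.0 / k)
        assert out["entropy_bits"] == pytest.approx(entropy)

    def test_uniformity_entropy_duality(self, rng):
        values = rng.normal(0, 50, size=500)
        out = uniformity_entropy(values)
        assert 0 < out["uniformity"] <= 1.0
        assert out["entropy_bits"] >= 0.0
        # uniformity 1 iff entropy 0
        assert (out["uniformity"] == 1.0) == (out["entropy_bits"] == 0.0)


class TestQuantize:
    def test_integer_span_maps_to_level_plus_one(self):
        values = np.arange(64.0).reshape(4, 4, 4)
        mask = _cube_mask((4, 4, 4))
        q = quantize(values, mask, n_levels=64)
        np.testing.assert_array_equal(q, values.astype(int) + 1)

    def test_constant_roi_single_level(self):
        q = quantize(np.full((4, 4, 4), 5.0), _cube_mask((4, 4, 4)))
        assert np.all(q == 1)

    def test_matches_bruteforce_binning(self, rng):
        values = rng.normal(0, 100, size=(6, 6, 6))
        mask = _cube_mask((6, 6, 6))
        n_levels = 16
        q = quantize(values, mask, n_levels=n_levels)
        vmin, vmax = values.min(), values.max()
        width = (vmax - vmin) / n_levels
        expected = np.minimum(
            np.floor((values - vmin) / width).astype(int) + 1, n_levels
        )
        np.testing.assert_array_equal(q, expected)


def _brute_force_glszm(quantized, mask):
    """Exhaustive flood-fill zone labeling with full connectivity."""
    ndim = quantized.ndim
    offsets = [
        o for o in np.ndindex(*(3,) * ndim)
        if any(d != 1 for d in o)
    ]
    offsets = [tuple(d - 1 for d in o) for o in offsets]
    seen = np.zeros(quantized.shape, dtype=bool)
    zones = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        level = quantized[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            pos = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if any(c < 0 or c >= s for c, s in zip(nb, quantized.shape)):
                    continue
                if seen[nb] or not mask[nb] or quantized[nb] != level:
                    continue
                seen[nb] = True
                stack.append(nb)
        zones.append((int(level), size))
    return sorted(zones)


class TestGlszm:
    def test_documented_3x3_example(self):
        grid = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]])
        mask = RoiMask(mask=np.ones((3, 3), dtype=bool), spacing=(1.0, 1.0))
        m = glszm_build(grid, mask)
        # one zone of size 3 per gray level
        assert m.counts[0, 2] == m.counts[1, 2] == m.counts[2, 2] == 1
        assert int(m.counts.sum()) == 3
        feats = glszm_features(m)
        assert feats["intensity_variability"] == pytest.approx(1.0)
        assert feats["size_zone_variability"] == pytest.approx(3.0)

    def test_constant_roi_single_zone(self):
        mask = RoiMask(mask=np.ones((5, 5), dtype=bool), spacing=(1.0, 1.0))
        m = glszm_build(np.ones((5, 5), dtype=int), mask)
        assert m.counts[0, 24] == 1 and int(m.counts.sum()) == 1
        feats = glszm_features(m)
        assert feats["intensity_variability"] == pytest.approx(1.0)
        assert feats["size_zone_variability"] == pytest.approx(1.0)

    def test_checkerboard_is_two_zones_under_full_connectivity(self):
        grid = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        mask = RoiMask(mask=np.ones((6, 6), dtype=bool), spacing=(1.0, 1.0))
        m = glszm_build(grid, mask)
        assert int(m.counts.sum()) == 2
        assert m.counts[0, 17] == 1 and m.counts[1, 17] == 1

    def test_distinct_zone_sizes_single_level(self):
        # K zones of one gray level with distinct sizes: GLN=K, SZN=1
        grid = np.zeros((1, 9), dtype=int)
        grid[0, :2] = 1  # size 2
        grid[0, 3:7] = 1  # size 4
        grid[0, 8] = 1  # size 1
        mask = RoiMask(mask=grid > 0, spacing=(1.0, 1.0))
        feats = glszm_features(glszm_build(grid, mask))
        assert feats["intensity_variability"] == pytest.approx(3.0)
        assert feats["size_zone_variability"] == pytest.approx(1.0)

    def test_matches_exhaustive_labeling_on_random_volumes(self, rng):
        for _ in range(60):
            q = rng.integers(1, 3, size=(3, 3, 3))
            mask_arr = rng.random((3, 3, 3)) < 0.8
            if not mask_arr.any():
                continue
            mask = RoiMask(mask=mask_arr, spacing=(1.0, 1.0, 1.0))
            m = glszm_build(np.where(mask_arr, q, 0), mask)
            expected = _brute_force_glszm(np.where(mask_arr, q, 0), mask_arr)
            got = sorted(
                (i + 1, j + 1)
                for (i, j), c in np.ndenumerate(m.counts)
                for _ in range(c)
            )
            assert got == expected
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert int((m.counts * sizes).sum()) == mask.n_voxels


class TestGradientMagnitude:
    def test_constant_volume_zero_gradient(self):
        g = gradient_magnitude(np.full((5, 5, 5), 40.0))
        np.testing.assert_allclose(g, 0.0)

    def test_linear_ramp_recovers_slope(self):
        x = np.arange(10.0)
        vol = np.broadcast_to(3.5 * x[:, None, None], (10, 4, 4)).copy()
        g = gradient_magnitude(vol, spacing=(1.0, 1.0, 1.0))
        np.testing.assert_allclose(g[1:-1], 3.5)

    def test_matches_loop_based_finite_differences(self, rng):
        vol = rng.normal(size=(5, 6, 7))
        spacing = (0.5, 1.0, 2.0)
        g = gradient_magnitude(vol, spacing)
        i, j, k = 2, 3, 3
        gx = (vol[i + 1, j, k] - vol[i - 1, j, k]) / (2 * spacing[0])
        gy = (vol[i, j + 1, k] - vol[i, j - 1, k]) / (2 * spacing[1])
        gz = (vol[i, j, k + 1] - vol[i, j, k - 1]) / (2 * spacing[2])
        assert g[i, j, k] == pytest.approx(np.sqrt(gx**2 + gy**2 + gz**2))


@pytest.fixture(scope="module")
def phantom_channels():
    cfg = PhantomConfig(grid_shape=(24, 24, 24), nodule_radius=8, seed=3)
    volume, mask, _, _ = simulate_nodule_phantom(cfg)
    return decompose_three_material(volume), mask


class TestExtractAllChannels:
    def test_zero_iodine_noiseless_phantom_i_features(self):
        cfg = PhantomConfig(
            grid_shape=(20, 20, 20), nodule_radius=6, noise_sd=0.0,
            iodine_map_spec={"kind": "none", "amplitude": 0.0},
        )
        volume, mask, _, _ = simulate_nodule_phantom(cfg)
        fv = extract_all_channels(decompose_three_material(volume), mask)
        assert fv.features["i-Uniformity"] == pytest.approx(1.0)
        assert fv.features["i-Entropy"] == pytest.approx(0.0)
        assert "i-Skewness" in fv.missing  # constant channel

    def test_feature_name_battery_is_complete(self, phantom_channels):
        channels, mask = phantom_channels
        fv = extract_all_channels(channels, mask)
        required = {
            "Uniformity", "i-Uniformity", "g-Uniformity",
            "Entropy", "i-Entropy", "g-Entropy",
            "75th percentile (HU)", "i-75th percentile (HU)", "g-75th percentile (HU)",
            "97.5th percentile (HU)", "i-97.5th percentile (HU)", "g-97.5th percentile (HU)",
            "Skewness", "Kurtosis", "Density", "Mass (g)", "Volume (cm3)",
            "Intensity-variability", "g-Size-zone-variability", "Solidity",
        }
        assert required <= set(fv.features)

    def test_extraction_is_deterministic(self, phantom_channels):
        channels, mask = phantom_channels
        f1 = extract_all_channels(channels, mask).features
        f2 = extract_all_channels(channels, mask).features
        assert f1 == f2

    def test_diff_mode_reports_featurewise_difference(self, phantom_channels):
        channels, mask = phantom_channels
        spatial = extract_all_channels(channels, mask).features
        diff = extract_all_channels(
            channels, mask, FeatureConfig(g_mode="diff")
        ).features
        assert diff["g-Entropy"] == pytest.approx(
            diff["i-Entropy"] - diff["Entropy"]
        )
        assert diff["g-Entropy"] != pytest.approx(spatial["g-Entropy"])

    def test_hu_offset_equivariance(self, phantom_channels):
        channels, mask = phantom_channels
        base = extract_all_channels(channels, mask).features
        shifted_channels = DerivedChannels(
            weighted_average=channels.weighted_average + 50.0,
            vnc=channels.vnc + 50.0,
            iodine=channels.iodine,
            spacing=channels.spacing,
        )
        shifted = extract_all_channels(shifted_channels, mask).features
        for name in ("Skewness", "Kurtosis", "Uniformity", "Entropy",
                     "Intensity-variability", "Size-zone-variability"):
            assert shifted[name] == pytest.approx(base[name], rel=1e-9)
        assert shifted["75th percentile (HU)"] == pytest.approx(
            base["75th percentile (HU)"] + 50.0
        )
        assert shifted["Density"] == pytest.approx(base["Density"] + 0.05)
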