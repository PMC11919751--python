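import numpy as np
import pytest

from limbictex.glszm import (
    FEATURE_NAMES,
    GLSZMFeatureExtractor,
    Zone,
    build_glszm,
    compute_features,
    discretize,
    glszm_features,
    label_zones,
    zones_from_grid,
)

from oracles import brute_features


class TestDiscretize:
    def test_two_point_endpoints(self, make_sample):
        s = make_sample(np.array([[[0.0, 10.0]]]))
        d = discretize(s, n_bins=2)
        assert d.levels.tolist() == [1, 2]
        assert d.n_levels == 2

    def test_constant_roi_single_level(self, make_sample):
        s = make_sample(np.full((2, 2, 2), 3.7))
        d = discretize(s, n_bins=16)
        assert d.n_levels == 1
        assert set(d.levels) == {1}

    def test_affine_invariance(self, make_sample, rng):
        x = rng.normal(size=(4, 4, 4))
        base = discretize(make_sample(x), n_bins=8).levels
        for a, b in [(2.5, -3.0), (0.01, 100.0), (1e4, 0.0)]:
            trans = discretize(make_sample(a * x + b), n_bins=8).levels
            np.testing.assert_array_equal(trans, base)

    def test_too_few_bins_rejected(self, make_sample):
        with pytest.raises(ValueError, match="n_bins"):
            discretize(make_sample(np.zeros((2, 2, 2))), n_bins=1)

    def test_levels_within_range(self, make_sample, rng):
        for n_bins in (2, 5, 16, 64):
            d = discretize(make_sample(rng.normal(size=(5, 5, 5))), n_bins=n_bins)
            assert d.levels.min() >= 1 and d.levels.max() <= n_bins


class TestLabelZones:
    def test_uniform_block_single_zone(self, make_sample):
        s = make_sample(np.full((2, 2, 1), 5.0))
        zones = label_zones(discretize(s, n_bins=4))
        assert zones == [Zone(level=1, size=4)]

    def test_three_zone_grid(self):
        # hand grid: levels [[1,1,2],[1,2,2],[3,3,3]] -> three zones of size 3
        grid = np.array([[[1], [1], [2]], [[1], [2], [2]], [[3], [3], [3]]])
        zones = zones_from_grid(grid, connectivity=26)
        assert sorted((z.level, z.size) for z in zones) == [(1, 3), (2, 3), (3, 3)]

    def test_corner_touch_connectivity(self):
        grid = np.zeros((2, 2, 2), dtype=int)
        grid[0, 0, 0] = 1
        grid[1, 1, 1] = 1  # touches only at the corner
        assert len(zones_from_grid(grid, connectivity=26)) == 1
        assert len(zones_from_grid(grid, connectivity=6)) == 2

    def test_edge_touch_connectivity(self):
        grid = np.zeros((2, 2, 1), dtype=int)
        grid[0, 0, 0] = 1
        grid[1, 1, 0] = 1  # shares an edge
        assert len(zones_from_grid(grid, connectivity=18)) == 1
        assert len(zones_from_grid(grid, connectivity=6)) == 2

    def test_every_voxel_in_exactly_one_zone(self, make_sample, rng):
        s = make_sample(rng.normal(size=(5, 5, 5)))
        zones = label_zones(discretize(s, n_bins=4))
        assert sum(z.size for z in zones) == 125

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            zones_from_grid(np.ones((2, 2, 2), dtype=int), connectivity=4)


class TestBuildGLSZM:
    def test_single_zone(self):
        m = build_glszm([Zone(3, 4)])
        assert m.P.shape == (1, 1) and m.P[0, 0] == 1
        assert m.n_zones == 1 and m.mu == 3.0 and m.n_voxels == 4

    def test_three_zone_example(self):
        m = build_glszm([Zone(1, 3), Zone(2, 3), Zone(3, 3)])
        assert m.n_zones == 3
        np.testing.assert_allclose(m.p, [[1 / 3], [1 / 3], [1 / 3]])
        assert m.mu == pytest.approx(2.0)

    def test_duplicated_zones_double_P_not_p(self):
        zones = [Zone(1, 2), Zone(2, 5)]
        m1 = build_glszm(zones)
        m2 = build_glszm(zones * 2)
        np.testing.assert_array_equal(m2.P, 2 * m1.P)
        np.testing.assert_allclose(m2.p, m1.p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_glszm([])

    def test_matrix_invariants(self, make_sample, rng):
        s = make_sample(rng.normal(size=(6, 6, 6)))
        zones = label_zones(discretize(s, n_bins=4))
        m = build_glszm(zones)
        assert m.P.sum() == m.n_zones == len(zones)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.n_voxels == 216
        assert (m.P >= 0).all()


class TestComputeFeatures:
    def test_single_zone_closed_forms(self):
        f = compute_features(build_glszm([Zone(2, 4)]))
        assert f["large_area_emphasis"] == 16.0
        assert f["small_area_emphasis"] == 1 / 16
        assert f["high_gray_level_zone_emphasis"] == 4.0
        assert f["gray_level_variance"] == 0.0
        assert f["large_area_low_gray_level_emphasis"] == 4.0

    def test_three_zone_hand_values(self):
        f = compute_features(build_glszm([Zone(1, 3), Zone(2, 3), Zone(3, 3)]))
        assert f["large_area_emphasis"] == pytest.approx(9.0)
        assert f["small_area_emphasis"] == pytest.approx(1 / 9)
        assert f["high_gray_level_zone_emphasis"] == pytest.approx(14 / 3)
        assert f["gray_level_variance"] == pytest.approx(2 / 3)
        assert f["large_area_low_gray_level_emphasis"] == pytest.approx(49 / 12)
        assert f["zone_entropy"] == pytest.approx(np.log2(3))

    def test_constant_image_closed_form(self, make_sample):
        s = make_sample(np.full((4, 3, 2), 1.5))
        f = glszm_features(s, n_bins=16)
        n = 24
        assert f["large_area_emphasis"] == n**2
        assert f["small_area_emphasis"] == 1 / n**2
        assert f["gray_level_variance"] == 0.0
        assert f["high_gray_level_zone_emphasis"] == 1.0

    def test_exactly_16_finite_features(self, make_sample, rng):
        f = glszm_features(make_sample(rng.normal(size=(4, 4, 4))))
        assert tuple(f) == FEATURE_NAMES
        assert len(f) == 16
        assert all(np.isfinite(v) for v in f.values())

    def test_matches_brute_formula_oracle(self, make_sample, rng):
        from collections import Counter

        s = make_sample(rng.normal(size=(5, 5, 5)))
        zones = label_zones(discretize(s, n_bins=4))
        f = compute_features(build_glszm(zones))
        oracle = brute_features(Counter((z.level, z.size) for z in zones))
        for name in FEATURE_NAMES:
            assert f[name] == pytest.approx(oracle[name], rel=1e-12), name


class TestExtractorTransformer:
    def test_transform_returns_16_column_frame(self, make_sample, rng):
        samples = [make_sample(rng.normal(size=(4, 4, 4))) for _ in range(3)]
        ext = GLSZMFeatureExtractor().fit(samples)
        out = ext.transform(samples)
        assert out.shape == (3, 16)
        assert list(out.columns) == list(FEATURE_NAMES)
        assert list(ext.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_sklearn_params_roundtrip(self):
        ext = GLSZMFeatureExtractor(n_bins=8, connectivity=6)
        assert ext.get_params() == {"n_bins": 8, "connectivity": 6}
        ext.set_params(n_bins=32)
        assert ext.n_bins == 32

    def test_invalid_params_rejected_at_fit(self):
        with pytest.raises(ValueError):
            GLSZMFeatureExtractor(n_bins=1).fit([])
        with pytest.raises(ValueError):
            GLSZMFeatureExtractor(connectivity=5).fit([])


def test_reference_radiomics_parity(make_sample, rng):
    """Cross-check against PyRadiomics on shared settings when available."""
    radiomics = pytest.importorskip("radiomics")
    import SimpleITK as sitk
    from radiomics.glszm import RadiomicsGLSZM

    data = rng.normal(size=(6, 6, 6))
    img = sitk.GetImageFromArray(data)
    mask = sitk.GetImageFromArray(np.ones((6, 6, 6), dtype=np.uint8))
    glszm = RadiomicsGLSZM(img, mask, binCount=4)
    glszm.enableAllFeatures()
    ref = glszm.execute()
    ours = glszm_features(make_sample(data), n_bins=4)
    mapping = {
        "SmallAreaEmphasis": "small_area_emphasis",
        "LargeAreaEmphasis": "large_area_emphasis",
        "GrayLevelNonUniformity": "gray_level_nonuniformity",
        "SizeZoneNonUniformity": "size_zone_nonuniformity",
        "ZonePercentage": "zone_percentage",
        "HighGrayLevelZoneEmphasis": "high_gray_level_zone_emphasis",
    }
    for theirs, mine in mapping.items():
        assert ours[mine] == pytest.approx(float(ref[theirs]), rel=1e-6)
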