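"""Topological voxel analysis: partitioning, per-cube features, radial topology."""

import numpy as np
import pytest

from helpers import phantom, population_features, small_spec

from qdmi.errors import ConfigurationError, SegmentationError
from qdmi.image_io import ImageStack
from qdmi.segmentation import NucleusROI
from qdmi import tva

PAPER_VOXEL = (120.0, 120.0, 250.0)


def _stack(dapi, mec, voxel=PAPER_VOXEL):
    data = np.stack([np.asarray(dapi, dtype=np.uint16), np.asarray(mec, dtype=np.uint16)])
    return ImageStack(data=data, voxel_size=voxel, channel_names=("DAPI", "MeC"))


def _roi_from_mask(mask, label=1):
    coords = np.argwhere(mask)
    lo, hi = coords.min(0), coords.max(0) + 1
    return NucleusROI(label, coords, len(coords), tuple(coords.mean(0)),
                      (tuple(int(v) for v in lo), tuple(int(v) for v in hi)), False)


def _ball_roi(shape=(24, 64, 64), center=(12, 32, 32), radius_nm=2800.0, voxel=PAPER_VOXEL):
    pitch = np.array([voxel[2], voxel[1], voxel[0]])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = np.sqrt(sum(((g - c) * p) ** 2 for g, c, p in zip(grids, center, pitch)))
    return d <= radius_nm, d


class TestLowIntensityThreshold:
    def test_bimodal_sample_split_between_modes(self):
        sample = np.array([10] * 50 + [1000] * 50)
        t = tva.low_intensity_threshold(sample)
        assert 10 < t < 1000

    def test_constant_sample_raises(self):
        with pytest.raises(SegmentationError):
            tva.low_intensity_threshold(np.full(100, 7))

    def test_same_stack_gives_identical_thresholds(self, default_phantom):
        stack, _, rois = default_phantom
        t1 = tva.image_thresholds(stack, rois)
        t2 = tva.image_thresholds(stack, rois)
        assert t1 == t2

    def test_raising_sub_threshold_mec_lowers_lim(self, default_phantom):
        stack, _, rois = default_phantom
        thresholds = tva.image_thresholds(stack, rois)
        roi = rois[0]
        _, lim_before = tva.lid_lim_percent(stack, roi, thresholds)
        boosted = stack.data.copy()
        mec_idx = stack.channel_names.index("MeC")
        sel = boosted[mec_idx][roi.pixel_index]
        boosted[mec_idx][roi.pixel_index] = np.where(
            sel < thresholds["MeC"], int(thresholds["MeC"]) + 100, sel
        ).astype(boosted.dtype)
        stack2 = ImageStack(boosted, stack.voxel_size, stack.channel_names, bit_depth=16)
        _, lim_after = tva.lid_lim_percent(stack2, roi, thresholds)
        assert lim_after < lim_before
        assert lim_after == 0.0


class TestLidLim:
    def test_all_pixels_below_both_thresholds(self):
        shape = (2, 4, 4)
        stack = _stack(np.full(shape, 10), np.full(shape, 20))
        roi = _roi_from_mask(np.ones(shape, dtype=bool))
        assert tva.lid_lim_percent(stack, roi, {"DAPI": 100, "MeC": 100}) == (100.0, 100.0)

    def test_no_pixels_below(self):
        shape = (2, 4, 4)
        stack = _stack(np.full(shape, 900), np.full(shape, 900))
        roi = _roi_from_mask(np.ones(shape, dtype=bool))
        assert tva.lid_lim_percent(stack, roi, {"DAPI": 100, "MeC": 100}) == (0.0, 0.0)

    def test_exact_half_below_dapi_threshold(self):
        dapi = np.zeros((2, 4, 4), dtype=int)
        dapi[0] = 10   # half the pixels
        dapi[1] = 900
        stack = _stack(dapi, np.full((2, 4, 4), 900))
        roi = _roi_from_mask(np.ones((2, 4, 4), dtype=bool))
        lid, lim = tva.lid_lim_percent(stack, roi, {"DAPI": 500, "MeC": 100})
        assert lid == 50.0 and lim == 0.0


class TestVoxelize:
    def test_single_cube_roi(self):
        # at 120x120x250 nm pitch a 500 nm cube spans 5 x 5 px laterally, 2 px axially
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[0:2, 0:5, 0:5] = True
        stack = _stack(np.zeros((4, 8, 8)), np.zeros((4, 8, 8)))
        grid = tva.voxelize(_roi_from_mask(mask), stack)
        assert grid.n_cubes == 1
        assert grid.occupancy[0] == 50
        assert grid.r[0] == 0.0

    def test_partition_conserves_ball_volume(self):
        mask, _ = _ball_roi()
        stack = _stack(np.zeros(mask.shape), np.zeros(mask.shape))
        grid = tva.voxelize(_roi_from_mask(mask), stack)
        assert grid.occupancy.sum() == mask.sum()
        assert np.bincount(grid.cube_ids).min() >= 1

    def test_boundary_cube_keeps_partial_occupancy(self):
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[0:2, 0:5, 0:7] = True  # second lateral cube only 2/5 covered
        stack = _stack(np.zeros((4, 8, 8)), np.zeros((4, 8, 8)))
        grid = tva.voxelize(_roi_from_mask(mask), stack)
        assert grid.n_cubes == 2
        assert sorted(grid.occupancy.tolist()) == [20, 50]

    def test_cube_below_pixel_pitch_rejected(self):
        mask = np.ones((2, 5, 5), dtype=bool)
        stack = _stack(np.zeros((2, 5, 5)), np.zeros((2, 5, 5)))
        with pytest.raises(ConfigurationError):
            tva.voxelize(_roi_from_mask(mask), stack, cube_size_nm=200)

    def test_radial_positions_bounded_and_increasing_outward(self):
        mask, d = _ball_roi()
        stack = _stack(np.zeros(mask.shape), np.zeros(mask.shape))
        grid = tva.voxelize(_roi_from_mask(mask), stack)
        assert np.all((grid.r >= 0) & (grid.r <= 1))
        # cube centers farther from the centroid get larger r
        order = np.argsort(grid.r)
        centroid_nm = (np.array(_roi_from_mask(mask).centroid) + 0.5) * np.array([250, 120, 120])
        dist = np.linalg.norm(grid.centers_nm - centroid_nm, axis=1)
        assert np.corrcoef(grid.r, dist)[0, 1] > 0.95


class TestVoxelFeatures:
    def _grid_feats(self, dapi_val, mec_val, thresholds, scales):
        shape = (2, 5, 5)
        stack = _stack(np.full(shape, dapi_val), np.full(shape, mec_val))
        roi = _roi_from_mask(np.ones(shape, dtype=bool))
        grid = tva.voxelize(roi, stack)
        return tva.voxel_features(stack, roi, grid, thresholds, scales)

    def test_pixels_at_scale_give_unit_features(self):
        f = self._grid_feats(2000, 1500, {"DAPI": 500, "MeC": 500}, {"DAPI": 2000, "MeC": 1500})
        assert f["cond"][0] == 1.0 and f["meth"][0] == 1.0 and f["assoc"][0] == 1.0

    def test_all_zero_pixels_are_low_but_perfectly_associated(self):
        f = self._grid_feats(0, 0, {"DAPI": 500, "MeC": 500}, {"DAPI": 2000, "MeC": 1500})
        assert f["cond"][0] == 0.0 and f["meth"][0] == 0.0 and f["assoc"][0] == 1.0

    def test_anticorrelated_channels_have_zero_assoc(self):
        shape = (2, 5, 5)
        idx = np.indices(shape).sum(axis=0) % 2 == 0
        dapi = np.where(idx, 2000, 100)   # high where mec low
        mec = np.where(idx, 100, 1400)
        stack = _stack(dapi, mec)
        roi = _roi_from_mask(np.ones(shape, dtype=bool))
        grid = tva.voxelize(roi, stack)
        f = tva.voxel_features(stack, roi, grid, {"DAPI": 500, "MeC": 500}, {"DAPI": 2000, "MeC": 1400})
        assert f["assoc"][0] == 0.0


class TestAggregate:
    def test_two_voxel_hand_example(self):
        grid = tva.VoxelGrid(500.0, np.zeros(1), np.array([100, 50]), np.zeros(2), np.zeros((2, 3)))
        agg = tva.aggregate(grid, {"cond": np.array([0.9, 0.3])})
        assert agg["cond"] == pytest.approx(0.7)

    def test_equal_occupancy_matches_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.random(8)
        grid = tva.VoxelGrid(500.0, np.zeros(1), np.full(8, 50), np.zeros(8), np.zeros((8, 3)))
        agg = tva.aggregate(grid, {"meth": vals})
        assert agg["meth"] == pytest.approx(vals.mean())

    def test_constant_feature_is_identity(self):
        grid = tva.VoxelGrid(500.0, np.zeros(1), np.array([10, 20, 30]), np.zeros(3), np.zeros((3, 3)))
        assert tva.aggregate(grid, {"assoc": np.full(3, 0.8)})["assoc"] == pytest.approx(0.8)


class TestRadialProfile:
    def test_single_shell_equals_aggregate(self):
        mask, _ = _ball_roi()
        rng = np.random.default_rng(1)
        stack = _stack(rng.integers(100, 3000, mask.shape), rng.integers(100, 3000, mask.shape))
        roi = _roi_from_mask(mask)
        grid = tva.voxelize(roi, stack)
        feats = tva.voxel_features(stack, roi, grid, {"DAPI": 800, "MeC": 800}, {"DAPI": 3000, "MeC": 3000})
        prof = tva.radial_profile(grid, feats, 1)
        agg = tva.aggregate(grid, feats)
        for name in feats:
            assert prof[name][0] == pytest.approx(agg[name])

    def test_rim_bright_dapi_gives_monotone_cond(self):
        mask, d = _ball_roi()
        dapi = np.where(mask, np.where(d > 0.65 * 2800, 3000, 800), 50)
        stack = _stack(dapi, np.where(mask, 1500, 50))
        roi = _roi_from_mask(mask)
        grid = tva.voxelize(roi, stack)
        feats = tva.voxel_features(stack, roi, grid, {"DAPI": 900, "MeC": 900}, {"DAPI": 3000, "MeC": 1500})
        prof = tva.radial_profile(grid, feats, 6)["cond"]
        assert not np.isnan(prof).any()
        assert np.all(np.diff(prof) >= -1e-9)
        assert prof[-1] > prof[0]

    def test_empty_shells_marked_missing(self):
        grid = tva.VoxelGrid(500.0, np.zeros(1), np.array([10, 10]), np.array([0.05, 0.95]), np.zeros((2, 3)))
        prof = tva.radial_profile(grid, {"cond": np.array([0.2, 0.8])}, 4)["cond"]
        assert prof[0] == pytest.approx(0.2) and prof[3] == pytest.approx(0.8)
        assert np.isnan(prof[1]) and np.isnan(prof[2])


class TestProfileDispersion:
    def test_identical_profiles_have_zero_sd(self):
        profiles = np.tile(np.linspace(0.2, 0.8, 5), (4, 1))
        disp = tva.profile_dispersion(profiles)
        np.testing.assert_allclose(disp["sd"], 0.0, atol=1e-12)

    def test_constant_offset_pair_has_closed_form_sd(self):
        base = np.linspace(0.2, 0.8, 5)
        c = 0.1
        disp = tva.profile_dispersion(np.stack([base, base + c]))
        np.testing.assert_allclose(disp["sd"], c / np.sqrt(2.0), atol=1e-12)

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError):
            tva.profile_dispersion(np.linspace(0, 1, 5)[None, :])

    def test_phantom_population_profiles_have_no_interior_gaps(self, default_phantom):
        stack, _, rois = default_phantom
        thresholds = tva.image_thresholds(stack, rois)
        scales = tva.channel_scales(stack, rois)
        profiles = []
        for roi in rois:
            f = tva.compute_tva_features(stack, roi, thresholds, scales, n_shells=5)
            profiles.append(f.radial_profile["cond"])
        disp = tva.profile_dispersion(np.stack(profiles))
        assert np.isfinite(disp["mean"]).all()
        assert np.isfinite(disp["sd"]).all()


class TestScaleRobustness:
    def test_doubling_both_channels_preserves_features(self, default_phantom):
        stack, _, rois = default_phantom
        # halve first so the doubled copy cannot clip 12-bit range
        halved = ImageStack((stack.data // 2).astype(np.uint16), stack.voxel_size,
                            stack.channel_names)
        doubled = ImageStack((halved.data * 2).astype(np.uint16), stack.voxel_size,
                             stack.channel_names)
        f1 = population_features(halved, rois)
        f2 = population_features(doubled, rois)
        for col in ("cond", "meth"):
            rel = np.abs(f1[col] - f2[col]) / f1[col]
            assert rel.max() < 0.01
        np.testing.assert_allclose(f1["assoc"], f2["assoc"], atol=5e-3)


def test_feature_bounds_on_phantom_population(default_features):
    f = default_features
    assert ((f["cond"] >= 0) & (f["cond"] <= 1)).all()
    assert ((f["meth"] >= 0) & (f["meth"] <= 1)).all()
    assert ((f["assoc"] >= 0) & (f["assoc"] <= 1)).all()
    assert ((f["lid_pct"] >= 0) & (f["lid_pct"] <= 100)).all()
    assert ((f["lim_pct"] >= 0) & (f["lim_pct"] <= 100)).all()
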