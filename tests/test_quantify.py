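"""Disc-level metric arithmetic and recovery from the generator."""

import numpy as np
import pytest

from discquant import (
    CompartmentMasks,
    ImageStack,
    LabelMask,
    SpotSet,
    death_density,
    mean_intensity,
    midline_compartments,
    pa_ratio,
    pouch_coverage,
    relative_patch_intensity,
    speckle_density,
)
from discquant.territories import decompose_border_center


def make_stack(img, voxel=(1.0, 1.0, 1.0), role="stain"):
    return ImageStack(np.asarray(img, dtype=float)[None], voxel, {role: 0})


class TestPouchCoverage:
    def test_full_and_empty(self):
        pouch = LabelMask(np.ones((2, 4, 4), dtype=np.int32), (1, 1, 1))
        assert pouch_coverage(pouch, pouch) == 100.0
        empty = LabelMask(np.zeros((2, 4, 4), dtype=np.int32), (1, 1, 1))
        assert pouch_coverage(empty, pouch) == 0.0

    def test_empty_pouch_errors(self):
        empty = LabelMask(np.zeros((2, 4, 4), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            pouch_coverage(empty, empty)

    def test_fraction_by_voxel_count(self, rng):
        pouch_arr = (rng.random((3, 20, 20)) > 0.3).astype(np.int32)
        patch_arr = pouch_arr * (rng.random((3, 20, 20)) > 0.5)
        pouch = LabelMask(pouch_arr, (1, 1, 1))
        patches = LabelMask(patch_arr.astype(np.int32), (1, 1, 1))
        expect = 100 * patch_arr.sum() / pouch_arr.sum()
        assert pouch_coverage(patches, pouch) == pytest.approx(expect)


class TestDeathDensity:
    @pytest.fixture
    def square_tmap(self):
        labels = np.zeros((1, 40, 40), dtype=np.int32)
        labels[0, 5:35, 5:35] = 1
        patches = LabelMask(labels, (1, 1, 1))
        return patches, decompose_border_center(patches, cell_diameter=2.5)

    def test_no_death_all_zero(self, square_tmap):
        patches, tmap = square_tmap
        death = LabelMask(np.zeros((1, 40, 40), dtype=np.int32), (1, 1, 1))
        dens = death_density(death, tmap)
        assert dens["border"] == 0.0 and dens["center"] == 0.0

    def test_death_covering_border_only(self, square_tmap):
        patches, tmap = square_tmap
        death = LabelMask((tmap.territory == 1).astype(np.int32), (1, 1, 1))
        dens = death_density(death, tmap)
        assert dens["border"] == 100.0
        assert dens["center"] == 0.0

    def test_empty_territory_flagged_nan(self):
        labels = np.zeros((1, 20, 20), dtype=np.int32)
        labels[0, 8:12, 8:12] = 1  # thin patch: no center
        patches = LabelMask(labels, (1, 1, 1))
        tmap = decompose_border_center(patches, cell_diameter=5.0)
        death = LabelMask(np.zeros_like(labels), (1, 1, 1))
        assert np.isnan(death_density(death, tmap)["center"])

    def test_exterior_restricted_to_roi(self, square_tmap):
        patches, tmap = square_tmap
        roi_arr = np.zeros((1, 40, 40), dtype=np.int32)
        roi_arr[0, :20, :] = 1
        death_arr = np.zeros_like(roi_arr)
        death_arr[0, :5, :] = 1  # outside patch, inside roi top band
        dens = death_density(LabelMask(death_arr, (1, 1, 1)), tmap,
                             roi=LabelMask(roi_arr, (1, 1, 1)))
        ext = (tmap.territory == 0) & (roi_arr > 0)
        expect = 100 * (death_arr[ext > 0].sum()) / ext.sum()
        assert dens["exterior_wt"] == pytest.approx(expect)


class TestMeanIntensity:
    def test_constant_and_checkerboard(self):
        stack = make_stack(np.full((4, 6, 6), 3.5))
        mask = LabelMask(np.ones((4, 6, 6), dtype=np.int32), (1, 1, 1))
        assert mean_intensity(stack, "stain", mask) == 3.5
        board = np.indices((4, 6, 6)).sum(axis=0) % 2 * 10.0
        assert mean_intensity(make_stack(board), "stain", mask) == pytest.approx(5.0)

    def test_matches_bruteforce_loop(self, rng):
        img = rng.random((3, 8, 8))
        mask_arr = (rng.random((3, 8, 8)) > 0.5).astype(np.int32)
        got = mean_intensity(make_stack(img), "stain", LabelMask(mask_arr, (1, 1, 1)))
        acc = [img[z, y, x] for z in range(3) for y in range(8) for x in range(8)
               if mask_arr[z, y, x]]
        assert got == pytest.approx(np.mean(acc))

    def test_empty_mask_errors(self):
        stack = make_stack(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            mean_intensity(stack, "stain", LabelMask(np.zeros((2, 4, 4), dtype=np.int32), (1, 1, 1)))


class TestPARatio:
    def _comps(self, shape=(3, 10, 10)):
        a = np.zeros(shape, dtype=bool)
        p = np.zeros(shape, dtype=bool)
        a[:, :, :5] = True
        p[:, :, 5:] = True
        return CompartmentMasks(anterior=a, posterior=p)

    def test_identical_compartments_unity(self):
        stack = make_stack(np.full((3, 10, 10), 8.0))
        assert pa_ratio(stack, "stain", self._comps()) == pytest.approx(1.0)

    def test_reciprocity_under_mask_swap(self, rng):
        img = rng.random((3, 10, 10)) + 0.5
        comps = self._comps()
        swapped = CompartmentMasks(anterior=comps.posterior, posterior=comps.anterior)
        stack = make_stack(img)
        assert pa_ratio(stack, "stain", comps) == pytest.approx(
            1.0 / pa_ratio(stack, "stain", swapped)
        )

    def test_scale_invariant_not_offset_invariant(self, rng):
        img = rng.random((3, 10, 10)) + 0.5
        comps = self._comps()
        r0 = pa_ratio(make_stack(img), "stain", comps)
        assert pa_ratio(make_stack(img * 3.7), "stain", comps) == pytest.approx(r0)
        assert pa_ratio(make_stack(img + 5.0), "stain", comps) != pytest.approx(r0)

    def test_degenerate_anterior_errors(self):
        img = np.zeros((3, 10, 10))
        img[:, :, 5:] = 1.0
        with pytest.raises(ValueError, match="anterior"):
            pa_ratio(make_stack(img), "stain", self._comps())

    def test_recovery_from_generator(self):
        from discquant import SimConfig, simulate_disc

        cfg = SimConfig(seed=31, target_coverage=0.0, n_patches=0, noise_sd=2.0,
                        pa_fold_change=1.8, channels=("stain",))
        stack, truth = simulate_disc(cfg)
        comps = midline_compartments(truth.pouch_mask)
        assert pa_ratio(stack, "stain", comps) == pytest.approx(1.8, rel=0.05)


class TestRelativePatchIntensity:
    def test_equal_intensity_unity_and_double(self):
        roi = LabelMask(np.ones((2, 10, 10), dtype=np.int32), (1, 1, 1))
        patch_arr = np.zeros((2, 10, 10), dtype=np.int32)
        patch_arr[:, 2:5, 2:5] = 1
        patches = LabelMask(patch_arr, (1, 1, 1))
        flat = make_stack(np.full((2, 10, 10), 6.0))
        assert relative_patch_intensity(flat, "stain", patches, roi) == pytest.approx(1.0)
        img = np.full((2, 10, 10), 4.0)
        img[patch_arr > 0] = 8.0
        assert relative_patch_intensity(make_stack(img), "stain", patches, roi) == pytest.approx(2.0)

    def test_no_wildtype_voxels_errors(self):
        roi = LabelMask(np.ones((1, 4, 4), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="wild-type"):
            relative_patch_intensity(make_stack(np.ones((1, 4, 4))), "stain", roi, roi)


class TestSpeckleDensity:
    def test_arithmetic(self):
        mask = LabelMask(np.ones((2, 10, 100), dtype=np.int32), (1, 1, 1))  # 2000 µm³
        spots = SpotSet(coords=np.array([[0, 5, k * 9.0] for k in range(10)]),
                        response=np.ones(10))
        assert speckle_density(spots, mask) == pytest.approx(5.0)

    def test_zero_spots(self):
        mask = LabelMask(np.ones((1, 5, 5), dtype=np.int32), (1, 1, 1))
        assert speckle_density(SpotSet(np.empty((0, 3)), np.empty(0)), mask) == 0.0

    def test_spots_outside_mask_not_counted(self):
        arr = np.zeros((1, 10, 10), dtype=np.int32)
        arr[0, :5] = 1
        mask = LabelMask(arr, (1, 1, 1))
        spots = SpotSet(coords=np.array([[0, 2, 2], [0, 8, 8]]), response=np.ones(2))
        assert speckle_density(spots, mask) == pytest.approx(1 / 50 * 1000)

    def test_empty_mask_errors(self):
        mask = LabelMask(np.zeros((1, 5, 5), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError):
            speckle_density(SpotSet(np.empty((0, 3)), np.empty(0)), mask)


class TestSubtractBackground:
    def test_flat_background_removed_feature_kept(self):
        from discquant import subtract_background

        img = np.full((2, 30, 30), 20.0)
        img[:, 14:16, 14:16] += 100.0  # small bright feature
        stack = make_stack(img)
        out = subtract_background(stack, "stain", radius_um=5.0)
        corrected = out.channel("stain")
        assert corrected[0, 0, 0] == pytest.approx(0.0)
        assert corrected[0, 15, 15] == pytest.approx(100.0, abs=1.0)

    def test_offset_invariance_of_ratio_after_subtraction(self):
        from discquant import CompartmentMasks, pa_ratio, subtract_background

        img = np.full((2, 10, 20), 10.0)
        img[:, :, 10:] = 30.0  # posterior 3x anterior above zero background
        a = np.zeros((2, 10, 20), dtype=bool); a[:, :, :10] = True
        p = ~a
        comps = CompartmentMasks(anterior=a, posterior=p)
        raw = pa_ratio(make_stack(img), "stain", comps)
        shifted = pa_ratio(make_stack(img + 50.0), "stain", comps)
        assert raw != pytest.approx(shifted)
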