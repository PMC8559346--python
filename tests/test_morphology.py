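import numpy as np
import pytest

from glomclass import morphology
from glomclass.image_io import NON_SCLEROTIC, SCLEROTIC
from glomclass.morphology import (
    CMYK_MAGENTA_COMPLEMENT,
    RGB_GREEN,
    binarize_channel,
    centered_disk,
    fuse_and_filter,
    lab_cluster_mask,
    magenta_complement,
    morphological_features,
    segment_white_regions,
    white_mask_from_channel,
)


def solid(h, w, rgb):
    img = np.empty((h, w, 3), np.uint8)
    img[:] = rgb
    return img


class TestChannelMasks:
    def test_uniform_white_gives_full_mask(self):
        img = solid(64, 64, (255, 255, 255))
        for ch in (RGB_GREEN, CMYK_MAGENTA_COMPLEMENT):
            assert white_mask_from_channel(img, ch).all()

    def test_uniform_dark_gives_empty_mask(self):
        # dark grey sits far below the threshold on the green plane
        assert not white_mask_from_channel(solid(64, 64, (50, 50, 50)), RGB_GREEN).any()
        # the magenta-complement plane needs a magenta-stained dark colour:
        # neutral greys carry no magenta at all, so their complement is 255
        assert not white_mask_from_channel(
            solid(64, 64, (80, 30, 60)), CMYK_MAGENTA_COMPLEMENT
        ).any()
        assert white_mask_from_channel(
            solid(8, 8, (50, 50, 50)), CMYK_MAGENTA_COMPLEMENT
        ).all()

    def test_white_square_recovered_within_15_percent(self):
        img = solid(100, 100, (60, 40, 50))
        img[30:70, 30:70] = (245, 245, 245)
        for ch in (RGB_GREEN, CMYK_MAGENTA_COMPLEMENT):
            mask = white_mask_from_channel(img, ch)
            assert abs(mask.sum() - 1600) <= 0.15 * 1600
            # mass stays on the square
            assert mask[35:65, 35:65].mean() > 0.9

    def test_magenta_complement_of_white_is_255(self):
        assert magenta_complement(solid(2, 2, (255, 255, 255))).max() == 255
        # PAS-pink tissue is far below the white threshold
        assert magenta_complement(solid(2, 2, (200, 120, 160))).max() < 190

    def test_threshold_monotonicity_before_cleaning(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        lower = binarize_channel(img, RGB_GREEN, threshold=150)
        higher = binarize_channel(img, RGB_GREEN, threshold=200)
        assert not (higher & ~lower).any()  # raising threshold never grows mask


class TestLabClusterMask:
    def test_two_tone_image_yields_white_half(self):
        img = solid(80, 80, (200, 120, 160))
        img[:, 40:] = (250, 250, 250)
        mask = lab_cluster_mask(img, rng_state=0)
        target = np.zeros((80, 80), bool)
        target[:, 40:] = True
        overlap = (mask & target).sum() / target.sum()
        assert overlap >= 0.95
        assert (mask & ~target).sum() / target.sum() < 0.05

    def test_uniform_image_collapses_to_full_mask(self):
        img = solid(32, 32, (100, 100, 100))
        assert lab_cluster_mask(img, rng_state=0).all()

    def test_deterministic_for_fixed_rng_state(self, one_crop_each):
        crop = one_crop_each[0]
        m1 = lab_cluster_mask(crop, rng_state=42)
        m2 = lab_cluster_mask(crop, rng_state=42)
        assert np.array_equal(m1, m2)


class TestFuseAndFilter:
    def test_two_of_three_votes_survive(self):
        shape = (64, 64)
        m1 = np.zeros(shape, bool)
        m2 = np.zeros(shape, bool)
        m3 = np.zeros(shape, bool)
        m1[30:34, 30:34] = True
        m2[30:34, 30:34] = True
        fused = fuse_and_filter(m1, m2, m3, min_region=1)
        assert fused[31, 31]
        only_one = np.zeros(shape, bool)
        only_one[10, 10] = True
        assert not fuse_and_filter(only_one, m3, m3, min_region=1).any()

    def test_all_empty_gives_empty(self):
        e = np.zeros((32, 32), bool)
        assert not fuse_and_filter(e, e, e).any()

    def test_blob_below_min_region_removed(self):
        shape = (120, 120)
        blob = np.zeros(shape, bool)
        blob[45:75, 45:75] = True  # 900 pixels, centred
        assert blob.sum() == 900
        assert not fuse_and_filter(blob, blob, blob, min_region=1000).any()
        # the same blob survives a 900-pixel threshold
        assert fuse_and_filter(blob, blob, blob, min_region=900).sum() == 900

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        masks = [rng.random((48, 48)) < 0.4 for _ in range(3)]
        from itertools import permutations

        results = {
            fuse_and_filter(*[masks[i] for i in p], min_region=5).tobytes()
            for p in permutations(range(3))
        }
        assert len(results) == 1

    def test_subset_of_union_and_disk(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            masks = [rng.random((50, 60)) < 0.5 for _ in range(3)]
            fused = fuse_and_filter(*masks, min_region=2)
            union = masks[0] | masks[1] | masks[2]
            assert not (fused & ~union).any()
            assert not (fused & ~centered_disk(fused.shape)).any()

    def test_mismatched_extents_rejected(self):
        with pytest.raises(ValueError, match="extents"):
            fuse_and_filter(
                np.zeros((4, 4), bool), np.zeros((4, 5), bool), np.zeros((4, 4), bool)
            )


class TestMorphologicalFeatures:
    def test_empty_mask_gives_zeros(self):
        f = morphological_features(np.zeros((50, 50), bool))
        assert (f.white_area_fraction, f.equivalent_radius) == (0.0, 0.0)

    def test_full_mask_fraction_is_one(self):
        f = morphological_features(np.ones((100, 100), bool))
        assert f.white_area_fraction == 1.0

    def test_disk_equivalent_radius_recovers_radius(self):
        yy, xx = np.mgrid[:100, :100]
        mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        f = morphological_features(mask)
        assert abs(f.equivalent_radius - 30) <= 1.0
        assert f.equivalent_radius <= np.sqrt(2) * 100  # bounded by the diagonal


class TestSeparationOnSyntheticData:
    def test_white_area_separates_classes(self, fast_dataset, fast_params):
        """Non-sclerotic crops must show more segmented white area than
        sclerotic ones (the signal the morphological features encode)."""
        fractions = {SCLEROTIC: [], NON_SCLEROTIC: []}
        # small crops: scale the region filter with the image area
        min_region = int(1000 * (fast_params.image_size / 112) ** 2)
        for crop in fast_dataset:
            mask = segment_white_regions(crop, min_region_px=min_region)
            fractions[crop.label].append(
                morphological_features(mask).white_area_fraction
            )
        gap = np.mean(fractions[NON_SCLEROTIC]) - np.mean(fractions[SCLEROTIC])
        assert gap > 0.05
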