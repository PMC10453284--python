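import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscnet.io_datasets import AVLabel, FundusSample
from mscnet.preprocessing import (
    augment,
    random_patches,
    resize_sample,
    stitch,
    tile,
    vessel_input_channels,
)


class TestVesselInputChannels:
    def test_flat_image_near_constant(self):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        out = vessel_input_channels(img)
        assert out.shape == (1, 64, 64)
        assert np.ptp(out) < 0.02

    def test_zero_green_channel(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, :, 0] = 200
        assert (vessel_input_channels(img) == 0).all()

    def test_contrast_non_decreasing(self, synth_sample):
        out = vessel_input_channels(synth_sample.image)
        raw = synth_sample.image[:, :, 1] / 255.0
        assert out.std() >= raw.std()
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            vessel_input_channels(np.zeros((10, 10), dtype=np.uint8))


class TestRandomPatches:
    def test_exact_size_gives_full_image(self, synth_sample):
        (img, m, av), = random_patches(synth_sample, 1, patch=128, rng_seed=0)
        np.testing.assert_array_equal(img, synth_sample.image)
        np.testing.assert_array_equal(m, synth_sample.vessel_mask)

    def test_seed_reproducibility(self, synth_sample):
        a = random_patches(synth_sample, 5, patch=64, rng_seed=9)
        b = random_patches(synth_sample, 5, patch=64, rng_seed=9)
        for (ia, ma, aa), (ib, mb, ab) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(aa, ab)

    def test_windows_in_bounds(self, synth_sample_256):
        crops = random_patches(synth_sample_256, 100, patch=256, rng_seed=3)
        for img, m, av in crops:
            assert img.shape == (256, 256, 3)
            assert m.shape == (256, 256)

    def test_too_small_image_rejected(self, synth_sample):
        with pytest.raises(ValueError, match="resize"):
            random_patches(synth_sample, 1, patch=256, rng_seed=0)

    def test_crops_are_aligned(self, synth_sample):
        for img, m, av in random_patches(synth_sample, 10, 64, rng_seed=5):
            np.testing.assert_array_equal(m.astype(bool),
                                          av != AVLabel.BACKGROUND)


class TestAugment:
    def _crop(self, synth_sample):
        return random_patches(synth_sample, 1, 64, rng_seed=2)[0]

    def test_identity_when_rotation0_noise0(self, synth_sample):
        crop = self._crop(synth_sample)
        # find a seed producing k=0 and sd=0 is awkward; call the primitive
        # with noise_sd_max=0 and scan for a k=0 seed
        for seed in range(50):
            if np.random.default_rng(seed).integers(0, 4) == 0:
                img, m, av = augment(crop, rng_seed=seed, noise_sd_max=0.0)
                np.testing.assert_allclose(img, crop[0] / 255.0, atol=1e-7)
                np.testing.assert_array_equal(m, crop[1])
                return
        pytest.fail("no seed with rotation 0 found")

    def test_rotation_count_invariant(self, synth_sample):
        crop = self._crop(synth_sample)
        for seed in range(8):
            img, m, av = augment(crop, rng_seed=seed)
            assert m.sum() == crop[1].sum()
            assert (av == AVLabel.ARTERY).sum() == (crop[2] == AVLabel.ARTERY).sum()

    def test_labels_never_get_noise(self, synth_sample):
        crop = self._crop(synth_sample)
        img, m, av = augment(crop, rng_seed=7)
        assert set(np.unique(av)) <= {0, 1, 2, 3}
        assert m.dtype == crop[1].dtype

    def test_image_label_alignment_delta_transport(self, synth_sample):
        # a delta in the image must land on the same pixel as a delta mask
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[5, 7] = 255
        m = np.zeros((32, 32), dtype=np.uint8)
        m[5, 7] = 1
        av = m.copy()
        for seed in range(6):
            out_img, out_m, _ = augment((img, m, av), rng_seed=seed,
                                        noise_sd_max=0.0)
            r, c = np.unravel_index(out_img[:, :, 0].argmax(), (32, 32))
            assert out_m[r, c] == 1 and out_m.sum() == 1

    def test_output_clipped(self, synth_sample):
        img, _, _ = augment(self._crop(synth_sample), rng_seed=3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_arbitrary_rotation_keeps_labels_categorical(self, synth_sample):
        crop = self._crop(synth_sample)
        img, m, av = augment(crop, rng_seed=4, rotation_mode="arbitrary")
        assert set(np.unique(av)) <= {0, 1, 2, 3}
        assert set(np.unique(m)) <= {0, 1}
        assert img.shape == crop[0].shape

    def test_unknown_rotation_mode_rejected(self, synth_sample):
        with pytest.raises(ValueError, match="rotation_mode"):
            augment(self._crop(synth_sample), rng_seed=0, rotation_mode="bogus")


class TestTileStitch:
    def test_single_patch_round_trip(self, rng):
        x = rng.normal(size=(256, 256, 3))
        grid, patches = tile(x, 256)
        assert len(patches) == 1
        np.testing.assert_array_equal(stitch(grid, patches), x)

    def test_padding_round_trip(self, rng):
        x = rng.normal(size=(300, 300))
        grid, patches = tile(x, 256)
        assert len(patches) == 4
        assert grid.pad == (212, 212)
        np.testing.assert_array_equal(stitch(grid, patches), x)

    @settings(max_examples=25, deadline=None)
    @given(h=st.integers(1, 300), w=st.integers(1, 300),
           patch=st.sampled_from([16, 64, 256]))
    def test_round_trip_property(self, h, w, patch):
        x = np.random.default_rng(h * 1000 + w).normal(size=(h, w))
        grid, patches = tile(x, patch)
        np.testing.assert_array_equal(stitch(grid, patches), x)

    def test_wrong_patch_count_or_size(self, rng):
        grid, patches = tile(rng.normal(size=(64, 64)), 32)
        with pytest.raises(ValueError):
            stitch(grid, patches[:-1])
        with pytest.raises(ValueError):
            stitch(grid, [p[:16, :16] for p in patches])

    def test_patches_cover_exactly_once(self):
        x = np.ones((70, 50))
        grid, patches = tile(x, 32)
        total = sum(p.sum() for p in patches)
        assert total == x.sum()  # each original pixel appears exactly once

    def test_overlap_round_trip_by_averaging(self, rng):
        x = rng.normal(size=(90, 70, 2))
        grid, patches = tile(x, 32, stride=16)
        assert len(patches) > 12
        np.testing.assert_allclose(stitch(grid, patches), x, atol=1e-12)

    def test_bad_stride_rejected(self, rng):
        with pytest.raises(ValueError, match="stride"):
            tile(rng.normal(size=(64, 64)), 32, stride=40)


class TestResizeSample:
    def test_identity(self, synth_sample):
        out = resize_sample(synth_sample, synth_sample.shape)
        np.testing.assert_array_equal(out.image, synth_sample.image)

    def test_labels_stay_categorical(self, synth_sample):
        out = resize_sample(synth_sample, (100, 90))
        assert set(np.unique(out.av_labels)) <= {0, 1, 2, 3}
        assert set(np.unique(out.vessel_mask)) <= {0, 1}

    def test_down_up_dice(self, synth_sample_256):
        down = resize_sample(synth_sample_256, (128, 128))
        up = resize_sample(down, (256, 256))
        a = synth_sample_256.vessel_mask.astype(bool)
        b = up.vessel_mask.astype(bool)
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.8
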