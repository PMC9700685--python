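"""Phantom generator: disks, nodule types, augmentation, split, resize."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import noduleseg as ns
from noduleseg.phantom import FLIP_SUFFIX, PATCH


def brute_force_disk_count(center, radius):
    """Independent oracle: count lattice points within the closed disk."""
    n = 0
    for r in range(PATCH):
        for c in range(PATCH):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius ** 2:
                n += 1
    return n


class TestSynthPatch:
    def test_disk_of_radius_five_has_81_pixels(self):
        s = ns.synth_patch(ns.NoduleSpec(radius_px=5, center=(32, 32),
                                         noise_sd=0))
        assert int(s.mask.sum()) == 81
        assert int(s.mask.sum()) == brute_force_disk_count((32, 32), 5)

    def test_subpixel_radius_keeps_only_centre(self):
        s = ns.synth_patch(ns.NoduleSpec(radius_px=0.4, center=(32, 32)))
        assert int(s.mask.sum()) == 1
        assert s.mask[32, 32] == 1

    def test_bit_identical_for_same_spec(self):
        spec = ns.NoduleSpec(nodule_type="juxta_vascular", radius_px=7,
                             center=(20.5, 40.2), seed=123)
        a, b = ns.synth_patch(spec), ns.synth_patch(spec)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_degenerate_disk_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ns.synth_patch(ns.NoduleSpec(radius_px=0.3, center=(32.5, 32.5)))

    def test_image_in_unit_range_and_mask_binary(self):
        for ntype in ns.NODULE_TYPES:
            s = ns.synth_patch(ns.NoduleSpec(nodule_type=ntype, seed=5))
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0
            assert set(np.unique(s.mask)) <= {0, 1}

    def test_mask_excludes_wall_and_vessel(self):
        """Attached structures appear in the image but never in the mask."""
        for ntype in ("juxta_pleural", "juxta_vascular"):
            spec = ns.NoduleSpec(nodule_type=ntype, radius_px=6,
                                 center=(32, 32), seed=2)
            s = ns.synth_patch(spec)
            plain = ns.synth_patch(
                ns.NoduleSpec(radius_px=6, center=(32, 32), seed=2))
            np.testing.assert_array_equal(s.mask, plain.mask)
            # the structure must brighten pixels outside the nodule disk
            assert (s.image - plain.image)[s.mask == 0].max() > 0.1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ns.NoduleSpec(radius_px=0)
        with pytest.raises(ValueError):
            ns.NoduleSpec(center=(70, 10))
        with pytest.raises(ValueError):
            ns.NoduleSpec(nodule_type="calcified")

    @settings(deadline=None, max_examples=30)
    @given(st.floats(2.0, 20.0), st.floats(24.0, 40.0), st.floats(24.0, 40.0))
    def test_lattice_disk_pixel_count_bounds(self, radius, r0, c0):
        s = ns.synth_patch(ns.NoduleSpec(radius_px=radius, center=(r0, c0)))
        n = int(s.mask.sum())
        assert math.pi * (radius - 1) ** 2 <= n <= math.pi * (radius + 1) ** 2


class TestSynthDataset:
    def test_exact_count_and_reproducibility(self):
        a = ns.synth_dataset(25, seed=9)
        b = ns.synth_dataset(25, seed=9)
        assert len(a) == 25
        assert [s.id for s in a] == [s.id for s in b]
        np.testing.assert_array_equal(a[7].image, b[7].image)

    def test_degenerate_mix_yields_single_type(self):
        samples = ns.synth_dataset(5, type_mix=(1, 0, 0), seed=1)
        assert {s.spec.nodule_type for s in samples} == {"well_circumscribed"}

    def test_type_counts_within_binomial_bounds(self):
        # 99.99% binomial bounds for p=1/3, n=300 are [60, 140]
        samples = ns.synth_dataset(300, seed=4)
        for ntype in ns.NODULE_TYPES:
            count = sum(s.spec.nodule_type == ntype for s in samples)
            assert 60 <= count <= 140

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            ns.synth_dataset(0)
        with pytest.raises(ValueError):
            ns.synth_dataset(5, type_mix=(0.5, 0.5, 0.5))

    def test_every_sample_has_foreground(self):
        assert all(s.mask.sum() >= 1 for s in ns.synth_dataset(40, seed=2))


class TestFlipAugment:
    def test_doubles_and_mirrors_jointly(self, small_dataset):
        out = ns.flip_augment(small_dataset)
        assert len(out) == 2 * len(small_dataset)
        n = len(small_dataset)
        for orig, mirrored in zip(out[:n], out[n:]):
            assert mirrored.id == orig.id + FLIP_SUFFIX
            np.testing.assert_array_equal(np.fliplr(mirrored.image),
                                          orig.image)
            np.testing.assert_array_equal(np.fliplr(mirrored.mask), orig.mask)

    def test_involution(self, small_dataset):
        twice = ns.flip_augment(ns.flip_augment(small_dataset[:3]))
        # the mirror of a mirrored sample equals the original
        for orig, back in zip(twice[:3], twice[9:12]):
            np.testing.assert_array_equal(orig.image, back.image)
            np.testing.assert_array_equal(orig.mask, back.mask)

    def test_empty_list(self):
        assert ns.flip_augment([]) == []


class TestSplit:
    def test_exact_partition_sizes(self, small_dataset):
        aug = ns.flip_augment(small_dataset)          # 24 samples
        split = ns.split_dataset(aug, 0.8, seed=0)
        assert (len(split.train), len(split.test)) == (19, 5)

    def test_ten_samples_eight_two(self, small_dataset):
        split = ns.split_dataset(small_dataset[:10], 0.8, seed=0)
        assert (len(split.train), len(split.test)) == (8, 2)

    def test_partition_property(self, small_dataset):
        split = ns.split_dataset(small_dataset, 0.75, seed=3)
        train_ids = {s.id for s in split.train}
        test_ids = {s.id for s in split.test}
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == {s.id for s in small_dataset}

    def test_same_seed_reproducible_different_seed_same_sizes(self,
                                                              small_dataset):
        a = ns.split_dataset(small_dataset, 0.8, seed=5)
        b = ns.split_dataset(small_dataset, 0.8, seed=5)
        c = ns.split_dataset(small_dataset, 0.8, seed=6)
        assert [s.id for s in a.train] == [s.id for s in b.train]
        assert len(a.train) == len(c.train)
        assert [s.id for s in a.train] != [s.id for s in c.train]

    def test_bad_arguments_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            ns.split_dataset(small_dataset, 1.2, seed=0)
        with pytest.raises(ValueError):
            ns.split_dataset(small_dataset[:1], 0.5, seed=0)


class TestCropAndResize:
    def test_identity_when_box_matches_output_size(self):
        img = np.random.default_rng(0).random((80, 90))
        box = ns.BoundingBox(5, 7, 69, 71)
        out = ns.crop_and_resize(img, box, (64, 64))
        np.testing.assert_array_equal(out, img[5:69, 7:71])

    def test_planar_ramp_upscales_exactly(self):
        a, b, c = 0.003, 0.005, 0.1
        img = a * np.arange(96)[:, None] + b * np.arange(96)[None, :] + c
        box = ns.BoundingBox(16, 16, 48, 48)
        out = ns.crop_and_resize(img, box, (64, 64))
        r = 16 + (np.arange(64) + 0.5) * 32 / 64 - 0.5
        cc = 16 + (np.arange(64) + 0.5) * 32 / 64 - 0.5
        exact = a * r[:, None] + b * cc[None, :] + c
        assert np.abs(out - exact).max() < 1e-6

    def test_constant_crop_stays_constant(self):
        img = np.full((40, 40), 0.37)
        out = ns.crop_and_resize(img, ns.BoundingBox(3, 3, 20, 31), (64, 64))
        np.testing.assert_allclose(out, 0.37, atol=1e-9)

    def test_output_clipped_to_input_range(self):
        rng = np.random.default_rng(1)
        img = rng.random((50, 50))
        out = ns.crop_and_resize(img, ns.BoundingBox(10, 10, 26, 26))
        assert out.min() >= img.min() and out.max() <= img.max()

    def test_out_of_bounds_box_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            ns.crop_and_resize(img, ns.BoundingBox(0, 0, 33, 16))
        with pytest.raises(ValueError):
            ns.BoundingBox(4, 4, 4, 10)


class TestDatasetIO:
    def test_png_csv_roundtrip(self, tmp_path, small_dataset):
        index = ns.save_dataset(small_dataset[:4], tmp_path / "ds")
        loaded = ns.load_dataset(index)
        assert [s.id for s in loaded] == [s.id for s in small_dataset[:4]]
        for a, b in zip(loaded, small_dataset[:4]):
            np.testing.assert_array_equal(a.mask, b.mask)
            # images are 8-bit quantised on disk
            assert np.abs(a.image - b.image).max() <= 1 / 255 + 1e-6
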