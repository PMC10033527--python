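"""IO round-trips, resizing, augmentation enumeration and the synthetic
generator's analytic ground truth."""

import numpy as np
import pytest

from eards import metrics as M
from eards.data import (
    AugmentationSpec,
    DEFAULT_TRANSLATIONS,
    SyntheticConfig,
    augment,
    generate_synthetic,
    heldout_test_split,
    load_mask,
    load_pair,
    make_synthetic_dataset,
    read_manifest,
    resize_pair,
    save_image,
    save_mask,
    split_dataset,
    write_synthetic_dataset,
)
from eards.exceptions import ConfigurationError, ShapeError


class TestMaskIO:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        mask = rng.integers(0, 3, size=(40, 40)).astype(np.uint8)
        p = tmp_path / "m.png"
        save_mask(p, mask)
        np.testing.assert_array_equal(load_mask(p), mask)

    def test_invalid_code_rejected(self, tmp_path):
        mask = np.full((4, 4), 7, dtype=np.uint8)
        with pytest.raises(ShapeError, match=r"\[7\]"):
            save_mask(tmp_path / "bad.png", mask)

    def test_mask_must_be_png(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_mask(tmp_path / "m.jpg")

    def test_pair_loading_checks_sizes(self, tmp_path, rng):
        save_image(tmp_path / "i.png", rng.random((8, 8, 3)))
        save_mask(tmp_path / "m.png", np.zeros((9, 9), np.uint8))
        with pytest.raises(ShapeError):
            load_pair(tmp_path / "i.png", tmp_path / "m.png")

    def test_jpeg_image_close_to_png(self, tmp_path, synthetic_128):
        img, _, _ = synthetic_128
        save_image(tmp_path / "a.png", img)
        save_image(tmp_path / "a.jpg", img)
        from eards.data import load_image
        png, jpg = load_image(tmp_path / "a.png"), load_image(tmp_path / "a.jpg")
        assert np.abs(png - img).max() < 0.01          # 8-bit quantization
        assert np.abs(jpg - png).mean() < 0.05         # lossy but close


class TestResize:
    def test_mask_codes_preserved(self, synthetic_128):
        _, mask, _ = synthetic_128
        _, m2 = resize_pair(np.zeros((*mask.shape, 3)), mask, 64)
        assert set(np.unique(m2)) <= {0, 1, 2}

    def test_constant_image_stays_constant(self):
        img = np.full((32, 32, 3), 0.5, dtype=np.float32)
        out, _ = resize_pair(img, np.zeros((32, 32), np.uint8), 64)
        np.testing.assert_allclose(out, 0.5, atol=1e-6)

    def test_down_up_round_trip_keeps_large_structures(self):
        cfg = SyntheticConfig(size=1024, disc_semi_axes=(110.0, 120.0),
                              cup_semi_axes=(44.0, 48.0), seed=5)
        _, mask, _ = generate_synthetic(cfg)
        img = np.zeros((1024, 1024, 3), dtype=np.float32)
        _, down = resize_pair(img, mask, 512)
        _, up = resize_pair(img[:512, :512], down, 1024)
        disc0, _ = M.structure_masks(mask)
        disc1, _ = M.structure_masks(up)
        dc = M.dice_coefficient(M.confusion_counts(disc1, disc0))
        assert dc >= 0.98


class TestAugmentation:
    def test_enumeration_counts(self, synthetic_128):
        image, mask, _ = synthetic_128
        out = augment(image, mask)
        assert len(out) == 4 * 14 == 56
        assert len(DEFAULT_TRANSLATIONS) == 14 and (0, 0) in DEFAULT_TRANSLATIONS

    def test_identity_variant_reproduces_input(self, synthetic_128):
        image, mask, _ = synthetic_128
        out = augment(image, mask)
        np.testing.assert_array_equal(out[0][0], image)
        np.testing.assert_array_equal(out[0][1], mask)

    def test_hflip_is_involution(self, synthetic_128):
        image, mask, _ = synthetic_128
        spec = AugmentationSpec(flips=("horizontal",), translations=((0, 0),))
        once = augment(image, mask, spec)[0]
        twice = augment(once[0], once[1], spec)[0]
        np.testing.assert_array_equal(twice[0], image)
        np.testing.assert_array_equal(twice[1], mask)

    def test_translation_preserves_cdr(self, synthetic_128):
        image, mask, _ = synthetic_128
        spec = AugmentationSpec(flips=("none",), translations=((0, 0), (16, -8)))
        for _, m2 in augment(image, mask, spec):
            d0, c0 = M.structure_masks(mask)
            d2, c2 = M.structure_masks(m2)
            assert M.cdr(c2, d2).value == M.cdr(c0, d0).value

    def test_every_variant_self_consistent_under_metrics(self, synthetic_128):
        image, mask, _ = synthetic_128
        for _, m2 in augment(image, mask)[:8]:
            disc, _ = M.structure_masks(m2)
            ref, _ = M.structure_masks(m2)
            assert M.dice_coefficient(M.confusion_counts(disc, ref)) == 1.0

    def test_oversized_offset_rejected(self, synthetic_128):
        image, mask, _ = synthetic_128
        spec = AugmentationSpec(translations=((0, 0), (200, 0)))
        with pytest.raises(ConfigurationError):
            augment(image, mask, spec)


class TestSyntheticGenerator:
    def test_deterministic_per_seed(self):
        cfg = SyntheticConfig(size=128, disc_semi_axes=(26.0, 28.0),
                              cup_semi_axes=(11.0, 12.0), seed=9)
        a = generate_synthetic(cfg)
        b = generate_synthetic(cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_background_dominates_default_image(self):
        _, mask, _ = generate_synthetic(SyntheticConfig(seed=1))
        assert (mask == 0).mean() > 0.9

    def test_cup_strictly_inside_disc_required(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(disc_semi_axes=(20.0, 20.0),
                            cup_semi_axes=(20.0, 10.0)).validate()

    def test_spec_example_half_cdr(self):
        cfg = SyntheticConfig(size=256, disc_semi_axes=(55.0, 60.0),
                              cup_semi_axes=(27.0, 30.0), center_jitter=10, seed=4)
        _, mask, true_cdr = generate_synthetic(cfg)
        disc, cup = M.structure_masks(mask)
        got = M.cdr(cup, disc)
        assert abs(got.value - 0.5) <= 1.0 / got.vd_disc + 0.01

    def test_cdr_recovered_within_one_pixel_across_seeds(self):
        for seed in range(25):
            cfg = SyntheticConfig(size=160, disc_semi_axes=(30.0, 33.0),
                                  cup_semi_axes=(13.0, 14.0),
                                  center_jitter=10, seed=seed)
            _, mask, true_cdr = generate_synthetic(cfg)
            disc, cup = M.structure_masks(mask)
            got = M.cdr(cup, disc)
            assert abs(got.value - true_cdr) <= 1.0 / got.vd_disc

    def test_cohort_has_both_regimes(self):
        samples = make_synthetic_dataset(8, seed=2, size=96, glaucoma_fraction=0.5)
        cdrs = np.array([s.true_cdr for s in samples])
        labs = np.array([s.glaucomatous for s in samples])
        assert (cdrs[labs == 1] > 0.5).all() and (cdrs[labs == 0] < 0.5).all()


class TestSplits:
    def test_all_in_train(self):
        tr, va, te = split_dataset(list(range(10)), (1, 0, 0), seed=0)
        assert tr == list(range(10)) and not va and not te

    def test_deterministic_and_partition(self):
        items = list(range(100))
        labels = [i % 2 for i in items]
        s1 = split_dataset(items, (0.6, 0.2, 0.2), seed=5, labels=labels)
        s2 = split_dataset(items, (0.6, 0.2, 0.2), seed=5, labels=labels)
        assert s1 == s2
        merged = sorted(s1[0] + s1[1] + s1[2])
        assert merged == items

    def test_stratified_test_draw_counts(self):
        items = list(range(400))
        labels = [1 if i < 40 else 0 for i in items]
        rest, test = heldout_test_split(items, labels, 10, 30, seed=1)
        test_labels = [labels[i] for i in test]
        assert sum(test_labels) == 10 and len(test) == 40
        assert len(rest) == 360 and set(rest) | set(test) == set(items)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ConfigurationError):
            heldout_test_split([1, 2, 3], [0, 0, 0], 1, 1, seed=0)


def test_manifest_round_trip(tmp_path):
    samples = make_synthetic_dataset(3, seed=0, size=64)
    manifest = write_synthetic_dataset(samples, tmp_path)
    rows = read_manifest(manifest)
    assert len(rows) == 3
    img, msk = load_pair(rows[0][0], rows[0][1])
    assert img.shape == (64, 64, 3) and msk.shape == (64, 64)
    assert rows[0][2] in (0, 1)
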