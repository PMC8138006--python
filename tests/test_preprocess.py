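"""Reference subtraction, flat-fielding, exposure equalization, and pixel repair."""

from dataclasses import replace

import numpy as np
import pytest

from specell.blocks import DataBlock, ReferenceImages, ValidationError
from specell.channels import default_channel_set
from specell.preprocess import (
    CorrectionSettings,
    equalize_exposure,
    flatfield_correct,
    preprocess_block,
    repair_bad_pixels,
    subtract_references,
)
from specell.synthetic import CohortConfig, generate_datablock, noise_free


def _tiny_block(n_channels=3, shape=(2, 2), raw=None, water=0.0, dark=0.0, calib=1.0):
    """Hand-built block with constant or explicit per-channel images."""
    cs = default_channel_set(n_channels=n_channels, exposures=[1.0] * n_channels)
    imgs = np.full((n_channels, *shape), 100.0) if raw is None else np.asarray(raw, float)
    mk = lambda v: np.broadcast_to(np.asarray(v, float), imgs.shape).copy()
    return DataBlock(
        channel_images=imgs.copy(),
        brightfield=np.zeros(shape),
        references=ReferenceImages(dark=mk(dark), water=mk(water), calibration=mk(calib)),
        channel_set=cs,
        field_id="F",
        patient_id="P",
        group_label=0,
    )


class TestSubtractReferences:
    def test_raw_equal_water_gives_zero(self):
        b = _tiny_block(water=100.0)
        out = subtract_references(b)
        assert np.all(out.channel_images == 0.0)

    def test_plain_arithmetic(self):
        b = _tiny_block(raw=np.full((3, 2, 2), 120.0), water=20.0)
        assert np.all(subtract_references(b).channel_images == 100.0)

    def test_negative_clipped(self):
        b = _tiny_block(raw=np.full((3, 2, 2), 15.0), water=20.0)
        assert np.all(subtract_references(b).channel_images == 0.0)

    def test_negative_kept_when_clip_disabled(self):
        b = _tiny_block(raw=np.full((3, 2, 2), 15.0), water=20.0)
        out = subtract_references(b, CorrectionSettings(clip_negative=False))
        assert np.all(out.channel_images == -5.0)


class TestFlatfield:
    def test_uniform_calibration_is_identity(self):
        b = _tiny_block(raw=np.full((3, 2, 2), 37.0), calib=5.0)
        out = flatfield_correct(b)
        assert np.allclose(out.channel_images, b.channel_images)

    def test_hand_example(self):
        # calib {1, 3} (mean 2), corrected {10, 30} -> flat {20, 20}
        raw = np.array([[[10.0, 30.0]]])
        b = _tiny_block(n_channels=1, shape=(1, 2), raw=raw, calib=0.0)
        b.references.calibration[0] = np.array([[1.0, 3.0]])
        out = flatfield_correct(b)
        assert np.allclose(out.channel_images[0], [[20.0, 20.0]])

    def test_nonpositive_calibration_names_channel(self):
        b = _tiny_block(calib=0.0)
        with pytest.raises(ValidationError, match="channel 1"):
            flatfield_correct(b)

    def test_inverts_generator_illumination_noise_free(self, spectra, channel_set):
        cfg = noise_free(CohortConfig(seed=3, image_shape=(128, 128)))
        block, _, truth = generate_datablock(cfg, spectra, "P", 1, "F")
        out = equalize_exposure(flatfield_correct(subtract_references(block)))
        exposures = channel_set.exposures[:, None, None]
        expected = (
            truth.clean_signal
            / truth.illumination[None]
            / exposures
            * truth.illumination.mean()
        )
        m = truth.clean_signal > 0
        rel = np.abs(out.channel_images[m] - expected[m]) / expected[m]
        assert rel.max() < 1e-10


class TestEqualizeExposure:
    def test_division_by_exposure(self):
        b = _tiny_block(n_channels=2)
        cs = default_channel_set(n_channels=2, exposures=[5.0, 2.0])
        b.channel_set = cs
        b.channel_images[0] = 50.0
        b.channel_images[1] = 50.0
        out = equalize_exposure(b)
        assert np.all(out.channel_images[0] == 10.0)
        assert np.all(out.channel_images[1] == 25.0)
        assert all(c.exposure == 1.0 for c in out.channel_set)

    def test_exposure_change_equalizes_noise_free(self, spectra):
        cfg = noise_free(CohortConfig(seed=6, image_shape=(64, 64)))
        out = {}
        for exposure in (1.0, 2.0):
            cs = default_channel_set(exposures=[exposure] * 34)
            from specell.synthetic import make_endmembers

            sp = make_endmembers(cs, seed=1)
            block, _, _ = generate_datablock(
                cfg, sp, "P", 0, "F", rng=np.random.default_rng(11)
            )
            out[exposure] = equalize_exposure(
                flatfield_correct(subtract_references(block))
            ).channel_images
        assert np.allclose(out[1.0], out[2.0])


class TestRepair:
    def test_clean_constant_image_unchanged(self):
        b = _tiny_block(n_channels=2, shape=(32, 32), calib=50.0)
        out, flags = repair_bad_pixels(b)
        assert flags.sum() == 0
        assert np.array_equal(out.channel_images, b.channel_images)

    def test_single_saturated_pixel_replaced_by_neighbourhood(self):
        b = _tiny_block(n_channels=1, shape=(32, 32), calib=50.0)
        b.channel_images[0, 10, 10] = b.saturation_level
        out, flags = repair_bad_pixels(b)
        assert flags.sum() == 1
        assert out.channel_images[0, 10, 10] == 100.0

    def test_injected_hot_and_dead_pixels_recovered(self, spectra):
        cfg = CohortConfig(
            seed=7, image_shape=(256, 256), hot_pixel_rate=1e-3, dead_pixel_rate=1e-3
        )
        block, _, truth = generate_datablock(cfg, spectra, "P", 1, "F")
        _, flags = repair_bad_pixels(block)
        injected = truth.hot_mask | truth.dead_mask
        assert flags[injected].mean() >= 0.99
        assert flags[~injected].mean() <= 0.005

    def test_unusable_channel_is_fatal(self):
        b = _tiny_block(n_channels=1, shape=(32, 32), dark=90.0, water=95.0, calib=140.0)
        # 30% of the channel below the dark floor -> channel unusable
        b.channel_images[0, :10, :] = 0.0
        with pytest.raises(ValidationError, match="unusable"):
            repair_bad_pixels(b)

    def test_uniform_target_flattened_below_one_percent_cv(self, rng):
        cs = default_channel_set(exposures=[1.0] * 34)
        from specell.synthetic import make_endmembers

        sp = make_endmembers(cs, seed=1)
        cfg = CohortConfig(seed=5, image_shape=(256, 256))
        block, _, _ = generate_datablock(
            cfg, sp, "P", 0, "F", uniform_target_level=30000.0
        )
        raw_cv = block.channel_images.std(axis=(1, 2)) / block.channel_images.mean(
            axis=(1, 2)
        )
        assert raw_cv.min() > 0.10
        out, _ = preprocess_block(block)
        cv = out.channel_images.std(axis=(1, 2)) / out.channel_images.mean(axis=(1, 2))
        assert cv.max() < 0.01


class TestComposedMap:
    def test_reprocessing_is_near_identity(self, processed_small_block):
        processed, _, _, _ = processed_small_block
        again, flags = preprocess_block(processed)
        changed = ~np.isclose(again.channel_images, processed.channel_images)
        # borderline noise-tail pixels may be re-repaired; everything else fixed
        assert changed.mean() < 1e-4
        untouched = ~changed
        assert np.allclose(
            again.channel_images[untouched], processed.channel_images[untouched]
        )

    def test_channel_permutation_commutes_with_processing(self, spectra):
        cfg = CohortConfig(seed=21, image_shape=(64, 64))
        block, _, _ = generate_datablock(cfg, spectra, "P", 0, "F")
        perm = np.arange(34)
        perm[[0, 7]] = perm[[7, 0]]

        def permute(b):
            out = b.copy()
            out.channel_images = b.channel_images[perm]
            out.references = ReferenceImages(
                dark=b.references.dark[perm],
                water=b.references.water[perm],
                calibration=b.references.calibration[perm],
            )
            chans = [b.channel_set[i] for i in perm]
            out.channel_set = type(b.channel_set)(
                tuple(replace(c, index=k + 1) for k, c in enumerate(chans))
            )
            return out

        direct, _ = preprocess_block(block)
        swapped, _ = preprocess_block(permute(block))
        assert np.allclose(permute(direct).channel_images, swapped.channel_images)
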