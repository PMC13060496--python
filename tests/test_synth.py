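"""Unit tests for the domain-randomized generator."""

import numpy as np
import pytest

from slabimpute import (GMMParams, LabelVolume, SynthConfig, deform_labels,
                        digital_slab_sample, gamma_augment,
                        generate_synthetic_volume, apply_illumination,
                        make_minibatch, sample_affine, sample_illumination,
                        sample_nonlinear_field, synthesize_intensity)
from slabimpute.synth import IlluminationField, extract_slice, sample_smooth_field

from conftest import make_ramp_volume


def autocorr_half_width(field, axis):
    """First lag at which the mean autocorrelation along ``axis`` drops below 0.5."""
    f = np.moveaxis(field, axis, -1)
    f = f - f.mean()
    for lag in range(1, f.shape[-1]):
        a = f[..., :-lag].ravel()
        b = f[..., lag:].ravel()
        c = np.corrcoef(a, b)[0, 1]
        if c < 0.5:
            return lag
    return f.shape[-1]


class TestSampleAffine:
    def test_identity_config_gives_identity(self, rng):
        assert np.array_equal(sample_affine(rng, SynthConfig.identity()),
                              np.eye(4))

    def test_pinned_scale(self, rng):
        cfg = SynthConfig.identity(scale=(2.0, 2.0))
        assert np.allclose(sample_affine(rng, cfg), np.diag([2, 2, 2, 1]))

    def test_deterministic_under_seed(self):
        cfg = SynthConfig()
        a = sample_affine(np.random.default_rng(3), cfg)
        b = sample_affine(np.random.default_rng(3), cfg)
        assert np.array_equal(a, b)
        assert abs(np.linalg.det(a)) > 0


class TestSmoothFields:
    def test_zero_amplitude_is_zero_field(self, rng):
        f = sample_smooth_field(rng, (8, 8, 8), 0.0, (16, 16, 4))
        assert not f.any()

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_smooth_field(rng, (8, 8, 8), -1.0, (16, 16, 4))

    def test_determinism(self):
        cfg = SynthConfig()
        f1 = sample_nonlinear_field(np.random.default_rng(5), (24, 24, 24), cfg)
        f2 = sample_nonlinear_field(np.random.default_rng(5), (24, 24, 24), cfg)
        assert np.array_equal(f1.displacement, f2.displacement)

    def test_ap_decorrelates_faster_than_inplane(self):
        cfg = SynthConfig(nonlinear_sd_mm=3.0, nonlinear_corr_mm=(16, 16, 4))
        for seed in range(10):
            f = sample_nonlinear_field(np.random.default_rng(seed),
                                       (48, 48, 48), cfg).displacement[0]
            hw_ap = autocorr_half_width(f, 2)
            assert hw_ap < autocorr_half_width(f, 0)
            assert hw_ap < autocorr_half_width(f, 1)

    def test_amplitude_scaling(self):
        cfg = SynthConfig(nonlinear_sd_mm=3.0, nonlinear_corr_mm=(16, 16, 4))
        f = sample_nonlinear_field(np.random.default_rng(0), (64, 64, 64), cfg)
        # pointwise sd is pinned to the configured value; |disp| stays bounded
        assert np.isclose(f.displacement[0].std(), 3.0)
        assert np.abs(f.displacement).mean() <= 3.0 * 3


class TestDeformLabels:
    def test_identity_returns_input(self, small_phantom):
        out = deform_labels(small_phantom, np.eye(4))
        assert np.array_equal(out.labels, small_phantom.labels)

    def test_translation_shifts_by_one_voxel(self, rng):
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32)
        vol = LabelVolume(labels)
        affine = np.eye(4)
        affine[0, 3] = 1.0
        out = deform_labels(vol, affine)
        assert np.array_equal(out.labels[1:], labels[:-1])
        assert not out.labels[0].any()  # vacated face becomes background

    def test_no_new_labels_appear(self, small_phantom, rng):
        affine = sample_affine(rng, SynthConfig())
        field = sample_nonlinear_field(rng, small_phantom.labels.shape,
                                       SynthConfig())
        out = deform_labels(small_phantom, affine, field)
        assert set(np.unique(out.labels)) <= set(np.unique(small_phantom.labels)) | {0}


class TestGMMSynthesis:
    def test_degenerate_gaussians(self, rng):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[2:] = 1
        vol = LabelVolume(labels)
        img = synthesize_intensity(vol, GMMParams({0: 1.0, 1: 9.0},
                                                  {0: 0.0, 1: 0.0}), rng)
        assert np.array_equal(img, np.where(labels == 1, 9.0, 1.0))

    def test_sample_moments(self, rng):
        labels = np.ones((22, 22, 22), dtype=np.int32)  # >1e4 voxels
        img = synthesize_intensity(LabelVolume(labels),
                                   GMMParams({1: 10.0}, {1: 2.0}), rng)
        assert abs(img.mean() - 10.0) < 0.1
        assert abs(img.std() - 2.0) < 0.1

    def test_missing_label_raises(self, rng):
        vol = LabelVolume(np.ones((3, 3, 3), dtype=np.int32))
        with pytest.raises(ValueError, match="without GMM"):
            synthesize_intensity(vol, GMMParams({0: 1.0}, {0: 1.0}), rng)


class TestGammaAugment:
    def test_identity_exponent_normalizes_only(self, rng):
        img = np.array([0.0, 0.25, 1.0])
        out = gamma_augment(img, rng, SynthConfig.identity())
        assert np.array_equal(out, img)

    def test_pinned_exponent_two(self, rng):
        cfg = SynthConfig.identity(log_gamma=(np.log(2.0), np.log(2.0)))
        out = gamma_augment(np.array([0.0, 0.25, 1.0]), rng, cfg)
        assert np.allclose(out, [0.0, 0.0625, 1.0])

    def test_rank_preservation(self, rng):
        img = np.random.default_rng(1).random((6, 6, 6))
        out = gamma_augment(img, rng, SynthConfig())
        assert np.array_equal(np.argsort(img.ravel()), np.argsort(out.ravel()))

    def test_constant_volume_maps_to_zero(self, rng):
        out = gamma_augment(np.full((3, 3, 3), 7.0), rng, SynthConfig())
        assert not out.any()


class TestIllumination:
    def test_unit_gain_is_identity(self, rng):
        img = rng.random((4, 4, 4))
        out = apply_illumination(img, IlluminationField(np.ones_like(img)))
        assert np.array_equal(out, img)

    def test_constant_fields_multiply(self):
        out = apply_illumination(np.full((2, 2, 2), 3.0),
                                 IlluminationField(np.full((2, 2, 2), 2.0)))
        assert np.array_equal(out, np.full((2, 2, 2), 6.0))

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            IlluminationField(np.zeros((2, 2, 2)))

    def test_gain_strictly_positive_and_anisotropic(self):
        cfg = SynthConfig()
        for seed in range(10):
            f = sample_illumination(np.random.default_rng(seed), (48, 48, 48), cfg)
            assert (f.gain > 0).all()
            logg = np.log(f.gain)
            assert autocorr_half_width(logg, 2) < autocorr_half_width(logg, 0)


class TestDigitalSlabbing:
    def test_ap_constant_volume_gives_equal_slices(self, rng):
        vol = np.tile(rng.random((8, 8))[:, :, None], (1, 1, 20))
        t = digital_slab_sample(vol, rng)
        assert np.allclose(t.x1, t.x2)
        assert np.allclose(t.x1, t.y)

    def test_geometry_invariants(self):
        rng = np.random.default_rng(0)
        vol = rng.random((8, 8, 20))
        for _ in range(200):
            t = digital_slab_sample(vol, rng)
            assert np.isclose(t.d1 + t.d2, t.thickness)
            assert 2.0 <= t.thickness <= 12.0

    def test_linear_ramp_target_is_exact_interpolation(self):
        rng = np.random.default_rng(3)
        vol = make_ramp_volume((8, 8, 30), slope=1.7, offset=0.4)
        for _ in range(50):
            t = digital_slab_sample(vol, rng)
            d = t.d1 + t.d2
            y_lin = (t.d2 / d) * t.x1 + (t.d1 / d) * t.x2
            assert np.allclose(t.y, y_lin, atol=1e-9)

    def test_too_thin_volume_rejected(self, rng):
        with pytest.raises(ValueError):
            digital_slab_sample(np.zeros((4, 4, 10)), rng)

    def test_extract_slice_bounds(self, rng):
        with pytest.raises(ValueError):
            extract_slice(np.zeros((4, 4, 10)), 9.5)


class TestMinibatch:
    def test_default_batch_is_32(self):
        rng = np.random.default_rng(0)
        vol = rng.random((8, 8, 20))
        assert len(make_minibatch(vol, rng)) == 32

    def test_single_triplet(self):
        rng = np.random.default_rng(0)
        vol = rng.random((8, 8, 20))
        assert len(make_minibatch(vol, rng, SynthConfig(minibatch=1))) == 1

    def test_replay_is_identical(self):
        vol = np.random.default_rng(1).random((8, 8, 20))
        b1 = make_minibatch(vol, np.random.default_rng(9))
        b2 = make_minibatch(vol, np.random.default_rng(9))
        for t1, t2 in zip(b1, b2):
            assert t1.d1 == t2.d1 and t1.d2 == t2.d2
            assert np.array_equal(t1.y, t2.y)


class TestFullSynthesis:
    def test_all_randomization_disabled_constant_label(self, rng):
        labels = np.ones((16, 16, 16), dtype=np.int32)
        labels[0, 0, 0] = 0  # two labels so the volume is not constant
        cfg = SynthConfig.identity(gmm_mean=(5.0, 5.0), gmm_sd=(0.0, 0.0))
        img, deformed = generate_synthetic_volume(LabelVolume(labels), rng, cfg)
        # identical means for both labels -> constant after GMM -> zeros by the
        # degenerate gamma rule
        assert not img.any()
        assert np.array_equal(deformed.labels, labels)

    def test_bit_identical_replay(self, small_phantom):
        img1, d1 = generate_synthetic_volume(small_phantom,
                                             np.random.default_rng(4))
        img2, d2 = generate_synthetic_volume(small_phantom,
                                             np.random.default_rng(4))
        assert np.array_equal(img1, img2)
        assert np.array_equal(d1.labels, d2.labels)

    def test_output_range(self, small_phantom):
        img, _ = generate_synthetic_volume(small_phantom,
                                           np.random.default_rng(8))
        assert np.isfinite(img).all()
        assert img.min() >= 0.0
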