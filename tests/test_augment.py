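import numpy as np
import pytest
from scipy import stats

from sasus.augment import (NOISE_TYPES, SASConfig, augment_policy,
                           classify_size, inject_noise, sample_thumbnail_size,
                           sas_transform, scale_to_thumbnail)

from conftest import disk_mask, ellipse_mask, make_sample


def tiny_cfg(**kw):
    """Small canvas config so high-repetition statistical tests stay fast."""
    defaults = dict(input_size=32, thumb_min=8, thumb_max=32)
    defaults.update(kw)
    return SASConfig(**defaults)


class TestClassify:
    @pytest.mark.parametrize("ratio,expected", [
        (0.03, "small"),        # "up to 3%" is inclusive
        (0.030001, "large"),
        (0.0, "small"),
        (1.0, "large"),
    ])
    def test_threshold(self, ratio, expected):
        assert classify_size(ratio) == expected

    def test_monotone_switch_exactly_after_threshold(self):
        ratios = np.linspace(0, 0.1, 201)
        classes = [classify_size(r) for r in ratios]
        flips = [i for i in range(1, len(classes)) if classes[i] != classes[i - 1]]
        assert len(flips) == 1
        assert ratios[flips[0] - 1] <= 0.03 < ratios[flips[0]]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_size(1.2)


class TestThumbnailSize:
    def test_degenerate_interval(self, rng):
        cfg = SASConfig(thumb_min=128, thumb_max=128)
        assert all(sample_thumbnail_size(cfg, rng) == 128 for _ in range(20))

    def test_uniform_over_range(self, rng):
        """1e5 draws at defaults: support is exactly 64..256 and the
        histogram is compatible with a uniform distribution."""
        cfg = SASConfig()
        draws = np.array([sample_thumbnail_size(cfg, rng) for _ in range(100_000)])
        assert draws.min() == 64 and draws.max() == 256
        counts = np.bincount(draws - 64, minlength=193)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01
        assert draws.min() / cfg.input_size == 0.25  # min scaling ratio


class TestScale:
    def test_identity_scale_keeps_content(self, rng):
        s = make_sample(disk_mask(64, 32, 32, 12), rng)
        cfg = SASConfig(input_size=64, thumb_min=16, thumb_max=64,
                        placement="centered")
        out = scale_to_thumbnail(s, 64, cfg, rng)
        assert np.array_equal(out.mask, s.mask)
        np.testing.assert_allclose(out.image, s.image, atol=1e-6)

    def test_area_scaling_law(self, rng):
        """Mask area scales as (thumb/input)^2 within rounding tolerance."""
        cfg = SASConfig(input_size=256, thumb_min=64, thumb_max=256)
        for mask in (disk_mask(256, 128, 128, 70),
                     ellipse_mask(256, 120, 130, 60, 90)):
            s = make_sample(mask, rng)
            for thumb in (64, 128, 192):
                out = scale_to_thumbnail(s, thumb, cfg, rng)
                expected = mask.sum() * (thumb / 256) ** 2
                assert out.mask.sum() == pytest.approx(expected, rel=0.04)

    def test_zero_background_conservation(self, rng):
        s = make_sample(disk_mask(64, 30, 30, 20), rng)
        s.image += 0.05  # strictly positive content everywhere
        cfg = SASConfig(input_size=64, thumb_min=8, thumb_max=64)
        for _ in range(50):
            thumb = sample_thumbnail_size(cfg, rng)
            out = scale_to_thumbnail(s, thumb, cfg, rng)
            top, left = out.history[-1][1]["top"], out.history[-1][1]["left"]
            outside = np.ones((64, 64), dtype=bool)
            outside[top:top + thumb, left:left + thumb] = False
            assert out.image[outside].sum() == 0.0

    def test_thumb_larger_than_input_raises(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 8), rng)
        with pytest.raises(ValueError):
            scale_to_thumbnail(s, 64, tiny_cfg(), rng)


class TestNoise:
    @pytest.mark.parametrize("noise_type", NOISE_TYPES)
    def test_mask_locality(self, noise_type, rng):
        """Pixels outside the mask are bit-identical for every noise type."""
        s = make_sample(disk_mask(48, 24, 24, 10), rng)
        cfg = tiny_cfg(input_size=48, thumb_max=48)
        out = inject_noise(s, noise_type, cfg, rng)
        bg = s.mask == 0
        assert np.array_equal(out.image[bg], s.image[bg])
        assert np.array_equal(out.mask, s.mask)
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_empty_roi_is_identity(self, rng):
        s = make_sample(np.zeros((32, 32), dtype=np.uint8), rng)
        out = inject_noise(s, "gaussian", tiny_cfg(), rng)
        assert np.array_equal(out.image, s.image)

    def test_salt_pepper_flip_count(self):
        """Average flipped-pixel count over seeded runs matches a*n."""
        mask = disk_mask(48, 24, 24, 15)
        n = int(mask.sum())
        amount = 0.05
        cfg = tiny_cfg(input_size=48, thumb_max=48,
                       noise_params={"gaussian_var": 0.01, "speckle_var": 0.01,
                                     "salt_pepper_amount": amount,
                                     "poisson_scale": 255.0})
        counts = []
        for seed in range(1000):
            r = np.random.default_rng(seed)
            s = make_sample(mask, np.random.default_rng(7))
            out = inject_noise(s, "salt_pepper", cfg, r)
            counts.append(int((out.image != s.image).sum()))
        # flips are Binomial(n, a); allow 4 sigma on the mean of 1000 runs
        expect = amount * n
        se = np.sqrt(n * amount * (1 - amount) / 1000)
        assert abs(np.mean(counts) - expect) < 4 * se

    def test_seed_determinism(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 8), rng)
        cfg = tiny_cfg()
        a = inject_noise(s, "gaussian", cfg, np.random.default_rng(5))
        b = inject_noise(s, "gaussian", cfg, np.random.default_rng(5))
        c = inject_noise(s, "gaussian", cfg, np.random.default_rng(6))
        assert np.array_equal(a.image, b.image)
        assert not np.array_equal(a.image, c.image)

    def test_unknown_type_raises(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 8), rng)
        with pytest.raises(ValueError, match="unknown"):
            inject_noise(s, "perlin", tiny_cfg(), rng)


class TestSASTransform:
    def test_both_flags_off_identity(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 8), rng)
        cfg = tiny_cfg(enable_scale=False, enable_noise=False)
        out = sas_transform(s, cfg, rng)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_scale_only_keeps_binary_mask_and_zero_bg(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 10), rng)
        cfg = tiny_cfg(enable_noise=False)
        out = sas_transform(s, cfg, rng)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_noise_type_frequencies(self):
        """Each of the four noise types is drawn with frequency 1/4 +- 0.01
        over 1e5 transforms."""
        cfg = tiny_cfg(input_size=16, thumb_min=8, thumb_max=16)
        s = make_sample(disk_mask(16, 8, 8, 4), np.random.default_rng(0))
        rng = np.random.default_rng(99)
        counts = dict.fromkeys(NOISE_TYPES, 0)
        n = 100_000
        for _ in range(n):
            out = sas_transform(s, cfg, rng)
            counts[out.history[-1][1]["noise_type"]] += 1
        for t in NOISE_TYPES:
            assert abs(counts[t] / n - 0.25) <= 0.01

    def test_full_stream_determinism(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 8), rng)
        cfg = tiny_cfg()
        a = sas_transform(s, cfg, np.random.default_rng(11))
        b = sas_transform(s, cfg, np.random.default_rng(11))
        assert np.array_equal(a.image, b.image)
        assert a.history == b.history


class TestPolicy:
    def test_small_structures_never_transformed(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 2), rng, size_class="small")
        for seed in range(30):
            out = augment_policy(s, tiny_cfg(), np.random.default_rng(seed))
            assert np.array_equal(out.image, s.image)

    def test_large_structures_transformed_half_the_time(self):
        """1e5 policy draws: applied fraction 0.5 +- 0.01."""
        cfg = tiny_cfg(input_size=16, thumb_min=8, thumb_max=16)
        s = make_sample(disk_mask(16, 8, 8, 5), np.random.default_rng(1),
                        size_class="large")
        rng = np.random.default_rng(42)
        applied = 0
        n = 100_000
        for _ in range(n):
            out = augment_policy(s, cfg, rng)
            applied += out.history[-1][1]["applied"]
        assert abs(applied / n - 0.5) <= 0.01

    def test_zero_probability_never_applies(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 10), rng, size_class="large")
        cfg = tiny_cfg(apply_prob=0.0)
        for seed in range(20):
            out = augment_policy(s, cfg, np.random.default_rng(seed))
            assert np.array_equal(out.image, s.image)

    def test_unassigned_size_class_raises(self, rng):
        s = make_sample(disk_mask(32, 16, 16, 10), rng)
        with pytest.raises(ValueError):
            augment_policy(s, tiny_cfg(), rng)


class TestConfigValidation:
    def test_invalid_thumb_range(self):
        with pytest.raises(ValueError):
            SASConfig(thumb_min=300, thumb_max=256)

    def test_invalid_prob(self):
        with pytest.raises(ValueError):
            SASConfig(apply_prob=1.5)

    def test_empty_noise_types_with_noise_enabled(self):
        with pytest.raises(ValueError):
            SASConfig(noise_types=(), enable_noise=True)
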