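"""Tests for glyph generation and the tissue-scattering forward model."""

import numpy as np
import pytest

from nirunet import (DatasetManifest, GLYPH_KINDS, PhantomParams,
                     build_dataset, generate_glyph, tissue_forward)
from nirunet.errors import ConfigurationError, DomainError
from nirunet.phantom_sim import glare_field, split_labels, split_sizes


class TestGenerateGlyph:
    @pytest.mark.parametrize("kind", GLYPH_KINDS)
    def test_shape_and_range(self, kind):
        img = generate_glyph(kind, 200, np.random.default_rng(0))
        assert img.shape == (200, 200)
        assert img.min() >= 0.0 and img.max() <= 1.0

    @pytest.mark.parametrize("kind", GLYPH_KINDS)
    def test_determinism(self, kind):
        a = generate_glyph(kind, 64, np.random.default_rng(99))
        b = generate_glyph(kind, 64, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_binary_before_antialias(self):
        img = generate_glyph("rectangle", 64, np.random.default_rng(1),
                             antialias=False)
        assert set(np.unique(img)) <= {0.0, 1.0}

    def test_stroke_digit_foreground_fraction_band(self):
        """Every one of 1,000 draws keeps 3-45% of pixels in the pattern."""
        rng = np.random.default_rng(2024)
        fracs = [generate_glyph("stroke-digit", 96, rng,
                                antialias=False).mean() for _ in range(1000)]
        assert min(fracs) >= 0.03 and max(fracs) <= 0.45

    @pytest.mark.parametrize("kind", ("ring", "rectangle", "random-polyline"))
    def test_other_kinds_fraction_band(self, kind):
        rng = np.random.default_rng(7)
        fracs = [generate_glyph(kind, 96, rng, antialias=False).mean()
                 for _ in range(100)]
        assert min(fracs) >= 0.03 and max(fracs) <= 0.45

    def test_errors(self):
        with pytest.raises(ConfigurationError):
            generate_glyph("pentagram", 64, 0)
        with pytest.raises(DomainError):
            generate_glyph("ring", 31, 0)


class TestTissueForward:
    def test_all_off_gives_constant_background(self, glyph96):
        p = PhantomParams(attenuation=0.0, glare_amplitude=0.0,
                          speckle_std=0.0, sensor_noise_std=0.0,
                          blur_sigma_px_per_mm=0.0, bit_depth=16)
        out = tissue_forward(glyph96, p)
        expected = np.round(p.background_level * (2 ** 16 - 1)) / (2 ** 16 - 1)
        np.testing.assert_allclose(out, expected)

    def test_identity_limit_inverts_target(self):
        target = generate_glyph("rectangle", 64, np.random.default_rng(3),
                                antialias=False)  # exactly two-level
        p = PhantomParams(attenuation=1.0, background_level=1.0,
                          glare_amplitude=0.0, speckle_std=0.0,
                          sensor_noise_std=0.0, blur_sigma_px_per_mm=0.0)
        out = tissue_forward(target, p)
        np.testing.assert_array_equal(out, 1.0 - target)

    def test_purity_bit_identical(self, glyph96):
        p = PhantomParams(seed=11)
        np.testing.assert_array_equal(tissue_forward(glyph96, p),
                                      tissue_forward(glyph96, p))

    def test_quantization_levels_and_range(self, glyph96):
        for bits in (4, 8):
            out = tissue_forward(glyph96, PhantomParams(bit_depth=bits))
            assert out.min() >= 0.0 and out.max() <= 1.0
            assert len(np.unique(out)) <= 2 ** bits

    def test_contrast_decays_with_thickness(self):
        """Correlation with the inverted target strictly decreases as the
        phantom thickens (stronger PSF), averaged over 50 seeded glyphs."""
        mean_corr = []
        for thick in (1.0, 5.0, 15.0):
            p = PhantomParams(thickness_mm=thick)
            corrs = []
            for i in range(50):
                g = generate_glyph("stroke-digit", 96,
                                   np.random.default_rng(i))
                c = tissue_forward(g, p, np.random.default_rng(1000 + i))
                corrs.append(abs(np.corrcoef(c.ravel(),
                                             (1 - g).ravel())[0, 1]))
            mean_corr.append(np.mean(corrs))
        assert mean_corr[0] > mean_corr[1] > mean_corr[2]

    def test_blur_removes_high_frequency_energy(self):
        """With sigma > 0 the captured spectrum above the PSF cutoff holds
        strictly less energy than the clean radiance map's."""
        p = PhantomParams(glare_amplitude=0.0, speckle_std=0.0,
                          sensor_noise_std=0.0, bit_depth=16)
        cutoff = 0.25  # cycles/px, well above the PSF passband
        for i in range(10):
            g = generate_glyph("ring", 96, np.random.default_rng(i))
            radiance = p.background_level * (1 - p.attenuation * g)
            captured = tissue_forward(g, p)
            fr = np.fft.fftfreq(96)
            mask = np.add.outer(fr ** 2, fr ** 2) > cutoff ** 2
            e_rad = np.sum(np.abs(np.fft.fft2(radiance))[mask] ** 2)
            e_cap = np.sum(np.abs(np.fft.fft2(captured))[mask] ** 2)
            assert e_cap < e_rad

    def test_glare_field_zero_mean_unit_gradient(self):
        f = glare_field((64, 64), amplitude=0.3, angle_deg=30.0)
        assert abs(f.mean() - 1.0) < 1e-12
        gy, gx = np.gradient((f - 1.0) / 0.3)
        mag = np.hypot(gx.mean(), gy.mean()) * 64
        assert abs(mag - 1.0) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            tissue_forward(np.full((8, 8, 3), 0.5), PhantomParams())
        with pytest.raises(DomainError):
            tissue_forward(np.full((8, 8), 1.5), PhantomParams())
        with pytest.raises(ConfigurationError):
            PhantomParams(thickness_mm=0.0)
        with pytest.raises(ConfigurationError):
            PhantomParams(attenuation=1.2)


class TestSplitsAndDataset:
    def test_split_sizes_paper_fractions(self):
        assert split_sizes(100, (0.70, 0.15, 0.15)) == (70, 15, 15)

    def test_split_sizes_remainder_to_training(self):
        # round(10003*0.15) = 1500 twice; training takes the remainder 7003
        assert split_sizes(10003, (0.70, 0.15, 0.15)) == (7003, 1500, 1500)

    @pytest.mark.parametrize("n", (10, 100, 999))
    def test_splits_disjoint_and_exhaustive(self, n):
        labels = split_labels(n, (0.70, 0.15, 0.15),
                              np.random.default_rng(0))
        counts = {s: int((labels == s).sum()) for s in ("train", "val", "test")}
        assert sum(counts.values()) == n
        assert counts["val"] == round(n * 0.15)
        assert counts["test"] == round(n * 0.15)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            split_sizes(100, (0.5, 0.25, 0.35))

    def test_build_dataset_deterministic(self, tmp_path):
        p = PhantomParams()
        m1 = build_dataset(12, p, seed=5, out_dir=tmp_path / "a", size=32)
        m2 = build_dataset(12, p, seed=5, out_dir=tmp_path / "b", size=32)
        assert m1.records == m2.records
        for r in m1.records:
            a = (tmp_path / "a" / r["captured"]).read_bytes()
            b = (tmp_path / "b" / r["captured"]).read_bytes()
            assert a == b

    def test_manifest_roundtrip(self, tmp_path):
        p = PhantomParams(thickness_mm=3.0)
        m = build_dataset(10, p, seed=1, out_dir=tmp_path, size=32)
        loaded = DatasetManifest.load(tmp_path / "manifest.json")
        assert loaded.records == m.records
        assert loaded.params == p
        assert loaded.split_sizes() == m.split_sizes()
        # every referenced file exists
        for t, c in loaded.paths("train"):
            assert t.exists() and c.exists()

    def test_build_dataset_too_small(self, tmp_path):
        with pytest.raises(DomainError):
            build_dataset(5, PhantomParams(), 0, tmp_path, size=32)
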