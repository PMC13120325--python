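"""Tests for MSE/PSNR/SSIM/FSIM, reports, profiles, and failure counting."""

import math

import numpy as np
import pytest

from nirunet import (MetricParams, evaluate_methods, failure_rate, fsim,
                     generate_glyph, intensity_profile, mse, psnr, ssim)
from nirunet.errors import DomainError, EvaluationError
from nirunet.quality_metrics import MetricsReport, plot_profiles

from oracles import ssim_reference


class TestMse:
    def test_hand_values(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert mse(x, x) == 0.0
        assert mse(np.ones((4, 4)), np.zeros((4, 4))) == 1.0
        assert mse(x, np.zeros((2, 2))) == 0.5

    def test_dimension_mismatch(self):
        with pytest.raises(DomainError):
            mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPsnr:
    def test_closed_forms(self):
        x = np.zeros((8, 8))
        assert psnr(x, x) == math.inf
        assert abs(psnr(np.ones((8, 8)), np.zeros((8, 8)), 1.0)) < 1e-12
        y = np.full((10, 10), 0.1)  # mse 0.01 -> 20 dB
        assert abs(psnr(np.zeros((10, 10)), y, 1.0) - 20.0) < 1e-12

    def test_strictly_decreasing_in_mse(self):
        values = [10.0 * math.log10(1.0 / m) for m in (0.001, 0.01, 0.1, 1.0)]
        computed = []
        for m in (0.001, 0.01, 0.1, 1.0):
            y = np.full((100,), math.sqrt(m))[None]
            computed.append(psnr(np.zeros((1, 100)), y))
        np.testing.assert_allclose(computed, values, atol=1e-10)
        assert all(a > b for a, b in zip(computed, computed[1:]))

    def test_bad_max_val(self):
        with pytest.raises(DomainError):
            psnr(np.zeros((4, 4)), np.ones((4, 4)), max_val=0.0)


class TestSsim:
    def test_identity_and_symmetry(self, rng):
        x = rng.random((64, 64))
        assert ssim(x, x) == 1.0
        for _ in range(20):
            a, b = rng.random((32, 32)), rng.random((32, 32))
            assert ssim(a, b) == ssim(b, a)

    def test_matches_reference_implementation(self):
        """Within 1e-6 of the original publication's formula on 20 seeded
        128x128 pairs."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            a = rng.random((128, 128))
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
            assert abs(ssim(a, b) - ssim_reference(a, b)) < 1e-6

    def test_too_small_image(self):
        with pytest.raises(DomainError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestFsim:
    def test_identity(self):
        g = generate_glyph("ring", 64, np.random.default_rng(0))
        assert abs(fsim(g, g) - 1.0) < 1e-12

    def test_range_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            v = fsim(rng.random((48, 48)), rng.random((48, 48)))
            assert 0.0 < v <= 1.0

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = rng.random((48, 48)), rng.random((48, 48))
            assert abs(fsim(a, b) - fsim(b, a)) < 1e-12

    def test_flip_invariance_with_ssim(self, rng):
        # odd sizes: the DFT grid is mirror-symmetric and invariance is
        # exact; even sizes leave an asymmetric Nyquist bin (~1e-5 effect)
        a = generate_glyph("stroke-digit", 65, rng)
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        for flip in (np.flipud, np.fliplr):
            assert abs(ssim(a, b) - ssim(flip(a), flip(b))) < 1e-9
            assert abs(fsim(a, b) - fsim(flip(a), flip(b))) < 1e-9
        a64, b64 = a[:64, :64], b[:64, :64]
        for flip in (np.flipud, np.fliplr):
            assert abs(fsim(a64, b64) - fsim(flip(a64), flip(b64))) < 1e-4

    def test_degrades_with_noise(self, rng):
        a = generate_glyph("rectangle", 64, rng)
        mild = np.clip(a + rng.normal(0, 0.02, a.shape), 0, 1)
        heavy = np.clip(a + rng.normal(0, 0.4, a.shape), 0, 1)
        assert fsim(a, mild) > fsim(a, heavy)

    def test_shape_mismatch(self):
        with pytest.raises(DomainError):
            fsim(np.zeros((64, 64)), np.zeros((64, 32)))


class TestMetricProperties:
    """Algebraic invariants over arbitrary image pairs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    pair = st.tuples(
        arrays(np.float64, (16, 16), elements=st.floats(0, 1)),
        arrays(np.float64, (16, 16), elements=st.floats(0, 1)))

    @given(pair)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mse_symmetric_nonnegative_bounded(self, ab):
        a, b = ab
        assert mse(a, b) == mse(b, a)
        assert 0.0 <= mse(a, b) <= 1.0

    @given(pair)
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_ssim_symmetric_and_bounded(self, ab):
        a, b = ab
        s = ssim(a, b, MetricParams(ssim_window=11))
        assert s == ssim(b, a, MetricParams(ssim_window=11))
        assert -1.0 <= s <= 1.0


class TestEvaluateMethods:
    def _pairs(self, n=3):
        rng = np.random.default_rng(9)
        out = []
        for i in range(n):
            t = generate_glyph("ring", 48, np.random.default_rng(i))
            c = np.clip(t + rng.normal(0, 0.1, t.shape), 0, 1)
            out.append((t, c))
        return out

    def test_row_count_and_columns(self):
        report = evaluate_methods(self._pairs(),
                                  {"identity": lambda c: c,
                                   "blurless": lambda c: c * 0.9})
        assert set(report.rows) == {"captured", "identity", "blurless"}
        for row in report.rows.values():
            assert row["n"] == 3 and row["psnr_std"] >= 0.0

    def test_perfect_method_scores_one(self):
        pairs = self._pairs()
        targets = iter([t for t, _ in pairs] * 2)
        report = evaluate_methods(pairs, {"oracle": lambda c: next(targets)})
        assert report.rows["oracle"]["ssim_mean"] == 1.0
        assert report.rows["oracle"]["ssim_std"] == 0.0
        # zero-MSE pairs are excluded from PSNR with a logged count
        assert report.rows["oracle"]["psnr_excluded"] == 3
        assert math.isnan(report.rows["oracle"]["psnr_mean"])

    def test_means_bounded_by_per_pair_extremes(self):
        report = evaluate_methods(self._pairs(4), {"id": lambda c: c})
        for name, per in report.per_pair.items():
            for metric in ("ssim", "fsim"):
                lo, hi = min(per[metric]), max(per[metric])
                assert lo <= report.rows[name][f"{metric}_mean"] <= hi

    def test_bad_method_shape_named(self):
        with pytest.raises(EvaluationError, match="cropper"):
            evaluate_methods(self._pairs(),
                             {"cropper": lambda c: c[:-1]})

    def test_empty_pairs(self):
        with pytest.raises(DomainError):
            evaluate_methods([], {})

    def test_report_writers(self, tmp_path):
        report = evaluate_methods(self._pairs(), {"id": lambda c: c})
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        header = (tmp_path / "r.csv").read_text().splitlines()[0]
        assert header.split(",") == list(MetricsReport.COLUMNS)
        import json
        rows = json.loads((tmp_path / "r.json").read_text())
        assert rows.keys() == report.rows.keys()


class TestProfilesAndFailures:
    def test_profile_values_and_length(self):
        img = np.tile(np.linspace(0, 1, 32), (8, 1))
        prof = intensity_profile(img, 3)
        assert prof.shape == (32,)
        np.testing.assert_array_equal(prof, img[3])
        np.testing.assert_array_equal(intensity_profile(np.full((4, 7), 0.3), 2),
                                      np.full(7, 0.3))

    def test_profile_row_out_of_range(self):
        with pytest.raises(DomainError):
            intensity_profile(np.zeros((8, 8)), 8)

    def test_profile_plot_written(self, tmp_path):
        a = np.random.default_rng(0).random((32, 32))
        plot_profiles(a, a, 16, tmp_path / "p.png")
        assert (tmp_path / "p.png").stat().st_size > 0

    def test_failure_rate(self):
        assert failure_rate([1.0, 1.0, 1.0], 0.5) == (0, 0.0)
        count, frac = failure_rate([0.2, 0.9, 0.95], 0.5)
        assert count == 1 and abs(frac - 1 / 3) < 1e-12
        with pytest.raises(DomainError):
            failure_rate([], 0.5)
        with pytest.raises(DomainError):
            failure_rate([0.5], 1.5)

    def test_metric_params_validation(self):
        with pytest.raises(DomainError):
            MetricParams(ssim_window=10)
        with pytest.raises(DomainError):
            MetricParams(fsim_t2=0.0)
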