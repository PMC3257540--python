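"""Image-analysis chain: bleach correction, ΔF/F, band-pass, t-test."""
import math

import numpy as np
import pytest
from scipy import stats

from sphmap import (AnalysisWindows, DifferentialImage, FilterParams, ImageStack,
                    ResponseMap, StimulusSpec, average_trials, bandpass_filter,
                    bleach_correct, differential_image, make_overlay, pixel_ttest)

BLANK = StimulusSpec.blank()
ELEC = StimulusSpec.electrical()


def stack_from(frames, onset=10, rate=5.0, stimulus=ELEC):
    return ImageStack(np.asarray(frames, dtype=float), frame_rate_hz=rate,
                      mm_per_px=0.02, stimulus_onset_frame=onset, stimulus=stimulus)


class TestBleachCorrect:
    def test_self_subtraction_yields_grand_mean(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(50, 150, size=(20, 8, 10))
        stim = stack_from(frames)
        blank = stack_from(frames, stimulus=BLANK)
        out = bleach_correct(stim, [blank])
        np.testing.assert_allclose(out.frames, frames.mean(), rtol=1e-12)

    def test_decay_cancellation_preserves_blob(self):
        t = np.arange(20) / 5.0
        decay = np.exp(-t / 10.0)
        f0 = np.full((8, 10), 80.0)
        blank_frames = f0[None] * decay[:, None, None]
        blob = np.zeros((8, 10))
        blob[4, 5] = 0.2
        stim_frames = blank_frames * (1.0 + blob[None] * (t >= 2.5)[:, None, None])
        out = bleach_correct(stack_from(stim_frames), [stack_from(blank_frames, stimulus=BLANK)])
        grand = blank_frames.mean()
        # baseline (pre-onset) flat in time at the blank grand mean
        np.testing.assert_allclose(out.frames[:10], grand, rtol=1e-12)
        # evoked blob survives on top of the flat offset
        resp = out.frames[15, 4, 5] - grand
        assert resp == pytest.approx(80.0 * decay[15] * 0.2, rel=1e-12)

    def test_requires_blank_trials(self):
        stim = stack_from(np.full((20, 8, 10), 100.0))
        with pytest.raises(ValueError, match="blank"):
            bleach_correct(stim, [])

    def test_shape_mismatch_rejected(self):
        stim = stack_from(np.full((20, 8, 10), 100.0))
        blank = stack_from(np.full((20, 8, 12), 100.0), stimulus=BLANK)
        with pytest.raises(ValueError, match="shape"):
            bleach_correct(stim, [blank])


class TestDifferentialImage:
    def test_constant_stack_gives_zero(self, flat_stack):
        d = differential_image(flat_stack(), AnalysisWindows.electrical())
        np.testing.assert_array_equal(d.dff, 0.0)

    def test_ten_percent_step(self, flat_stack):
        d = differential_image(flat_stack(base=100.0, step=0.10),
                               AnalysisWindows.electrical())
        np.testing.assert_allclose(d.dff, 0.10, rtol=1e-12)

    def test_doubling_gives_one(self, flat_stack):
        d = differential_image(flat_stack(step=1.0), AnalysisWindows.electrical())
        np.testing.assert_allclose(d.dff, 1.0, rtol=1e-12)

    def test_scale_invariance(self, flat_stack):
        s = flat_stack(step=0.3)
        d1 = differential_image(s, AnalysisWindows.electrical())
        d2 = differential_image(s.with_frames(s.frames * 7.5), AnalysisWindows.electrical())
        np.testing.assert_allclose(d1.dff, d2.dff, rtol=1e-12)

    def test_empty_window_rejected(self, flat_stack):
        s = flat_stack(n_frames=12, onset=10)
        with pytest.raises(ValueError):
            differential_image(s, AnalysisWindows(0.5, 1.5, 2.0))

    def test_window_frame_rounding(self):
        # floor for starts, ceil for ends, half-open
        w = AnalysisWindows(0.5, 1.5, 2.0)
        base, stim = w.frame_windows(5.0, 10, 25)
        assert (base.start, base.stop) == (0, 10)
        assert (stim.start, stim.stop) == (12, 18)


class TestBandpassFilter:
    MMPP = 0.02

    def test_constant_image_rejected_to_zero(self):
        out = bandpass_filter(np.full((64, 64), 37.0), FilterParams(), self.MMPP)
        assert np.abs(out).max() < 37.0 * 1e-10

    @pytest.mark.parametrize("cycles", [4, 16, 40])
    def test_sinusoid_attenuated_by_transfer_function(self, cycles):
        n = 128
        params = FilterParams()
        x = np.arange(n)
        img = np.sin(2 * np.pi * cycles * x / n)[None, :].repeat(n, axis=0)
        f0 = cycles / (n * self.MMPP)  # cycles/mm
        out = bandpass_filter(img, params, self.MMPP)
        expected = params.transfer(np.array([f0]))[0]
        assert out.max() == pytest.approx(expected * img.max(), rel=0.01)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((64, 64))
        out = bandpass_filter(img, FilterParams(), self.MMPP)
        assert out.var() < img.var()

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 50))
        y = rng.standard_normal((40, 50))
        p = FilterParams()
        lhs = bandpass_filter(2.5 * x - 1.5 * y, p, self.MMPP)
        rhs = 2.5 * bandpass_filter(x, p, self.MMPP) - 1.5 * bandpass_filter(y, p, self.MMPP)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_non_finite_rejected(self):
        img = np.zeros((8, 8))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            bandpass_filter(img, FilterParams(), self.MMPP)

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(sigma_hi_per_mm=0.1, sigma_lo_per_mm=50.0)


class TestAverageTrials:
    def test_single_image_identity(self):
        d = DifferentialImage(np.arange(12.0).reshape(3, 4))
        out = average_trials([d])
        np.testing.assert_array_equal(out.dff, d.dff)
        assert out.n_trials == 1

    def test_opposite_images_cancel(self):
        a = DifferentialImage(np.ones((3, 4)))
        b = DifferentialImage(-np.ones((3, 4)))
        np.testing.assert_array_equal(average_trials([a, b]).dff, 0.0)

    def test_noisy_copies_converge_to_template(self):
        rng = np.random.default_rng(3)
        template = np.zeros((20, 20))
        template[10, 10] = 1.0
        sd = 0.2
        imgs = [DifferentialImage(template + rng.normal(0, sd, template.shape))
                for _ in range(10)]
        mean = average_trials(imgs).dff
        se = sd / math.sqrt(10)
        assert np.all(np.abs(mean - template) < 5 * se)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_trials([DifferentialImage(np.ones((3, 4))),
                            DifferentialImage(np.ones((4, 4)))])


def brute_force_pooled_t(x, y):
    """Textbook pooled-variance two-sample t, scalar arithmetic only."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    s1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestPixelTtest:
    def _groups(self, seed=0, shift=0.0, n=10, shape=(6, 8)):
        rng = np.random.default_rng(seed)
        a = [DifferentialImage(rng.normal(shift, 1, shape)) for _ in range(n)]
        b = [DifferentialImage(rng.normal(0, 1, shape)) for _ in range(n)]
        return a, b

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        imgs = [DifferentialImage(rng.normal(0, 1, (6, 8))) for _ in range(10)]
        rmap = pixel_ttest(imgs, [DifferentialImage(d.dff.copy()) for d in imgs])
        assert rmap.sig_mask.sum() == 0
        np.testing.assert_array_equal(rmap.t_stat, 0.0)

    def test_matches_brute_force_on_random_pixels(self):
        a, b = self._groups(seed=5, shift=0.7)
        rmap = pixel_ttest(a, b)
        A = np.stack([d.dff for d in a])
        B = np.stack([d.dff for d in b])
        rng = np.random.default_rng(6)
        for _ in range(50):
            i = rng.integers(0, A.shape[1])
            j = rng.integers(0, A.shape[2])
            expected = brute_force_pooled_t(list(A[:, i, j]), list(B[:, i, j]))
            assert rmap.t_stat[i, j] == pytest.approx(expected, rel=1e-10)

    def test_matches_reference_implementation(self):
        a, b = self._groups(seed=7, shift=0.3)
        rmap = pixel_ttest(a, b)
        A = np.stack([d.dff for d in a])
        B = np.stack([d.dff for d in b])
        ref_t, ref_p = stats.ttest_ind(A, B, axis=0, equal_var=True)
        np.testing.assert_allclose(rmap.t_stat, ref_t, rtol=1e-10)
        np.testing.assert_allclose(rmap.p_value, ref_p, rtol=1e-10)

    def test_welch_matches_reference(self):
        a, b = self._groups(seed=11, shift=0.3)
        rmap = pixel_ttest(a, b, equal_var=False)
        A = np.stack([d.dff for d in a])
        B = np.stack([d.dff for d in b])
        ref_t, ref_p = stats.ttest_ind(A, B, axis=0, equal_var=False)
        np.testing.assert_allclose(rmap.t_stat, ref_t, rtol=1e-10)
        np.testing.assert_allclose(rmap.p_value, ref_p, rtol=1e-8)

    def test_group_swap_negates_t_keeps_p(self):
        a, b = self._groups(seed=8, shift=0.5)
        r1 = pixel_ttest(a, b)
        r2 = pixel_ttest(b, a)
        np.testing.assert_allclose(r1.t_stat, -r2.t_stat, rtol=1e-12)
        np.testing.assert_allclose(r1.p_value, r2.p_value, rtol=1e-12)

    def test_degenerate_pixels(self):
        const = [DifferentialImage(np.full((2, 2), 1.0)) for _ in range(3)]
        shifted = [DifferentialImage(np.full((2, 2), 2.0)) for _ in range(3)]
        same = pixel_ttest(const, [DifferentialImage(d.dff.copy()) for d in const])
        np.testing.assert_array_equal(same.p_value, 1.0)
        diff = pixel_ttest(shifted, const)
        np.testing.assert_array_equal(diff.p_value, 0.0)
        assert np.all(np.isinf(diff.t_stat) & (diff.t_stat > 0))

    def test_small_groups_rejected(self):
        d = DifferentialImage(np.ones((2, 2)))
        with pytest.raises(ValueError):
            pixel_ttest([d], [d, d])

    def test_multiple_testing_correction_is_conservative(self):
        a, b = self._groups(seed=12, shift=0.2, shape=(10, 12))
        raw = pixel_ttest(a, b)
        bonf = pixel_ttest(a, b, correction="bonferroni")
        fdr = pixel_ttest(a, b, correction="fdr_bh")
        assert bonf.sig_mask.sum() <= fdr.sig_mask.sum() <= raw.sig_mask.sum()
        np.testing.assert_allclose(
            bonf.p_value, np.clip(raw.p_value * raw.p_value.size, 0, 1))
        with pytest.raises(ValueError):
            pixel_ttest(a, b, correction="holm")


class TestResponseMapAndOverlay:
    def _rmap(self, p, mean=None, alpha=0.01):
        p = np.asarray(p, dtype=float)
        mean = np.zeros_like(p) if mean is None else np.asarray(mean, dtype=float)
        return ResponseMap(mean_dff=mean, t_stat=np.zeros_like(p), p_value=p,
                           sig_mask=p < alpha, alpha=alpha,
                           n_stim_trials=10, n_blank_trials=10)

    def test_mask_consistency_enforced(self):
        p = np.full((4, 4), 0.5)
        with pytest.raises(ValueError):
            ResponseMap(mean_dff=np.zeros((4, 4)), t_stat=np.zeros((4, 4)),
                        p_value=p, sig_mask=np.ones((4, 4), dtype=bool),
                        alpha=0.01, n_stim_trials=10, n_blank_trials=10)

    def test_empty_mask_returns_grayscale(self):
        rng = np.random.default_rng(9)
        anatomy = rng.uniform(0, 255, (5, 6))
        rgb = make_overlay(self._rmap(np.full((5, 6), 0.5)), anatomy)
        gray = (anatomy - anatomy.min()) / (anatomy.max() - anatomy.min())
        for c in range(3):
            np.testing.assert_allclose(rgb[:, :, c], gray)

    def test_single_significant_pixel_colorized(self):
        p = np.full((5, 6), 0.5)
        p[2, 3] = 1e-6
        mean = np.zeros((5, 6))
        mean[2, 3] = 0.05
        rgb = make_overlay(self._rmap(p, mean), np.zeros((5, 6)))
        colored = np.abs(rgb - rgb[0, 0]).sum(axis=2) > 0
        assert colored.sum() == 1 and colored[2, 3]

    def test_full_mask_all_colorized(self):
        p = np.full((4, 4), 1e-6)
        mean = np.full((4, 4), 0.05)
        rgb = make_overlay(self._rmap(p, mean), np.zeros((4, 4)))
        # red channel saturated everywhere under the yellow-to-red map
        assert np.all(rgb[:, :, 0] == 1.0)
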