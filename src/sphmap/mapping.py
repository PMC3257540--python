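"""From raw trial stacks to significance-masked response maps.

The chain mirrors the standard widefield ΔF/F protocol for presynaptic
fluorescence reporters:

1. bleach correction — subtract the frame-wise mean of the blank (no
   stimulus) trials, restoring the blank grand mean as an offset so the
   baseline stays positive for the subsequent ratio;
2. differential image — temporal average over the stimulus window divided
   by the 2-s pre-stimulus temporal average, minus one (ΔF/F);
3. spatial band-pass — frequency-domain Gaussian filter removing slow
   global fluctuation (high-pass, σ_lo) and shot noise (low-pass, σ_hi);
4. trial averaging;
5. pixel-wise two-sample t-test of stimulus-trial ΔF/F against blank-trial
   ΔF/F, giving a significance mask at the chosen alpha.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .stacks import ImageStack


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AnalysisWindows:
    """Temporal analysis windows, in seconds relative to stimulus onset.

    ``stim_start_s``/``stim_end_s`` bound the half-open response window
    [start, end) after onset; ``baseline_s`` is the duration of the
    pre-stimulus baseline, which always ends at onset.  Conversion to
    frames uses floor for window starts and ceil for window ends, so the
    frame windows are half-open and deterministic.
    """

    stim_start_s: float = 0.5
    stim_end_s: float = 1.5
    baseline_s: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.stim_start_s < self.stim_end_s):
            raise ValueError("need 0 <= stim_start_s < stim_end_s")
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be positive")

    @classmethod
    def electrical(cls) -> "AnalysisWindows":
        """Response window 0.5–1.5 s after onset."""
        return cls(0.5, 1.5, 2.0)

    @classmethod
    def odour(cls) -> "AnalysisWindows":
        """Response window 0.5–2.0 s after onset."""
        return cls(0.5, 2.0, 2.0)

    def frame_windows(self, frame_rate_hz: float, onset_frame: int,
                      n_frames: int) -> tuple[slice, slice]:
        """(baseline, stimulus) frame slices for a given acquisition."""
        n_base = math.floor(self.baseline_s * frame_rate_hz)
        s0 = onset_frame + math.floor(self.stim_start_s * frame_rate_hz)
        s1 = onset_frame + math.ceil(self.stim_end_s * frame_rate_hz)
        if n_base < 1 or s1 <= s0:
            raise ValueError("analysis window empty after rounding to frames")
        if onset_frame - n_base < 0 or s1 > n_frames:
            raise ValueError("analysis windows fall outside the stack")
        return slice(onset_frame - n_base, onset_frame), slice(s0, s1)


@dataclass(frozen=True)
class FilterParams:
    """Gaussian band-pass cutoffs as frequency-domain standard deviations.

    Units are cycles/mm.  ``sigma_hi_per_mm`` is the low-pass (shot noise)
    cutoff, ``sigma_lo_per_mm`` the high-pass (global fluctuation) cutoff.
    The transfer function is the product
    ``H(f) = exp(-f^2 / (2 σ_hi^2)) * (1 - exp(-f^2 / (2 σ_lo^2)))``
    with f the radial spatial frequency, so H ∈ [0, 1] and H(0) = 0.
    """

    sigma_hi_per_mm: float = 50.0
    sigma_lo_per_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.sigma_lo_per_mm < self.sigma_hi_per_mm):
            raise ValueError("need 0 < sigma_lo < sigma_hi")

    def transfer(self, f_per_mm: np.ndarray) -> np.ndarray:
        f2 = np.asarray(f_per_mm, dtype=np.float64) ** 2
        lo = np.exp(-f2 / (2.0 * self.sigma_hi_per_mm ** 2))
        hi = 1.0 - np.exp(-f2 / (2.0 * self.sigma_lo_per_mm ** 2))
        return lo * hi


@dataclass
class DifferentialImage:
    """Single-trial (or averaged) ΔF/F image."""

    dff: np.ndarray
    windows: Optional[AnalysisWindows] = None
    trial_id: str = ""
    filtered: bool = False
    n_trials: int = 1
    invalid_mask: Optional[np.ndarray] = None  # pixels with baseline <= 0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=np.float64)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D")


@dataclass
class ResponseMap:
    """Pixel-wise response statistics for one condition versus blank."""

    mean_dff: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    n_stim_trials: int
    n_blank_trials: int

    def __post_init__(self) -> None:
        if np.any(self.p_value < 0) or np.any(self.p_value > 1):
            raise ValueError("p-values outside [0, 1]")
        if not np.array_equal(self.sig_mask, self.p_value < self.alpha):
            raise ValueError("sig_mask inconsistent with p_value < alpha")

    @property
    def sig_fraction(self) -> float:
        return float(self.sig_mask.mean())


# ---------------------------------------------------------------------------
# operations


def _check_aligned(a: ImageStack, b: ImageStack) -> None:
    if a.shape != b.shape:
        raise ValueError("stacks differ in shape")
    if a.frame_rate_hz != b.frame_rate_hz or a.stimulus_onset_frame != b.stimulus_onset_frame:
        raise ValueError("stacks differ in frame rate or onset frame")


def bleach_correct(stim_stack: ImageStack, blank_stacks: Sequence[ImageStack]) -> ImageStack:
    """Remove photobleaching using the blank (no-stimulus) trials.

    Subtracts the frame-wise mean across blank trials, then adds back the
    blank grand mean (a scalar) so the corrected baseline remains positive
    and the subsequent ratio is well defined.  With a shared exponential
    decay this flattens the baseline exactly while leaving evoked
    modulation in place.
    """
    if len(blank_stacks) == 0:
        raise ValueError("at least one blank stack is required")
    for b in blank_stacks:
        _check_aligned(stim_stack, b)
    blank_mean = np.mean([b.frames for b in blank_stacks], axis=0)
    grand_mean = float(blank_mean.mean())
    corrected = stim_stack.frames - blank_mean + grand_mean
    return stim_stack.with_frames(np.maximum(corrected, 0.0))


def differential_image(stack: ImageStack, windows: AnalysisWindows) -> DifferentialImage:
    """Windowed ΔF/F: stimulus-window mean over baseline mean, minus one.

    Pixels whose baseline mean is non-positive are set to 0 and flagged in
    ``invalid_mask``.
    """
    base_sl, stim_sl = windows.frame_windows(
        stack.frame_rate_hz, stack.stimulus_onset_frame, stack.n_frames)
    base = stack.frames[base_sl].mean(axis=0)
    stim = stack.frames[stim_sl].mean(axis=0)
    invalid = base <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(invalid, 0.0, stim / np.where(invalid, 1.0, base) - 1.0)
    return DifferentialImage(dff, windows=windows, trial_id=stack.trial_id,
                             invalid_mask=invalid)


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def bandpass_filter(dff: DifferentialImage | np.ndarray, params: FilterParams,
                    mm_per_px: float) -> DifferentialImage | np.ndarray:
    """Frequency-domain Gaussian band-pass of a ΔF/F image.

    The image is mean-padded to the next power of two in each dimension to
    suppress wrap-around artefacts, multiplied in the Fourier domain by the
    band-pass transfer function (cycles/mm), inverse-transformed and
    cropped back.  The DC component is removed, so the output mean is ≈ 0.
    Accepts and returns either a bare array or a :class:`DifferentialImage`.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    arr = dff.dff if isinstance(dff, DifferentialImage) else np.asarray(dff, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains NaN or Inf")
    h0, w0 = arr.shape
    h2, w2 = _next_pow2(h0), _next_pow2(w0)
    padded = np.full((h2, w2), arr.mean(), dtype=np.float64)
    padded[:h0, :w0] = arr
    fy = np.fft.fftfreq(h2, d=mm_per_px)
    fx = np.fft.rfftfreq(w2, d=mm_per_px)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    spec = np.fft.rfft2(padded) * params.transfer(f)
    out = np.fft.irfft2(spec, s=(h2, w2))[:h0, :w0]
    if isinstance(dff, DifferentialImage):
        return replace(dff, dff=out, filtered=True)
    return out


def average_trials(dffs: Sequence[DifferentialImage]) -> DifferentialImage:
    """Pixel-wise arithmetic mean of per-trial ΔF/F images; records n."""
    if len(dffs) == 0:
        raise ValueError("need at least one image")
    shapes = {d.dff.shape for d in dffs}
    if len(shapes) != 1:
        raise ValueError("images differ in shape")
    mean = np.mean([d.dff for d in dffs], axis=0)
    return DifferentialImage(mean, windows=dffs[0].windows,
                             trial_id="mean", filtered=dffs[0].filtered,
                             n_trials=len(dffs))


def pixel_ttest(stim_dffs: Sequence[DifferentialImage],
                blank_dffs: Sequence[DifferentialImage],
                alpha: float = 0.01,
                equal_var: bool = True,
                correction: Optional[str] = None) -> ResponseMap:
    """Per-pixel two-sample two-tailed t-test, stimulus versus blank trials.

    Pooled-variance (Student) t by default, matching a balanced design of
    equal trial counts; ``equal_var=False`` switches to Welch.  Pixels where
    both groups have zero variance and equal means get p = 1 (t = 0); zero
    variance with unequal means gives p = 0.  No multiple-testing
    correction is applied by default (the map is a per-pixel error-rate
    statement); ``correction`` may be 'bonferroni' or 'fdr_bh' to adjust
    the p-values before thresholding.
    """
    if len(stim_dffs) < 2 or len(blank_dffs) < 2:
        raise ValueError("each group needs at least 2 trials")
    a = np.stack([d.dff for d in stim_dffs])
    b = np.stack([d.dff for d in blank_dffs])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups differ in image shape")
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    diff = m1 - m2
    if equal_var:
        df = np.float64(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se1, se2 = v1 / n1, v2 / n2
        denom = np.sqrt(se1 + se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (se1 + se2) ** 2 / (se1 ** 2 / (n1 - 1) + se2 ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        zero = denom == 0
        t = np.where(zero & (diff == 0), 0.0, t)
        t = np.where(zero & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    if correction == "bonferroni":
        p = np.clip(p * p.size, 0.0, 1.0)
    elif correction == "fdr_bh":
        p = stats.false_discovery_control(p.ravel(), method="bh").reshape(p.shape)
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction}")
    return ResponseMap(mean_dff=m1, t_stat=t, p_value=p, sig_mask=p < alpha,
                       alpha=alpha, n_stim_trials=n1, n_blank_trials=n2)


def make_overlay(rmap: ResponseMap, anatomy: np.ndarray) -> np.ndarray:
    """Overlay significant pixels on a grayscale anatomical image.

    The anatomy (e.g. the blood-vessel image) is rendered in grayscale;
    significant pixels are colourised yellow-to-red by |mean ΔF/F|
    magnitude.  Returns an RGB float array in [0, 1].
    """
    import matplotlib

    anatomy = np.asarray(anatomy, dtype=np.float64)
    if anatomy.shape != rmap.sig_mask.shape:
        raise ValueError("anatomy shape does not match the response map")
    lo, hi = anatomy.min(), anatomy.max()
    gray = (anatomy - lo) / (hi - lo) if hi > lo else np.zeros_like(anatomy)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    mask = rmap.sig_mask
    if mask.any():
        mag = np.abs(rmap.mean_dff[mask])
        top = mag.max()
        norm = mag / top if top > 0 else np.zeros_like(mag)
        # autumn runs red->yellow; reverse so increasing magnitude runs yellow->red
        colors = matplotlib.colormaps["autumn"](1.0 - norm)[:, :3]
        rgb[mask] = colors
    return rgb


def map_condition(stim_stacks: Sequence[ImageStack],
                  blank_stacks: Sequence[ImageStack],
                  windows: Optional[AnalysisWindows] = None,
                  filter_params: Optional[FilterParams] = None,
                  alpha: float = 0.01,
                  equal_var: bool = True,
                  ) -> tuple[ResponseMap, list[DifferentialImage], list[DifferentialImage]]:
    """Full chain for one condition: correct, ratio, filter, t-test.

    Bleach correction and filtering are applied identically to the stimulus
    and the blank trials, so the null distribution of the test statistic is
    the same in both groups.  Returns the response map plus the filtered
    per-trial ΔF/F images of each group.
    """
    if len(stim_stacks) == 0:
        raise ValueError("no stimulus trials supplied")
    windows = windows or AnalysisWindows.electrical()
    filter_params = filter_params or FilterParams()
    mm_per_px = stim_stacks[0].mm_per_px

    def process(stack: ImageStack) -> DifferentialImage:
        corrected = bleach_correct(stack, blank_stacks)
        d = differential_image(corrected, windows)
        return bandpass_filter(d, filter_params, mm_per_px)

    stim_dffs = [process(s) for s in stim_stacks]
    blank_dffs = [process(b) for b in blank_stacks]
    rmap = pixel_ttest(stim_dffs, blank_dffs, alpha=alpha, equal_var=equal_var)
    return rmap, stim_dffs, blank_dffs
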