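"""Synthetic trial stacks and aligned sequence pairs with known ground truth.

The imaging generator emulates the statistical structure the mapping chain
assumes: a spatially smooth baseline fluorescence field shared by all
trials of an experiment (the "preparation"), multiplicative exponential
photobleaching, a slow low-spatial-frequency multiplicative global
fluctuation, additive Gaussian shot noise, and — on stimulus trials —
a respiration-locked evoked response that is a spatial Gaussian blob
entering multiplicatively on the bleached baseline, with amplitude a
saturating monotone function of stimulus strength.  Blank trials carry
everything except the evoked term.

The sequence generator emits gap-free pairwise alignments with a uniform
background match probability, planted high-identity blocks, and consensus
motif instances written with an exact mismatch count, for recovery tests
of the conservation/motif scan.

All generators are bit-deterministic under a fixed seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .enhancer import TBOX_MOTIF, AlignmentPair
from .stacks import ImageStack
from .stimuli import StimulusSpec


@dataclass(frozen=True)
class Blob:
    """One evoked response focus: an isotropic spatial Gaussian."""

    center: tuple[float, float]  # (row, col) in px
    sigma_px: float
    peak_dff: float

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be non-negative")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic imaging experiment.

    Spatial/temporal defaults follow the acquisition geometry of the real
    recordings (336×256 px at 5 Hz); tests typically shrink the field.
    Temporal parameters are converted to whole frames by flooring.
    ``blobs`` maps a condition label (``StimulusSpec.label``) to the evoked
    foci active under that condition.
    """

    height_px: int = 256
    width_px: int = 336
    frame_rate_hz: float = 5.0
    mm_per_px: float = 0.02
    n_frames: int = 30
    stimulus_onset_s: float = 2.0
    n_trials_per_condition: int = 10
    baseline_f0: float = 100.0
    f0_heterogeneity: float = 0.1
    f0_sigma_mm: float = 0.5
    bleach_tau_s: float = 20.0
    shot_noise_sd: float = 1.0
    global_fluct_amplitude: float = 0.02
    global_fluct_spatial_sigma_mm: float = 3.0
    global_fluct_spatial_contrast: float = 0.0
    global_fluct_tau_s: float = 2.0
    response_latency_s: float = 0.5
    response_duration_s: float = 1.0
    blobs: Mapping[str, Sequence[Blob]] = field(default_factory=dict)
    gain_halfsat_pulses: float = 3.0
    gain_halfsat_ua: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.n_frames <= 0:
            raise ValueError("image dimensions and frame count must be positive")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if self.shot_noise_sd < 0 or self.global_fluct_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not (0 <= self.stimulus_onset_s < self.n_frames / self.frame_rate_hz):
            raise ValueError("stimulus onset outside the acquisition")

    # -- frame arithmetic (floor rounding throughout) --

    @property
    def onset_frame(self) -> int:
        return math.floor(self.stimulus_onset_s * self.frame_rate_hz)

    @property
    def latency_frames(self) -> int:
        return math.floor(self.response_latency_s * self.frame_rate_hz)

    @property
    def duration_frames(self) -> int:
        return math.floor(self.response_duration_s * self.frame_rate_hz)

    # -- deterministic per-preparation fields --

    def f0_field(self) -> np.ndarray:
        """Smooth baseline fluorescence field, fixed by ``rng_seed``.

        The field is shared by every trial of an experiment, as the real
        anatomy is; only noise and the global fluctuation vary per trial.
        """
        rng = np.random.default_rng(self.rng_seed)
        base = np.full((self.height_px, self.width_px), self.baseline_f0)
        if self.f0_heterogeneity > 0:
            smooth = _smooth_unit_field(rng, (self.height_px, self.width_px),
                                        self.f0_sigma_mm / self.mm_per_px)
            base = base * np.clip(1.0 + self.f0_heterogeneity * smooth, 0.1, None)
        return base

    def fluct_field(self) -> np.ndarray:
        """Spatial weighting of the slow global fluctuation.

        Nonspecific fluctuations (excitation intensity, brain-wide
        hemodynamics) modulate the whole imaged field; by default the
        weighting is uniform (all ones).  A nonzero
        ``global_fluct_spatial_contrast`` adds a fixed anatomical
        large-scale pattern (correlation length
        ``global_fluct_spatial_sigma_mm``) shared by all trials of a
        preparation; only the temporal modulation varies per trial.
        """
        ones = np.ones((self.height_px, self.width_px))
        if self.global_fluct_spatial_contrast == 0:
            return ones
        rng = np.random.default_rng(np.random.SeedSequence([self.rng_seed, 1]))
        structure = _smooth_unit_field(rng, (self.height_px, self.width_px),
                                       self.global_fluct_spatial_sigma_mm / self.mm_per_px)
        return ones + self.global_fluct_spatial_contrast * structure

    def amplitude_gain(self, stimulus: StimulusSpec) -> float:
        """Saturating monotone gain mapping stimulus strength to peak ΔF/F.

        Normalised so the default electrical stimulus (100 uA, 5 pulses)
        and the default odourant dilution have gain 1; a blob's
        ``peak_dff`` is therefore the peak at the reference stimulus.
        """
        if stimulus.is_blank:
            return 0.0

        def sat(x: float, k: float) -> float:
            return x / (x + k)

        if stimulus.kind == "electrical":
            gp = sat(stimulus.n_pulses, self.gain_halfsat_pulses) / sat(5, self.gain_halfsat_pulses)
            gc = sat(stimulus.current_ua, self.gain_halfsat_ua) / sat(100.0, self.gain_halfsat_ua)
            return gp * gc
        return sat(stimulus.dilution, 0.05) / sat(0.10, 0.05)

    def condition_blobs(self, stimulus: StimulusSpec) -> Sequence[Blob]:
        """Blobs active for a stimulus: by label, else the '*' wildcard entry."""
        if stimulus.is_blank:
            return ()
        if stimulus.label in self.blobs:
            return self.blobs[stimulus.label]
        return self.blobs.get("*", ())

    def spatial_response(self, stimulus: StimulusSpec) -> np.ndarray:
        """Noiseless peak ΔF/F map for a stimulus (zeros for blank)."""
        out = np.zeros((self.height_px, self.width_px))
        if stimulus.is_blank:
            return out
        gain = self.amplitude_gain(stimulus)
        rows = np.arange(self.height_px)[:, None]
        cols = np.arange(self.width_px)[None, :]
        for blob in self.condition_blobs(stimulus):
            r0, c0 = blob.center
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            out += gain * blob.peak_dff * np.exp(-d2 / (2.0 * blob.sigma_px ** 2))
        return out


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       sigma_px: float) -> np.ndarray:
    """Gaussian-smoothed white noise, centred and scaled to unit SD."""
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px,
                                     mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


@dataclass
class SyntheticTruth:
    """Generator ground truth for parameter-recovery tests."""

    active_masks: dict[str, np.ndarray]        # condition label -> bool mask
    blob_centers: dict[str, list[tuple[float, float]]]
    amplitudes: dict[str, np.ndarray]          # per-trial realized peak gain*dff

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "active_masks": {k: np.flatnonzero(v).tolist() for k, v in self.active_masks.items()},
            "mask_shape": {k: list(v.shape) for k, v in self.active_masks.items()},
            "blob_centers": {k: [list(c) for c in v] for k, v in self.blob_centers.items()},
            "amplitudes": {k: list(map(float, v)) for k, v in self.amplitudes.items()},
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# imaging generator


def generate_trial(config: SyntheticConfig, stimulus: StimulusSpec, seed: int,
                   trial_id: str = "") -> ImageStack:
    """Generate one trial stack.

    frames = F0(x,y) · exp(−t/τ) · (1 + fluct(x,y,t)) · (1 + evoked(x,y,t))
             + Gaussian noise,
    with evoked = 0 on blank trials and before onset + latency.  The same
    config and seed always yield bit-identical output.
    """
    rng = np.random.default_rng(seed)
    f0 = config.f0_field()
    t = np.arange(config.n_frames) / config.frame_rate_hz
    decay = (np.ones_like(t) if math.isinf(config.bleach_tau_s)
             else np.exp(-t / config.bleach_tau_s))
    frames = f0[None, :, :] * decay[:, None, None]

    if config.global_fluct_amplitude > 0:
        # fixed anatomical pattern, per-trial slow Gaussian temporal modulation;
        # the modulation stays a linear map of white noise (no per-trial
        # renormalisation) so trial-to-trial variability is exactly Gaussian
        g = config.fluct_field()
        sigma_t = config.global_fluct_tau_s * config.frame_rate_hz
        m = ndimage.gaussian_filter1d(rng.standard_normal(config.n_frames),
                                      sigma_t, mode="reflect")
        # exact per-frame unit variance from the filter's row weights, so the
        # amplitude parameter is the per-frame SD of the relative fluctuation
        weights = ndimage.gaussian_filter1d(np.eye(config.n_frames), sigma_t,
                                            axis=0, mode="reflect")
        m /= np.sqrt((weights ** 2).sum(axis=0))
        frames = frames * (1.0 + config.global_fluct_amplitude *
                           g[None, :, :] * m[:, None, None])

    if not stimulus.is_blank:
        spatial = config.spatial_response(stimulus)
        if spatial.any():
            start = config.onset_frame + config.latency_frames
            stop = min(start + config.duration_frames, config.n_frames)
            temporal = np.zeros(config.n_frames)
            temporal[start:stop] = 1.0
            frames = frames * (1.0 + spatial[None, :, :] * temporal[:, None, None])

    if config.shot_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.shot_noise_sd, frames.shape)
        frames = np.maximum(frames, 0.0)

    return ImageStack(frames, config.frame_rate_hz, config.mm_per_px,
                      config.onset_frame, stimulus,
                      trial_id=trial_id or f"{stimulus.label}_s{seed}")


def generate_experiment(config: SyntheticConfig, conditions: Sequence[StimulusSpec],
                        seed: int) -> tuple[list[ImageStack], SyntheticTruth]:
    """Generate a full experiment: n trials per condition plus matched blanks.

    Returns ``n_trials_per_condition`` stacks for every condition and the
    same number of blank stacks, together with the ground truth: the
    per-condition active mask (pixels whose noiseless peak ΔF/F reaches
    half the blob peak), blob centers, and per-trial realized amplitudes.
    """
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    if any(c.is_blank for c in conditions):
        raise ValueError("blanks are generated automatically; do not list them")

    rng = np.random.default_rng(seed)
    n = config.n_trials_per_condition
    trial_seeds = rng.integers(0, 2 ** 31 - 1, size=(len(conditions) + 1) * n)

    stacks: list[ImageStack] = []
    active: dict[str, np.ndarray] = {}
    centers: dict[str, list[tuple[float, float]]] = {}
    amps: dict[str, np.ndarray] = {}
    k = 0
    for cond in conditions:
        spatial = config.spatial_response(cond)
        gain = config.amplitude_gain(cond)
        cond_blobs = config.condition_blobs(cond)
        peaks = [gain * b.peak_dff for b in cond_blobs]
        half = 0.5 * max(peaks) if peaks else np.inf
        active[cond.label] = spatial >= half
        centers[cond.label] = [b.center for b in cond_blobs]
        amps[cond.label] = np.full(n, max(peaks) if peaks else 0.0)
        for i in range(n):
            stacks.append(generate_trial(config, cond, int(trial_seeds[k]),
                                         trial_id=f"{cond.label}_trial{i:02d}"))
            k += 1
    blank = StimulusSpec.blank()
    active[blank.label] = np.zeros((config.height_px, config.width_px), dtype=bool)
    centers[blank.label] = []
    amps[blank.label] = np.zeros(n)
    for i in range(n):
        stacks.append(generate_trial(config, blank, int(trial_seeds[k]),
                                     trial_id=f"blank_trial{i:02d}"))
        k += 1
    return stacks, SyntheticTruth(active, centers, amps)


# ---------------------------------------------------------------------------
# sequence generator


_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class AlignmentTruth:
    """Planted structure of a generated alignment (1-based coordinates)."""

    blocks: tuple[tuple[int, int, float], ...]   # (start, width, identity)
    motif_positions: tuple[tuple[int, int], ...]  # (position, n_mismatches)
    background_identity: float


def generate_alignment(length_bp: int, background_identity: float,
                       planted_blocks: Sequence[tuple[int, int, float]] = (),
                       planted_motifs: Sequence[tuple[int, int]] = (),
                       seed: int = 0, motif: str = TBOX_MOTIF,
                       ) -> tuple[AlignmentPair, AlignmentTruth]:
    """Generate a gap-free aligned pair with planted structure.

    Each column matches with the background probability, except inside
    planted ``(start, width, identity)`` blocks (1-based starts,
    non-overlapping).  ``planted_motifs`` are ``(position, n_mismatch)``
    pairs: the consensus motif is written into the reference at the given
    1-based position with exactly that many substitutions.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    if not (0.0 <= background_identity <= 1.0):
        raise ValueError("background_identity must be in [0, 1]")
    blocks = sorted(planted_blocks)
    for i, (start, width, ident) in enumerate(blocks):
        if start < 1 or start + width - 1 > length_bp:
            raise ValueError(f"block {i} out of bounds")
        if not (0.0 <= ident <= 1.0):
            raise ValueError(f"block {i} identity outside [0, 1]")
        if i and start <= blocks[i - 1][0] + blocks[i - 1][1] - 1:
            raise ValueError("planted blocks overlap")
    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=length_bp)

    motif_arr = np.frombuffer(motif.upper().encode(), dtype="S1")
    m = len(motif_arr)
    truth_motifs = []
    for pos, n_mm in planted_motifs:
        if pos < 1 or pos + m - 1 > length_bp:
            raise ValueError("planted motif out of bounds")
        if not (0 <= n_mm <= m):
            raise ValueError("mismatch count outside motif length")
        inst = motif_arr.copy()
        for j in rng.choice(m, size=n_mm, replace=False):
            others = _BASES[_BASES != inst[j]]
            inst[j] = rng.choice(others)
        ref[pos - 1:pos - 1 + m] = inst
        truth_motifs.append((int(pos), int(n_mm)))

    p_match = np.full(length_bp, background_identity)
    for start, width, ident in blocks:
        p_match[start - 1:start - 1 + width] = ident
    mismatch = rng.random(length_bp) >= p_match
    partner = ref.copy()
    for i in np.nonzero(mismatch)[0]:
        others = _BASES[_BASES != ref[i]]
        partner[i] = rng.choice(others)

    pair = AlignmentPair(ref.tobytes().decode(), partner.tobytes().decode(),
                         ref_name="ref_synth", partner_name="partner_synth")
    truth = AlignmentTruth(tuple((int(s), int(w), float(v)) for s, w, v in blocks),
                           tuple(truth_motifs), background_identity)
    return pair, truth
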