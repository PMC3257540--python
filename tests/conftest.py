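"""Shared fixtures: small synthetic configurations and hand-built stacks."""
import numpy as np
import pytest

from sphmap import ImageStack, StimulusSpec, SyntheticConfig


@pytest.fixture
def small_null_config():
    """Desk-scale null experiment config (no evoked response)."""
    def make(seed: int = 1, **overrides) -> SyntheticConfig:
        kwargs = dict(height_px=64, width_px=84, n_frames=25, rng_seed=seed)
        kwargs.update(overrides)
        return SyntheticConfig(**kwargs)
    return make


@pytest.fixture
def flat_stack():
    """Stack with a constant baseline and an optional multiplicative step."""
    def make(base=100.0, step=0.0, n_frames=20, onset=10, shape=(8, 10),
             rate=5.0, stimulus=None) -> ImageStack:
        frames = np.full((n_frames, *shape), float(base))
        if step:
            frames[onset:] *= (1.0 + step)
        return ImageStack(frames, frame_rate_hz=rate, mm_per_px=0.02,
                          stimulus_onset_frame=onset,
                          stimulus=stimulus or StimulusSpec.electrical(),
                          trial_id="flat")
    return make
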