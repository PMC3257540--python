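"""Trial image stacks and their on-disk representation.

A stack is one trial's multi-frame fluorescence movie plus the acquisition
metadata the analysis needs: frame rate, spatial scale, the frame at which
the stimulus was applied (acquisition is time-locked to respiration, so the
onset frame is known exactly), and the stimulus itself.

On disk a stack is a multi-frame TIFF next to a JSON sidecar of the same
stem holding the metadata.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .stimuli import StimulusSpec


@dataclass
class ImageStack:
    """One trial: frames of shape (time, height, width) in fluorescence a.u."""

    frames: np.ndarray
    frame_rate_hz: float
    mm_per_px: float
    stimulus_onset_frame: int
    stimulus: StimulusSpec
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frames must be non-negative")
        if self.frame_rate_hz <= 0 or self.mm_per_px <= 0:
            raise ValueError("frame_rate_hz and mm_per_px must be positive")
        if not (0 <= self.stimulus_onset_frame < self.frames.shape[0]):
            raise ValueError("stimulus_onset_frame outside the stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def is_blank(self) -> bool:
        return self.stimulus.is_blank

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame (s), frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """Copy of this stack with new pixel data, metadata preserved."""
        return ImageStack(frames, self.frame_rate_hz, self.mm_per_px,
                          self.stimulus_onset_frame, self.stimulus, self.trial_id)


def save_stack(stack: ImageStack, tiff_path: str | Path) -> Path:
    """Write a stack as multi-frame TIFF plus a ``.json`` metadata sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "mm_per_px": stack.mm_per_px,
        "stimulus_onset_frame": stack.stimulus_onset_frame,
        "stimulus": stack.stimulus.to_dict(),
        "blank": stack.is_blank,
        "trial_id": stack.trial_id,
    }
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return tiff_path


def load_stack(tiff_path: str | Path) -> ImageStack:
    """Read a stack written by :func:`save_stack`."""
    tiff_path = Path(tiff_path)
    sidecar = tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(tiff_path)
    return ImageStack(
        frames=np.asarray(frames, dtype=np.float64),
        frame_rate_hz=meta["frame_rate_hz"],
        mm_per_px=meta["mm_per_px"],
        stimulus_onset_frame=meta["stimulus_onset_frame"],
        stimulus=StimulusSpec.from_dict(meta["stimulus"]),
        trial_id=meta.get("trial_id", tiff_path.stem),
    )
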