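"""Stimulus descriptions for widefield imaging trials.

A trial is driven either by focal electrical microstimulation of an
olfactory-bulb glomerulus, by an odourant delivered to the nostril, or by
nothing at all (a blank / pure-air trial used for bleach correction and as
the null comparison group).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

ELECTRICAL = "electrical"
ODOURANT = "odourant"
BLANK = "blank"


@dataclass(frozen=True)
class StimulusSpec:
    """Description of the stimulus applied on one trial.

    Exactly one kind is populated: ``electrical`` carries current amplitude,
    pulse train frequency, pulse count and pulse width; ``odourant`` carries
    the compound name and its dilution in mineral oil; ``blank`` carries
    nothing.
    """

    kind: str
    current_ua: Optional[float] = None
    frequency_hz: Optional[float] = None
    n_pulses: Optional[int] = None
    pulse_width_ms: Optional[float] = None
    name: Optional[str] = None
    dilution: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in (ELECTRICAL, ODOURANT, BLANK):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        elec = (self.current_ua, self.frequency_hz, self.n_pulses, self.pulse_width_ms)
        odo = (self.name, self.dilution)
        if self.kind == ELECTRICAL:
            if any(v is None for v in elec) or any(v is not None for v in odo):
                raise ValueError("electrical stimulus requires current/frequency/pulses/width only")
            if any(v <= 0 for v in elec):  # type: ignore[operator]
                raise ValueError("electrical stimulus parameters must be positive")
        elif self.kind == ODOURANT:
            if any(v is not None for v in elec) or any(v is None for v in odo):
                raise ValueError("odourant stimulus requires name and dilution only")
            if self.dilution <= 0:  # type: ignore[operator]
                raise ValueError("dilution must be positive")
        else:
            if any(v is not None for v in elec + odo):
                raise ValueError("blank stimulus carries no parameters")

    @classmethod
    def electrical(
        cls,
        current_ua: float = 100.0,
        frequency_hz: float = 60.0,
        n_pulses: int = 5,
        pulse_width_ms: float = 0.2,
    ) -> "StimulusSpec":
        """Electrical microstimulation; defaults 100 uA, 60 Hz, 5 x 0.2 ms pulses."""
        return cls(ELECTRICAL, current_ua=current_ua, frequency_hz=frequency_hz,
                   n_pulses=n_pulses, pulse_width_ms=pulse_width_ms)

    @classmethod
    def odourant(cls, name: str, dilution: float = 0.10) -> "StimulusSpec":
        """Odourant stimulus, e.g. TMT or heptanoic acid at 10% in mineral oil."""
        return cls(ODOURANT, name=name, dilution=dilution)

    @classmethod
    def blank(cls) -> "StimulusSpec":
        return cls(BLANK)

    @property
    def is_blank(self) -> bool:
        return self.kind == BLANK

    @property
    def label(self) -> str:
        """Short condition label used to group trials."""
        if self.kind == ELECTRICAL:
            return f"elec_{self.current_ua:g}uA_{self.n_pulses}p"
        if self.kind == ODOURANT:
            return f"odour_{self.name}_{self.dilution:g}"
        return BLANK

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)
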