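"""Core data model for the lateralization task.

The experiment presents one-octave noise bursts over headphones with an
interaural time difference (ITD), an interaural level difference (ILD),
monaurally to one ear, or diotically (zero ITD and zero ILD).  The listener
reports the perceived intracranial position on a 9-key scale: key 1 = far
left, key 5 = center, key 9 = far right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

#: Physiologically attainable ITDs (microseconds), negative = left-leading.
ITD_PHYSIOLOGICAL = (-600.0, -400.0, -200.0, 200.0, 400.0, 600.0)
#: ITDs outside the physiological range.
ITD_EXTREME = (-1500.0, 1500.0)
#: ILD stimulus set (dB), negative = left ear louder.
ILD_SET = (-12.0, -8.0, -4.0, 4.0, 8.0, 12.0)

#: Cue span over which a unit-gain listener sweeps the full key range.
ITD_SPAN_US = 600.0
ILD_SPAN_DB = 12.0

CUE_TYPES = ("itd", "ild", "mono_left", "mono_right", "diotic")

#: Presentations per stimulus in a complete session.
REPEATS_NONDIOTIC = 6
REPEATS_DIOTIC = 8

KEY_MIN, KEY_CENTER, KEY_MAX = 1, 5, 9

GROUPS = ("control", "patient")
DEFAULT_PHASE_ORDER = ("acute", "subacute", "chronic")


@dataclass(frozen=True)
class StimulusDescriptor:
    """One stimulus of the lateralization design.

    ``cue_value`` carries microseconds for ``itd``, decibels for ``ild``,
    and is ``None`` for monaural and diotic stimuli (the diotic stimulus is
    the shared zero of both cue continua).
    """

    cue_type: str
    cue_value: float | None = None

    def __post_init__(self) -> None:
        if self.cue_type not in CUE_TYPES:
            raise ValueError(f"unknown cue_type {self.cue_type!r}")
        if self.cue_type == "itd":
            if self.cue_value not in ITD_PHYSIOLOGICAL + ITD_EXTREME:
                raise ValueError(f"invalid ITD cue value {self.cue_value!r} µs")
        elif self.cue_type == "ild":
            if self.cue_value not in ILD_SET:
                raise ValueError(f"invalid ILD cue value {self.cue_value!r} dB")
        elif self.cue_value is not None:
            raise ValueError(f"{self.cue_type} stimulus carries no cue value")

    @property
    def key(self) -> tuple[str, float | None]:
        return (self.cue_type, self.cue_value)

    def mirrored(self) -> "StimulusDescriptor":
        """Left-right mirror image of this stimulus."""
        if self.cue_type in ("itd", "ild"):
            return StimulusDescriptor(self.cue_type, -self.cue_value)
        if self.cue_type == "mono_left":
            return StimulusDescriptor("mono_right")
        if self.cue_type == "mono_right":
            return StimulusDescriptor("mono_left")
        return self


@dataclass(frozen=True)
class Trial:
    stimulus: StimulusDescriptor
    presentation_index: int  # 1-based, per stimulus
    response_key: int

    def __post_init__(self) -> None:
        if not (KEY_MIN <= self.response_key <= KEY_MAX):
            raise ValueError(
                f"response_key {self.response_key} outside {KEY_MIN}..{KEY_MAX}"
            )
        if self.presentation_index < 1:
            raise ValueError("presentation_index is 1-based")


def full_design() -> list[tuple[StimulusDescriptor, int]]:
    """All stimuli of a complete session with their repetition counts."""
    design: list[tuple[StimulusDescriptor, int]] = []
    for v in ITD_PHYSIOLOGICAL + ITD_EXTREME:
        design.append((StimulusDescriptor("itd", v), REPEATS_NONDIOTIC))
    for v in ILD_SET:
        design.append((StimulusDescriptor("ild", v), REPEATS_NONDIOTIC))
    design.append((StimulusDescriptor("mono_left"), REPEATS_NONDIOTIC))
    design.append((StimulusDescriptor("mono_right"), REPEATS_NONDIOTIC))
    design.append((StimulusDescriptor("diotic"), REPEATS_DIOTIC))
    return design


@dataclass
class LateralizationSession:
    """All lateralization trials of one participant in one phase."""

    participant_id: str
    group: str
    phase: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def stimulus_groups(self) -> dict[tuple[str, float | None], list[Trial]]:
        groups: dict[tuple[str, float | None], list[Trial]] = {}
        for t in self.trials:
            groups.setdefault(t.stimulus.key, []).append(t)
        return groups

    def is_complete(self) -> bool:
        """True when every stimulus has its full presentation count."""
        groups = self.stimulus_groups()
        for stim, n in full_design():
            if len(groups.get(stim.key, [])) != n:
                return False
        return len(self.trials) == sum(n for _, n in full_design())

    def mirrored(self) -> "LateralizationSession":
        """Mirror stimuli and responses about the midline (key 5)."""
        flipped = [
            Trial(
                t.stimulus.mirrored(),
                t.presentation_index,
                KEY_MIN + KEY_MAX - t.response_key,
            )
            for t in self.trials
        ]
        return replace(self, trials=flipped)


@dataclass(frozen=True)
class AudiogramRecord:
    """One pure-tone threshold of one ear."""

    participant_id: str
    phase: str
    ear: str  # "left" | "right"
    frequency: float  # Hz
    threshold: float  # dB HL

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"unknown ear {self.ear!r}")
        if not (125 <= self.frequency <= 8000):
            raise ValueError(f"frequency {self.frequency} Hz outside 125..8000")


def is_na(x: float | None) -> bool:
    """Uniform undefined-value test (None or NaN)."""
    return x is None or (isinstance(x, float) and math.isnan(x))
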