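"""The continuous multichannel recording container and its annotations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class RecordingError(ValueError):
    """Invalid recording construction."""


@dataclass(frozen=True)
class Span:
    """A time interval ``[onset_s, onset_s + duration_s)`` in seconds."""

    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise RecordingError("negative span duration")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def overlap(self, onset_s: float, end_s: float) -> float:
        """Length of overlap with ``[onset_s, end_s)``."""
        return max(0.0, min(self.end_s, end_s) - max(self.onset_s, onset_s))


@dataclass(frozen=True)
class ConditionSpan(Span):
    """A condition block: state (HY|NC), memory (NDE|AUTOBIO), phase (OBE|PE|KS)."""

    state: str = "NC"
    memory: str = "NDE"
    phase: str = "PE"

    STATES = ("HY", "NC")
    MEMORIES = ("NDE", "AUTOBIO")
    PHASES = ("OBE", "PE", "KS")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.state not in self.STATES:
            raise RecordingError(f"unknown state {self.state!r}")
        if self.memory not in self.MEMORIES:
            raise RecordingError(f"unknown memory {self.memory!r}")
        if self.phase not in self.PHASES:
            raise RecordingError(f"unknown phase {self.phase!r}")


@dataclass
class Recording:
    """Continuous multichannel potentials with annotations.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` array of potentials in microvolts.
    sfreq
        Sampling rate in Hz.
    channel_ids
        Channel identifiers aligned with the rows of ``data``.
    condition_annotations
        Condition blocks covering the session.
    artifact_annotations
        Marked bad portions of data.
    bad_channels
        Channels marked bad (to be interpolated).
    reference
        ``"original"`` or ``"average"``.
    participant
        Optional participant id the recording belongs to.
    """

    data: np.ndarray
    sfreq: float
    channel_ids: list[str]
    condition_annotations: list[ConditionSpan] = field(default_factory=list)
    artifact_annotations: list[Span] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)
    reference: str = "original"
    participant: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sfreq <= 0:
            raise RecordingError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_ids):
            raise RecordingError("data must be (n_channels, n_samples)")
        dur = self.duration_s
        for ann in [*self.condition_annotations, *self.artifact_annotations]:
            if ann.onset_s < -1e-9 or ann.end_s > dur + 1e-6:
                raise RecordingError(
                    f"annotation [{ann.onset_s}, {ann.end_s}) outside recording "
                    f"of {dur} s")
        unknown = self.bad_channels - set(self.channel_ids)
        if unknown:
            raise RecordingError(f"bad channels not in montage: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Copy of this recording with new samples (annotations untouched)."""
        return replace(self, data=data, **changes)

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())
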