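"""Core containers: waveforms and acoustic feature trajectories.

The analysis operates on two in-memory objects: :class:`Waveform`, a
labelled mono audio segment, and :class:`FeatureTrajectory`, one named,
uniformly sampled acoustic channel (F0, HNR, CPP, envelope, formants,
MFCCs) with a per-frame validity mask. Invalid frames carry NaN and are
never used in correlations.

Each channel has a fixed registry rate: F0 is sampled at 1000 Hz, MFCCs
at 200 Hz, and all remaining channels (HNR, CPP, envelope, formants,
optional creak) at 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Waveform",
    "FeatureTrajectory",
    "RecordingFeatures",
    "registry_rate",
    "LARYNGEAL_CHANNELS",
    "ANALYSIS_CATEGORIES",
]

#: Channels tied to vocal-fold activity; correlations involving any of
#: these are restricted to voiced (non-zero pitch) regions.
LARYNGEAL_CHANNELS = frozenset({"F0", "HNR", "CPP", "CREAK"})

#: The five vocalization categories used in the analysis.
ANALYSIS_CATEGORIES = (
    "self-talk",
    "delight",
    "dysregulation",
    "frustration",
    "request",
)


def registry_rate(channel: str) -> float:
    """Return the registry sampling rate (Hz) for a channel name.

    F0 trajectories are emitted at 1000 Hz, MFCC coefficients at 200 Hz,
    and every other channel at 100 Hz.
    """
    if channel == "F0":
        return 1000.0
    if channel.startswith("MFCC"):
        return 200.0
    return 100.0


@dataclass
class Waveform:
    """A mono audio segment with its sampling rate and cohort labels."""

    samples: np.ndarray
    rate_hz: float
    recording_id: str = ""
    subject_id: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidInputError("waveform samples must be 1-D (mono)")
        if self.rate_hz <= 0:
            raise InvalidInputError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class FeatureTrajectory:
    """One uniformly sampled acoustic channel with a validity mask.

    ``values`` are in channel units (Hz for F0/F1-F3, dB for HNR/CPP,
    linear amplitude for ENV, dimensionless for MFCCs). Frames where
    ``mask`` is False carry NaN and are excluded from all correlations.
    """

    name: str
    values: np.ndarray
    rate_hz: float
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise InvalidInputError(
                f"mask length {self.mask.size} != values length {self.values.size}"
            )
        # invalid frames carry a NaN sentinel so accidental use is loud
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def times(self) -> np.ndarray:
        """Frame-center times in seconds."""
        return np.arange(self.values.size) / self.rate_hz

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def valid_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class RecordingFeatures:
    """All extracted channels for one recording, with its labels."""

    recording_id: str
    subject_id: str
    category: str
    duration_s: float
    channels: dict[str, FeatureTrajectory] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> FeatureTrajectory:
        return self.channels[name]

    def channel_names(self) -> list[str]:
        return sorted(self.channels)
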