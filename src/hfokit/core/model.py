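"""Domain types shared by every pipeline stage.

Conventions used throughout the package:

* sample indices are 0-based;
* event intervals are half-open ``[onset, offset)``;
* all times are seconds from recording start;
* signal amplitudes are microvolts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Condition",
    "Band",
    "Category",
    "Lobe",
    "Montage",
    "Recording",
    "ChannelInfo",
    "PatientOutcome",
    "CandidateEvent",
    "ClassifiedEvent",
    "ENGEL_CLASSES",
    "MIN_RATE_HZ",
    "RATE_CATEGORIES",
]

#: Minimum sampling rate able to resolve the 250-600 Hz band with margin.
MIN_RATE_HZ = 1250.0

#: Ordered post-surgical outcome scale; anything at or beyond "IIa" is a failure.
ENGEL_CLASSES = ("I", "IIa", "IIb", "III", "IV")


class Condition(str, enum.Enum):
    INTRAOP = "intraop"
    SLEEP = "sleep"


class Band(str, enum.Enum):
    #: 80-600 Hz detection band (ripple vs fast-ripple resolved downstream).
    BROAD_HFO = "broad_hfo"
    #: dedicated 250-600 Hz pass for fast-ripple sensitivity.
    FAST_RIPPLE = "fast_ripple"


#: Detection passbands in Hz.
BAND_EDGES_HZ = {Band.BROAD_HFO: (80.0, 600.0), Band.FAST_RIPPLE: (250.0, 600.0)}

#: Ripple vs fast-ripple split frequency.
RIPPLE_SPLIT_HZ = 250.0


class Category(str, enum.Enum):
    RON_O = "RonO"
    RON_S = "RonS"
    FRON_O = "fRonO"
    FRON_S = "fRonS"
    SHARP_SPIKE = "SharpSpike"
    ARTIFACT = "Artifact"


#: Categories that enter rate statistics (Artifact is audit-only).
RATE_CATEGORIES = (
    Category.RON_O,
    Category.RON_S,
    Category.FRON_O,
    Category.FRON_S,
    Category.SHARP_SPIKE,
)


class Lobe(str, enum.Enum):
    FRONTAL = "frontal"
    PARIETAL = "parietal"
    TEMPORAL = "temporal"
    OCCIPITAL = "occipital"
    OTHER = "other"


class Montage(str, enum.Enum):
    REFERENTIAL = "referential"
    BIPOLAR = "bipolar"


@dataclass
class Recording:
    """Multichannel iEEG block: ``samples`` is channels x timepoints in uV."""

    samples: np.ndarray
    rate_hz: float = 2000.0
    channel_ids: tuple[str, ...] = ()
    condition: Condition = Condition.INTRAOP
    patient_id: str = ""
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x timepoints array")
        self.channel_ids = tuple(self.channel_ids)
        if len(self.channel_ids) != len(set(self.channel_ids)):
            raise ValueError("channel_ids must be unique")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.channel_ids)} channel ids"
            )
        if self.rate_hz <= 1200.0:
            raise ValueError(
                "rate_hz must exceed 1200 Hz (Nyquist must cover the 600 Hz "
                "upper band edge)"
            )
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"channel {channel_id!r} not in recording") from None

    def get(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]


@dataclass
class ChannelInfo:
    """Per-contact metadata, constant across recording conditions.

    ``resected`` is tri-state: ``True``/``False`` when the resection status
    is known, ``None`` when the region was not sampled by post-op imaging.
    """

    channel_id: str
    patient_id: str
    lobe: Lobe = Lobe.OTHER
    soz: bool = False
    resected: Optional[bool] = None
    matched: bool = False
    montage_partner: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.lobe, str):
            self.lobe = Lobe(self.lobe)


@dataclass
class PatientOutcome:
    patient_id: str
    engel_class: str
    postop_mri: bool = True

    def __post_init__(self) -> None:
        if self.engel_class not in ENGEL_CLASSES:
            raise ValueError(
                f"engel_class must be one of {ENGEL_CLASSES}, got {self.engel_class!r}"
            )

    @property
    def is_failure(self) -> bool:
        """Surgical failure: Engel class IIa or worse."""
        return ENGEL_CLASSES.index(self.engel_class) >= ENGEL_CLASSES.index("IIa")


@dataclass
class CandidateEvent:
    """Suprathreshold envelope event prior to time-frequency review."""

    channel_id: str
    band: Band
    onset_s: float
    offset_s: float
    peak_envelope_z: float
    montage: Montage = Montage.REFERENTIAL
    condition: Condition = Condition.INTRAOP

    def __post_init__(self) -> None:
        if isinstance(self.band, str):
            self.band = Band(self.band)
        if isinstance(self.montage, str):
            self.montage = Montage(self.montage)
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)
        if not self.offset_s > self.onset_s:
            raise ValueError("event offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "CandidateEvent") -> float:
        return max(
            0.0, min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s)
        )


@dataclass
class ClassifiedEvent(CandidateEvent):
    """Candidate event after time-frequency classification."""

    category: Category = Category.ARTIFACT
    power: float = 0.0
    spectral_freq_hz: float = float("nan")
    duration_ms: float = float("nan")
    has_spike: bool = False
    tf_island: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if isinstance(self.category, str):
            self.category = Category(self.category)
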