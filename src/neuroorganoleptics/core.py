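"""Shared domain types: acquisition configuration, protocol timelines, recordings.

These are the in-memory containers exchanged between the simulator, the
quality screen, the ECG/HRV chain and the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "Event",
    "EventTimeline",
    "RawRecording",
    "ArtifactRecord",
    "GroundTruth",
]

#: Event kinds a protocol timeline may contain, in their scientific meaning:
#: an initial relaxation baseline, 10-s on-screen visual stimuli, 60-s product
#: tastings, the question phases that follow each tasting, and the session end.
EVENT_KINDS = ("baseline", "visual_stimulus", "tasting_onset", "question_phase", "session_end")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling configuration of the multi-channel acquisition unit.

    The study hardware ran at 1 kHz with 10-bit resolution; ``channel_map``
    gives the ordered roles of the analog channels.
    """

    sampling_rate: float = 1000.0
    resolution_bits: int = 10
    vcc: float = 3.3
    channel_map: tuple[str, ...] = ("ECG", "EDA", "PZT", "PPG")

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.resolution_bits < 1:
            raise ValueError(f"resolution_bits must be >= 1, got {self.resolution_bits}")
        roles = tuple(r.upper() for r in self.channel_map)
        object.__setattr__(self, "channel_map", roles)

    @property
    def max_code(self) -> int:
        return 2**self.resolution_bits - 1

    @property
    def full_scale(self) -> int:
        return 2**self.resolution_bits


@dataclass(frozen=True)
class Event:
    kind: str
    product: str | None
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EventTimeline:
    """Ordered, typed protocol events for one session.

    Onsets are strictly increasing; visual stimuli last 10 s and tastings
    60 s by protocol.
    """

    events: list[Event]

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def tasting_onset(self, product: str) -> Event:
        for e in self.events:
            if e.kind == "tasting_onset" and e.product == product:
                return e
        raise KeyError(f"no tasting_onset event for product {product!r}")

    @property
    def products(self) -> list[str]:
        return [e.product for e in self.events if e.kind == "tasting_onset"]

    @property
    def end(self) -> float:
        return max(e.end for e in self.events) if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"kind": e.kind, "product": e.product or "", "onset_s": e.onset, "duration_s": e.duration}
                for e in self.events
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTimeline":
        events = [
            Event(
                kind=str(r["kind"]),
                product=(str(r["product"]) or None) if not pd.isna(r["product"]) else None,
                onset=float(r["onset_s"]),
                duration=float(r["duration_s"]),
            )
            for _, r in frame.iterrows()
        ]
        return cls(events)


@dataclass
class RawRecording:
    """Multi-channel integer ADC streams plus acquisition metadata."""

    config: AcquisitionConfig
    streams: dict[str, np.ndarray]
    subject: str = "S00"
    session: int = 1
    timestamp: str = "1970-01-01T00:00:00"

    def __post_init__(self) -> None:
        lengths = {role: len(s) for role, s in self.streams.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel streams differ in length: {lengths}")
        for role, s in self.streams.items():
            s = np.asarray(s)
            if s.size and (s.min() < 0 or s.max() > self.config.max_code):
                raise ValueError(
                    f"channel {role}: codes outside [0, {self.config.max_code}]"
                )
            self.streams[role] = s.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.streams.values()))) if self.streams else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.config.sampling_rate


@dataclass(frozen=True)
class ArtifactRecord:
    """One injected artifact episode: interval in seconds plus its kind."""

    start: float
    end: float
    kind: str  # flatline | saturation | spike_burst
    channel: str = "ECG"


@dataclass
class GroundTruth:
    """What the simulator knows that the pipeline must recover."""

    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    injected_artifacts: list[ArtifactRecord] = field(default_factory=list)
    lf_power_true: dict[str, float] = field(default_factory=dict)
    hf_power_true: dict[str, float] = field(default_factory=dict)
    score_means: dict[str, float] = field(default_factory=dict)
    saturation_warnings: int = 0

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        self.beat_times = bt
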