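"""Stimulus protocols for timed superfusion experiments.

A protocol is the temporal frame for all trace analysis: a sorted list of
non-overlapping stimulus events (two urine stimuli presented in alternating
sequence, followed by a terminal high-K+ depolarization pulse) plus the
acquisition sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

K_LABEL = "K"


@dataclass(frozen=True)
class StimulusEvent:
    """A single timed stimulus application."""

    label: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"event {self.label!r}: duration must be > 0")
        if self.onset_s < 0:
            raise ValueError(f"event {self.label!r}: onset must be >= 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Timed stimulus events plus sampling rate.

    Invariants enforced at construction: events sorted by onset with no
    overlap; exactly one K+ event and it is last; the total duration covers
    every event.
    """

    events: tuple[StimulusEvent, ...]
    sampling_rate_hz: float = 1.0
    total_duration_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not self.events:
            raise ValueError("protocol needs at least one event")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset_s < prev.onset_s:
                raise ValueError("events must be sorted by onset")
            if nxt.onset_s < prev.offset_s:
                raise ValueError(
                    f"events overlap: {prev.label!r} "
                    f"[{prev.onset_s}, {prev.offset_s}) and {nxt.label!r} "
                    f"[{nxt.onset_s}, {nxt.offset_s})"
                )
        k_events = [e for e in self.events if e.label == K_LABEL]
        if len(k_events) != 1:
            raise ValueError(f"protocol must contain exactly one {K_LABEL!r} event")
        if self.events[-1].label != K_LABEL:
            raise ValueError(f"the {K_LABEL!r} event must be last")
        last = self.events[-1]
        if self.total_duration_s == 0.0:
            # default: pad with one stimulus duration after the K offset
            object.__setattr__(
                self, "total_duration_s", last.offset_s + 2 * last.duration_s
            )
        if self.total_duration_s < last.offset_s:
            raise ValueError("total_duration_s does not cover the last event")

    # -- accessors -------------------------------------------------------

    @property
    def k_event(self) -> StimulusEvent:
        return self.events[-1]

    @property
    def stimulus_labels(self) -> tuple[str, ...]:
        """Distinct non-K labels in order of first appearance."""
        seen: list[str] = []
        for e in self.events:
            if e.label != K_LABEL and e.label not in seen:
                seen.append(e.label)
        return tuple(seen)

    def presentations(self, label: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.label == label)

    @property
    def n_timepoints(self) -> int:
        import math

        return int(math.floor(self.total_duration_s * self.sampling_rate_hz)) + 1

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "events": [
                {"label": e.label, "onset_s": e.onset_s, "duration_s": e.duration_s}
                for e in self.events
            ],
            "sampling_rate_hz": self.sampling_rate_hz,
            "total_duration_s": self.total_duration_s,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        events = tuple(
            StimulusEvent(e["label"], float(e["onset_s"]), float(e["duration_s"]))
            for e in d["events"]
        )
        return cls(
            events=events,
            sampling_rate_hz=float(d.get("sampling_rate_hz", 1.0)),
            total_duration_s=float(d.get("total_duration_s", 0.0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_protocol(
    stim_labels: Sequence[str] = ("stim_A", "stim_B"),
    n_repeats: int = 2,
    baseline_s: float = 30.0,
    stim_duration_s: float = 10.0,
    isi_s: float = 180.0,
    k_duration_s: float = 10.0,
    sampling_rate_hz: float = 1.0,
    tail_s: float = 30.0,
) -> StimulusProtocol:
    """Build an alternating-stimulation protocol.

    The default reproduces the standard pairwise paradigm: a 30 s lead-in,
    then stim_A / stim_B presented alternately ``n_repeats`` times each
    (10 s pulses, 180 s offset-to-next-onset inter-stimulus interval), and a
    terminal 10 s high-K+ pulse, sampled at 1 Hz.

    With ``n_repeats=0`` a K-only protocol is produced (degenerate but valid).
    """
    if stim_duration_s <= 0 or k_duration_s <= 0:
        raise ValueError("stimulus durations must be > 0")
    if isi_s <= 0:
        raise ValueError("inter-stimulus interval must be > 0")
    if baseline_s < 0 or tail_s < 0:
        raise ValueError("baseline_s and tail_s must be >= 0")

    events: list[StimulusEvent] = []
    t = baseline_s
    for _ in range(n_repeats):
        for label in stim_labels:
            events.append(StimulusEvent(label, t, stim_duration_s))
            t += stim_duration_s + isi_s
    events.append(StimulusEvent(K_LABEL, t, k_duration_s))
    total = t + k_duration_s + tail_s
    return StimulusProtocol(
        events=tuple(events),
        sampling_rate_hz=sampling_rate_hz,
        total_duration_s=total,
    )
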