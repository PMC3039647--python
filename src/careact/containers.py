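"""Core in-memory containers: spike trains and event schedules.

All times are in seconds (float). Windows are half-open ``[start, end)``
and bin indices are 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The four startling episodic event types used throughout.
EVENT_TYPES = ("sound", "air", "drop", "shake")

#: Event types delivered at graded intensities (levels 1..3).
PARAMETRIC_TYPES = ("air", "drop")


@dataclass(frozen=True)
class Event:
    """A single stimulus delivery.

    ``level`` is 1..3 for parametric (intensity-graded) stimuli and 0 for
    fixed-intensity stimuli.
    """

    event_type: str
    level: int
    onset_s: float
    session: int

    @property
    def condition(self) -> str:
        """Class label used for classification, e.g. ``drop-3`` or ``sound``."""
        if self.level:
            return f"{self.event_type}-{self.level}"
        return self.event_type


@dataclass
class EventSchedule:
    """Typed, intensity-graded, timed stimulus schedule.

    Parameters
    ----------
    events
        Stimulus deliveries, onset-ordered within each session.
    baseline_span_s
        Seconds of event-free recording before the first onset.
    span_s
        Total recording span; all analysis windows must fit inside it.
    """

    events: list[Event]
    baseline_span_s: float
    span_s: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_session: dict[int, list[float]] = {}
        for ev in self.events:
            by_session.setdefault(ev.session, []).append(ev.onset_s)
        for sess, onsets in by_session.items():
            arr = np.asarray(onsets)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"onsets not strictly increasing in session {sess}")
        if self.events and self.events[-1].onset_s >= self.span_s:
            raise ValueError("last event onset beyond recording span")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, event_type: str | None = None, level: int | None = None) -> np.ndarray:
        """Onset times, optionally restricted to one type and/or level."""
        sel = [
            ev.onset_s
            for ev in self.events
            if (event_type is None or ev.event_type == event_type)
            and (level is None or ev.level == level)
        ]
        return np.asarray(sel, dtype=float)

    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: list[str] = []
        for ev in self.events:
            if ev.condition not in seen:
                seen.append(ev.condition)
        return seen

    def event_types(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.event_type not in seen:
                seen.append(ev.event_type)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": [ev.event_type for ev in self.events],
                "level": [ev.level for ev in self.events],
                "onset_s": [ev.onset_s for ev in self.events],
                "session": [ev.session for ev in self.events],
            }
        )

    def stimulation_intervals(self, pre_s: float = 0.0, post_s: float = 3.0) -> np.ndarray:
        """``(n, 2)`` array of windows around stimuli to exclude from rest-time
        statistics (default: onset to onset + 3 s)."""
        iv = np.array([[ev.onset_s - pre_s, ev.onset_s + post_s] for ev in self.events])
        return iv if len(iv) else np.empty((0, 2))


class SpikeTrainSet:
    """Per-unit spike timestamps.

    Each train is a sorted 1-D float array of spike times in seconds.
    Optional per-spike ``amplitudes`` (arbitrary units) support the complex
    spike index.
    """

    def __init__(
        self,
        trains: list[np.ndarray],
        unit_ids: list | None = None,
        amplitudes: list[np.ndarray] | None = None,
        span_s: float | None = None,
    ) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in trains]
        for t in self.trains:
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError("spike times must be ascending within a unit")
            if t.size and t[0] < 0:
                raise ValueError("negative spike time")
        self.unit_ids = list(unit_ids) if unit_ids is not None else list(range(len(trains)))
        if len(self.unit_ids) != len(self.trains):
            raise ValueError("unit_ids length mismatch")
        self.amplitudes = amplitudes
        if span_s is None:
            span_s = max((float(t[-1]) for t in self.trains if t.size), default=0.0)
        self.span_s = float(span_s)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def subset(self, indices) -> "SpikeTrainSet":
        indices = list(indices)
        amps = [self.amplitudes[i] for i in indices] if self.amplitudes is not None else None
        return SpikeTrainSet(
            [self.trains[i] for i in indices],
            unit_ids=[self.unit_ids[i] for i in indices],
            amplitudes=amps,
            span_s=self.span_s,
        )

    def counts_in_windows(self, starts: np.ndarray, width: float) -> np.ndarray:
        """Spike counts per unit in half-open windows ``[s, s + width)``.

        Returns an ``(n_units, n_windows)`` integer array.
        """
        starts = np.asarray(starts, dtype=float)
        out = np.empty((self.n_units, starts.size), dtype=np.int64)
        ends = starts + width
        for i, t in enumerate(self.trains):
            out[i] = np.searchsorted(t, ends, side="left") - np.searchsorted(
                t, starts, side="left"
            )
        return out

    def rates_in_windows(self, starts: np.ndarray, width: float) -> np.ndarray:
        """Firing rates (Hz) per unit in half-open windows."""
        return self.counts_in_windows(starts, width) / float(width)
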