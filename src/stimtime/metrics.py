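"""Session-level timing metrics.

A recording session is ~100 repeated trials of one commanded stimulus.
Accuracy is the median physical duration over the session; precision is its
sample SD together with the mean absolute deviation about the median (the
error bars of the validation figures).  ISIs are offset-to-next-onset gaps by
default (the commanded spacing convention), with onset-to-onset exposed as an
alternative.  Frame-miss rate is the fraction of visual trials whose duration
sits one frame period away from the session's typical duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DelayTable, DetectionParams, Event, Trace
from .analysis import detect_events

__all__ = [
    "StimulusCountError",
    "session_accuracy",
    "session_precision",
    "measure_isi",
    "frame_miss_rate",
    "simultaneity_deltas",
    "session_durations",
    "MetricsReport",
]


class StimulusCountError(ValueError):
    """A trial yielded fewer events than commanded (merged or missing)."""


def session_accuracy(durations_ms: Sequence[float]) -> float:
    """Median measured duration across a session (ms)."""
    d = np.asarray(durations_ms, dtype=float)
    if d.size == 0:
        raise ValueError("empty duration list")
    return float(np.median(d))


def session_precision(durations_ms: Sequence[float]) -> tuple[float, float]:
    """(sample SD, mean absolute deviation about the median), both ms."""
    d = np.asarray(durations_ms, dtype=float)
    if d.size < 2:
        raise ValueError("precision needs at least two measurements")
    sd = float(d.std(ddof=1))
    mad = float(np.mean(np.abs(d - np.median(d))))
    return sd, mad


def measure_isi(
    events: Sequence[Event], convention: str = "offset_to_onset"
) -> list[float]:
    """Inter-stimulus intervals between successive events (ms).

    ``offset_to_onset`` (default) is the silent gap: onset(i+1) − offset(i).
    ``onset_to_onset`` returns onset(i+1) − onset(i).  Fewer than two events
    means the device merged or dropped a stimulus and raises
    :class:`StimulusCountError`.
    """
    if len(events) < 2:
        raise StimulusCountError(
            f"need >= 2 events for an ISI, got {len(events)} "
            "(merged or missing stimulus)"
        )
    if convention == "offset_to_onset":
        return [b.onset_ms - a.offset_ms for a, b in zip(events, events[1:])]
    if convention == "onset_to_onset":
        return [b.onset_ms - a.onset_ms for a, b in zip(events, events[1:])]
    raise ValueError(f"unknown ISI convention {convention!r}")


def frame_miss_rate(
    durations_ms: Sequence[float], nominal_ms: float, frame_period_ms: float
) -> float:
    """Fraction of trials whose duration is one frame off the modal duration.

    The session's modal duration (the most common value, located by the
    median, valid while misses stay below 50 %) is the frame-perfect
    rendition of ``nominal_ms``; a trial counts as a miss when its deviation
    from it matches one frame period within ±25 %.
    """
    d = np.asarray(durations_ms, dtype=float)
    if d.size == 0:
        raise ValueError("empty duration list")
    if frame_period_ms <= 0:
        raise ValueError("frame_period_ms must be positive")
    modal = float(np.median(d))
    dev = np.abs(d - modal)
    miss = np.abs(dev - frame_period_ms) <= 0.25 * frame_period_ms
    return float(miss.mean())


def simultaneity_deltas(events_by_modality: Mapping[str, Event]) -> DelayTable:
    """Onset delay of each modality relative to the fastest one (ms).

    The fastest modality gets 0 by definition; requires one event for each
    of at least two modalities.
    """
    if len(events_by_modality) < 2:
        raise ValueError("need events from at least two modalities")
    onsets = {m: e.onset_ms for m, e in events_by_modality.items()}
    fastest = min(onsets.values())
    return DelayTable({m: o - fastest for m, o in onsets.items()})


def session_durations(
    traces: Iterable[Trace],
    modality: str,
    params: DetectionParams | None = None,
    *,
    n_expected: int = 1,
) -> tuple[list[float], int]:
    """Detect events over a session; return (durations, n_incomplete).

    A trial contributes its durations only when it yields exactly
    ``n_expected`` events; merged/missing/extra-event trials are counted in
    ``n_incomplete`` and excluded (not silently dropped) from the metric.
    """
    durations: list[float] = []
    incomplete = 0
    for tr in traces:
        evs = detect_events(tr, modality, params)
        if len(evs) != n_expected:
            incomplete += 1
        else:
            durations.extend(e.duration_ms for e in evs)
    return durations, incomplete


@dataclass
class MetricsReport:
    """Validation summary tables.

    ``durations``: one row per (modality, nominal duration) with accuracy,
    precision (SD and MAD), trial counts, missing-event counts and — for the
    visual channel — the frame-miss rate.  ``intervals``: same per sequential
    session, for the measured ISIs (the convention is recorded per row).
    ``onset_deltas``: modality → onset delay from a trimodal trial, before
    and optionally after delay compensation.
    """

    durations: pd.DataFrame = field(default_factory=pd.DataFrame)
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)
    onset_deltas: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def has_incomplete_trials(self) -> bool:
        n = 0
        for df in (self.durations, self.intervals):
            if not df.empty and "n_incomplete" in df:
                n += int(df["n_incomplete"].sum())
        return n > 0

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.durations.to_csv(outdir / "durations.csv", index=False)
        self.intervals.to_csv(outdir / "intervals.csv", index=False)
        self.onset_deltas.to_csv(outdir / "onset_deltas.csv", index=False)
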