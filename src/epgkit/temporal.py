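"""Temporal slicing (by-hour / cumulative) and per-event tables.

A temporal window is either one hour of the recording (``by-hour``:
``[60*(h-1), 60*h)`` minutes) or everything up to the end of hour ``h``
(``cumulative``: ``[0, 60*h)``).  The full registry can be recomputed on the
clipped recording of each window.  A period spanning a window boundary is by
default split, each window counting its own fragment as one period (so
by-hour counts may sum to more than the full-recording count, while
durations always partition exactly); attributing whole periods to their
starting window is available via ``split="start"``.

Event tables list every period of one waveform across a treatment (waveform
duration per event, WDE); because pooled events from one insect are not
independent replicates, the per-insect mean (WDEI) is also provided.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import pandas as pd

from . import waveforms as wf
from .errors import DomainError
from .model import Period, Recording, _assign_probes
from .variables import ComputeOptions, VariableResult, compute_all


def replace_options(options: ComputeOptions, **updates) -> ComputeOptions:
    new = copy.copy(options)
    for key, value in updates.items():
        setattr(new, key, value)
    return new


@dataclass(frozen=True)
class TemporalWindow:
    mode: str  # "by-hour" | "cumulative"
    hour_index: int  # 1-based

    def __post_init__(self):
        if self.mode not in ("by-hour", "cumulative"):
            raise DomainError(f"unknown temporal mode {self.mode!r}")
        if self.hour_index < 1:
            raise DomainError("hour_index must be >= 1")

    @property
    def interval(self) -> tuple[float, float]:
        h = self.hour_index
        return (60.0 * (h - 1), 60.0 * h) if self.mode == "by-hour" else (0.0, 60.0 * h)


def slice_recording(recording: Recording, window: TemporalWindow, split: str = "split") -> Recording:
    """Clip a recording to a temporal window.

    ``split="split"`` retains the in-window part of a boundary-spanning
    period; ``split="start"`` attributes whole periods to the window where
    they begin.  The clipped final period is truncated by the window unless
    the window reaches the true end of the recording.
    """
    lo, hi = window.interval
    if lo >= recording.total_duration:
        raise DomainError(
            f"window {window.mode} hour {window.hour_index} starts at {lo} min, "
            f"beyond the recording ({recording.total_duration} min)"
        )
    hi = min(hi, recording.total_duration)
    if split not in ("split", "start"):
        raise DomainError(f"unknown split policy {split!r}")

    clipped: list[Period] = []
    for p in recording.periods:
        if split == "split":
            a, b = max(p.start, lo), min(p.end, hi)
            if b > a:
                clipped.append(Period(p.label, a - lo, b - a))
        else:
            if lo <= p.start < hi:
                clipped.append(Period(p.label, p.start - lo, p.duration))
    total = (hi - lo) if split == "split" else (
        clipped[-1].end if clipped else 0.0
    )
    return Recording(
        periods=tuple(_assign_probes(clipped)),
        total_duration=total,
        file_name=recording.file_name,
        treatment=recording.treatment,
        last_period_truncated=True,
        terminated=True,
    )


def compute_temporal(
    recording: Recording,
    mode: str = "by-hour",
    hours: list[int] | None = None,
    options: ComputeOptions | None = None,
    split: str = "split",
    truncate_window_cuts: bool = False,
) -> dict[TemporalWindow, list[VariableResult]]:
    """Recompute the registry per temporal window.

    The truncated-wave criterion targets end-of-recording truncation, so a
    final period cut by a *window* boundary is left as observed unless
    ``truncate_window_cuts`` is set; a window reaching the true end of the
    recording applies whatever the caller's options say.
    """
    options = options or ComputeOptions()
    if hours is None:
        hours = list(range(1, max(1, math.ceil(recording.total_duration / 60.0)) + 1))
    out: dict[TemporalWindow, list[VariableResult]] = {}
    for h in hours:
        window = TemporalWindow(mode, h)
        lo, hi = window.interval
        if lo >= recording.total_duration:
            continue
        sliced = slice_recording(recording, window, split=split)
        reaches_end = hi >= recording.total_duration
        opts = options
        if options.truncated_criterion and not reaches_end and not truncate_window_cuts:
            opts = replace_options(options, truncated_criterion=False)
        out[window] = compute_all(sliced, opts)
    return out


def temporal_frame(results_by_window: dict[TemporalWindow, list[VariableResult]]) -> pd.DataFrame:
    """Flatten temporal results into a tidy frame with window columns."""
    rows = []
    for window, results in results_by_window.items():
        lo, hi = window.interval
        for r in results:
            rows.append(
                {"mode": window.mode, "hour": window.hour_index, "lo_min": lo, "hi_min": hi,
                 "acronym": r.acronym, "value": r.value, "missing_reason": r.missing_reason}
            )
    return pd.DataFrame(rows)


def events_table(recordings: list[Recording], waveform: str) -> pd.DataFrame:
    """Every period of one waveform across a treatment, one row per event.

    Rows carry provenance (treatment, file, event index within recording)
    so the per-insect grouping needed for correct statistics is explicit.
    """
    if not recordings:
        raise ValueError("events_table needs at least one recording")
    rows = []
    for rec in recordings:
        k = 0
        for p in rec.periods:
            if p.label == waveform:
                k += 1
                rows.append(
                    {"treatment": rec.treatment, "file": rec.file_name, "waveform": waveform,
                     "event_index": k, "start_min": p.start, "duration_min": p.duration}
                )
    return pd.DataFrame(rows, columns=["treatment", "file", "waveform", "event_index",
                                       "start_min", "duration_min"])


def wdei(recording: Recording, waveform: str) -> float | None:
    """Waveform duration per event and per insect: the mean period duration
    of one waveform within one recording (None when the waveform is absent).

    The individual recording is the statistical replicate, so treatment
    comparisons should use this per-insect mean rather than pooled events.
    """
    durations = recording.durations(waveform)
    if not durations:
        return None
    return sum(durations) / len(durations)
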