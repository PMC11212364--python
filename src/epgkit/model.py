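"""Canonical in-memory data model: marks, periods, recordings.

All times are real minutes from the start of the file.  A recording is a
gap-free tiling of ``[0, total_duration)`` by labelled half-open periods; the
terminal mark (code 99) is a boundary that closes the final period, so the
final period is always artificially truncated by the end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import waveforms as wf


@dataclass(frozen=True)
class Mark:
    """One annotation event: integer waveform code + onset time in minutes."""

    code: int
    time: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"mark time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class Period:
    """A labelled waveform interval ``[start, start + duration)``.

    ``probe_index`` is None for non-probing periods; ``cumulative_in_probe``
    is the running sum of durations of periods within the same probe,
    mirroring the data-sheet column of the workbook this engine reimplements.
    """

    label: str
    start: float
    duration: float
    probe_index: int | None = None
    cumulative_in_probe: float | None = None

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Recording:
    """Validated ordered list of periods for one insect/plant combination."""

    periods: tuple[Period, ...]
    total_duration: float
    file_name: str = ""
    treatment: int = 1
    #: the terminal mark always cuts the final period short
    last_period_truncated: bool = True
    #: False only when a terminal-mark violation was injected synthetically
    terminated: bool = True

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.periods)

    def durations(self, label: str) -> list[float]:
        """Observed durations of every period carrying ``label``, in order."""
        return [p.duration for p in self.periods if p.label == label]

    def with_labels(self, labels: list[str]) -> "Recording":
        """Return a copy with period labels replaced (times untouched).

        Used by the violation injector; probe bookkeeping is recomputed.
        """
        if len(labels) != len(self.periods):
            raise ValueError("label list length mismatch")
        raw = [replace(p, label=lab) for p, lab in zip(self.periods, labels)]
        return replace(self, periods=tuple(_assign_probes(raw)))


def _assign_probes(periods: list[Period]) -> list[Period]:
    """Fill probe_index / cumulative_in_probe: a probe is a maximal run of
    non-Np periods; every Np ends the current probe."""
    out: list[Period] = []
    probe = -1
    in_probe = False
    running = 0.0
    for p in periods:
        if p.label == wf.NP:
            in_probe = False
            out.append(replace(p, probe_index=None, cumulative_in_probe=None))
        else:
            if not in_probe:
                probe += 1
                running = 0.0
                in_probe = True
            running += p.duration
            out.append(replace(p, probe_index=probe, cumulative_in_probe=running))
    return out
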