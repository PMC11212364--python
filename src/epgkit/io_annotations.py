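"""Reading annotation-file dialects and writing tabular results.

Two plain-text dialects are supported:

* **stylet** — one mark per line, ``<integer code><sep><time>`` with the
  separator auto-detected among whitespace, ``;`` and ``,``; times default to
  seconds and are converted to minutes internally.
* **windaq** — a CSV event export with a time column (seconds) and an
  event/label column resolvable through the code map.

Both produce the same ordered list of :class:`~epgkit.model.Mark` and hence
identical recordings for the same event sequence.
"""

from __future__ import annotations

import csv
import io
import os
import re
from dataclasses import dataclass

import pandas as pd

from . import waveforms as wf
from .errors import ConfigError, FormatError, ParseError, UsageError
from .model import Mark, Period, Recording, _assign_probes

_SEP_RE = re.compile(r"[;,\s]+")

MISSING_TERMINAL_MSG = (
    "missing terminal mark (T, code 99): "
    "The end of each recording must be marked"
)


def _check_marks(marks: list[Mark], path: str | None) -> None:
    if not marks:
        raise ParseError("empty annotation file", path=path)
    last = None
    for i, m in enumerate(marks):
        if last is not None and m.time <= last:
            raise FormatError(
                f"timestamps not strictly increasing at mark {i + 1} "
                f"({m.time} min after {last} min)",
                line=i + 1,
                path=path,
            )
        last = m.time
    terminal = [i for i, m in enumerate(marks) if m.code == wf.TERMINAL_CODE]
    if not terminal:
        raise FormatError(MISSING_TERMINAL_MSG, path=path)
    if terminal != [len(marks) - 1]:
        raise FormatError(
            "terminal mark (code 99) must occur exactly once, in last position",
            line=terminal[0] + 1,
            path=path,
        )


def read_stylet_annotations(
    path: str | os.PathLike | io.TextIOBase,
    code_map: wf.CodeMap | None = None,
    time_unit: str = "seconds",
) -> list[Mark]:
    """Parse a Stylet+-style two-column annotation file into marks.

    Parameters
    ----------
    path
        File path or open text handle.
    code_map
        Used only to verify that codes are resolvable; defaults to the
        standard map in p-pd mode.
    time_unit
        ``"seconds"`` (default) or ``"minutes"``; converted to minutes.
    """
    code_map = code_map or wf.CodeMap()
    if time_unit not in ("seconds", "minutes"):
        raise ConfigError(f"time_unit must be 'seconds' or 'minutes', got {time_unit!r}")
    scale = 1.0 / 60.0 if time_unit == "seconds" else 1.0

    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = getattr(path, "name", None)
    else:
        name = os.fspath(path)
        with open(name, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    marks: list[Mark] = []
    for lineno, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = [f for f in _SEP_RE.split(stripped) if f]
        if len(fields) != 2:
            raise ParseError(f"cannot parse annotation line {raw!r}", line=lineno, path=name)
        try:
            code = int(fields[0])
            time = float(fields[1])
        except ValueError:
            raise ParseError(f"cannot parse annotation line {raw!r}", line=lineno, path=name) from None
        try:
            code_map.label(code)
        except KeyError as exc:
            raise ParseError(str(exc), line=lineno, path=name) from None
        marks.append(Mark(code=code, time=time * scale))
    _check_marks(marks, name)
    return marks


def read_windaq_annotations(
    path: str | os.PathLike | io.TextIOBase,
    code_map: wf.CodeMap | None = None,
) -> list[Mark]:
    """Parse a Windaq-style CSV event export (time in seconds, event label).

    The first column that parses as a number is taken as the time column and
    the following column as the event code/label; a header row is skipped if
    present.  Labels may be numeric codes or waveform names resolvable
    through the code map.
    """
    code_map = code_map or wf.CodeMap()
    if isinstance(path, io.TextIOBase):
        rows = list(csv.reader(path))
        name = getattr(path, "name", None)
    else:
        name = os.fspath(path)
        with open(name, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))

    marks: list[Mark] = []
    for lineno, row in enumerate(rows, start=1):
        cells = [c.strip() for c in row if c.strip() != ""]
        if not cells:
            continue
        try:
            time_s = float(cells[0])
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ParseError(f"cannot parse time value {cells[0]!r}", line=lineno, path=name) from None
        if len(cells) < 2:
            raise ParseError("event row lacks a label column", line=lineno, path=name)
        label_text = cells[1]
        code = _resolve_label(label_text, code_map, lineno, name)
        marks.append(Mark(code=code, time=time_s / 60.0))
    _check_marks(marks, name)
    return marks


def _resolve_label(text: str, code_map: wf.CodeMap, lineno: int, name: str | None) -> int:
    try:
        code = int(text)
    except ValueError:
        try:
            return code_map.code(text)
        except KeyError:
            raise ParseError(f"unresolvable event label {text!r}", line=lineno, path=name) from None
    try:
        code_map.label(code)
    except KeyError:
        raise ParseError(f"unresolvable event label {text!r}", line=lineno, path=name) from None
    return code


def periods_from_marks(
    marks: list[Mark],
    code_map: wf.CodeMap | None = None,
    file_name: str = "",
    treatment: int = 1,
) -> Recording:
    """Turn a valid mark list into a :class:`Recording`.

    Durations come from successive differencing (the terminal mark closes the
    final period), probes are maximal runs of non-Np periods, and the
    within-probe cumulative duration column is filled.
    """
    code_map = code_map or wf.CodeMap()
    if len(marks) < 2:
        raise FormatError("a recording needs at least one waveform mark and a terminal mark")
    _check_marks(marks, file_name or None)
    periods: list[Period] = []
    for prev, nxt in zip(marks[:-1], marks[1:]):
        periods.append(
            Period(label=code_map.label(prev.code), start=prev.time, duration=nxt.time - prev.time)
        )
    total = marks[-1].time - marks[0].time
    if marks[0].time != 0.0:
        # normalise so the recording starts at t = 0
        periods = [Period(p.label, p.start - marks[0].time, p.duration) for p in periods]
    return Recording(
        periods=tuple(_assign_probes(periods)),
        total_duration=total,
        file_name=file_name,
        treatment=treatment,
    )


def marks_from_recording(recording: Recording, code_map: wf.CodeMap | None = None) -> list[Mark]:
    """Inverse of :func:`periods_from_marks` (used for round-trips and export)."""
    code_map = code_map or wf.CodeMap()
    marks = [Mark(code=code_map.code(p.label), time=p.start) for p in recording.periods]
    marks.append(Mark(code=wf.TERMINAL_CODE, time=recording.total_duration))
    return marks


def write_stylet_annotations(recording: Recording, path, code_map=None, time_unit="seconds") -> None:
    """Write a recording back out in the stylet dialect."""
    scale = 60.0 if time_unit == "seconds" else 1.0
    with open(path, "w", encoding="utf-8") as fh:
        for m in marks_from_recording(recording, code_map):
            fh.write(f"{m.code} {m.time * scale:.10f}\n")


def write_windaq_annotations(recording: Recording, path, code_map=None) -> None:
    """Write a recording back out in the windaq CSV dialect (time in seconds)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "event"])
        for m in marks_from_recording(recording, code_map):
            writer.writerow([f"{m.time * 60.0:.10f}", m.code])


@dataclass
class FileError:
    """One failed file in a batch load, keyed the way the error report expects."""

    position: int  # 1-based position at which the file was loaded
    file_name: str
    error: Exception


@dataclass
class LoadReport:
    recordings: list[Recording]
    errors: list[FileError]

    @property
    def ok(self) -> bool:
        return not self.errors


def load_treatment_files(
    paths: list,
    treatment: int,
    dialect: str = "stylet",
    code_map: wf.CodeMap | None = None,
    time_unit: str = "seconds",
) -> LoadReport:
    """Load every file of one treatment with shared options.

    Per-file failures are collected (position + name), not raised, mirroring
    the batch error report of the workbook workflow.
    """
    if not paths:
        raise UsageError("no annotation files given")
    if dialect not in ("stylet", "windaq"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    code_map = code_map or wf.CodeMap()
    recs: list[Recording] = []
    errors: list[FileError] = []
    for pos, path in enumerate(paths, start=1):
        name = os.fspath(path)
        try:
            if dialect == "stylet":
                marks = read_stylet_annotations(name, code_map, time_unit)
            else:
                marks = read_windaq_annotations(name, code_map)
            recs.append(
                periods_from_marks(marks, code_map, file_name=os.path.basename(name), treatment=treatment)
            )
        except Exception as exc:  # aggregate, don't fail fast
            errors.append(FileError(position=pos, file_name=os.path.basename(name), error=exc))
    return LoadReport(recordings=recs, errors=errors)


def results_frame(results_by_recording: dict, order: list[str] | None = None) -> pd.DataFrame:
    """Assemble per-recording variable results into a wide DataFrame.

    ``results_by_recording`` maps a recording name to a list of
    ``VariableResult``; rows are recordings, columns variables.  ``order``
    lists acronyms to put first; unlisted acronyms follow in registry order.
    """
    from .registry import ordered_acronyms

    rows = {}
    for name, results in results_by_recording.items():
        rows[name] = {r.acronym: r.value for r in results}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    cols = ordered_acronyms(order, available=list(frame.columns))
    return frame.reindex(columns=cols)


def write_results(
    results_by_recording: dict,
    path,
    transpose: bool = False,
    order: list[str] | None = None,
    missing_token: str = "",
) -> pd.DataFrame:
    """Write the wide results table to CSV (optionally transposed).

    Returns the frame actually written.  Missing values render as
    ``missing_token`` (empty cell by default, pass ``"NA"`` for explicit NA).
    """
    frame = results_frame(results_by_recording, order)
    out = frame.T if transpose else frame
    out.to_csv(path, na_rep=missing_token)
    return out


def write_workbook(
    results_by_recording: dict,
    path,
    events: pd.DataFrame | None = None,
    order: list[str] | None = None,
    transpose_sheet: bool = True,
) -> None:
    """Write an xlsx workbook with 'Results', optional 'Results T' and 'Events'."""
    frame = results_frame(results_by_recording, order)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        frame.to_excel(writer, sheet_name="Results")
        if transpose_sheet:
            frame.T.to_excel(writer, sheet_name="Results T")
        if events is not None:
            events.to_excel(writer, sheet_name="Events", index=False)
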