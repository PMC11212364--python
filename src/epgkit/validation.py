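"""Grammar validation of the marked waveform sequence.

The marking guidelines form a small transition grammar over waveform labels
(non-probing must be followed by pathway, phloem ingestion must be preceded
by phloem salivation, potential-drop subphases must run II-1, II-2, II-3,
and so on).  The validator is a rule engine: each rule inspects the period
label sequence and emits located, rule-identified issues; it never throws on
content.  Rule G1 (recording starts with Np) can be disabled for insects
that are already probing when recording starts; G4b (grammar of the shared
code-11 waveforms D / p-pd, which the guidelines leave unspecified) can be
disabled likewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import waveforms as wf
from .model import Recording

ALL_RULES = ("G1", "G2", "G3", "G4", "G4b", "G5", "G6", "G7", "G8", "G9", "G10", "G11", "DUP")
#: rules that can be toggled off; everything else is always enforced
OPTIONAL_RULES = ("G1", "G4b")

RULE_TEXT = {
    "G1": "The recording always starts with Np",
    "G2": "Np is always followed by C",
    "G3": "E2 is always preceded by E1",
    "G4": "pd waveform is always preceded by C and followed by C or Np",
    "G4b": "D / p-pd is always preceded by C",
    "G5": "The subphase sequence after pd (pdII-1) should be II-2, II-3",
    "G6": "F is always preceded by C",
    "G7": "F is always followed by Np or C",
    "G8": "G is always preceded by C",
    "G9": "G is always followed by Np or C",
    "G10": "E1 is always followed by E1e, E2, C, or Np",
    "G11": "The end of each recording must be marked (T, code 99)",
    "DUP": "Waveform duplication (identical adjacent marks)",
}


@dataclass(frozen=True)
class ValidationIssue:
    """One grammar violation located in the period sequence.

    ``row`` indexes the second element of the offending transition (row 0 for
    the start-of-recording and terminal-mark rules)."""

    rule_id: str
    row: int
    observed: tuple[str | None, str | None]
    message: str

    def __str__(self):
        prev, cur = self.observed
        return f"row {self.row}: [{self.rule_id}] ({prev} -> {cur}): {self.message}"


@dataclass(frozen=True)
class GuidelineSet:
    """Which rules are enforced.  G2–G11 and DUP are always on."""

    enabled: frozenset[str] = field(default_factory=lambda: frozenset(ALL_RULES))

    def __post_init__(self):
        unknown = self.enabled - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown rule ids: {sorted(unknown)}")
        mandatory = set(ALL_RULES) - set(OPTIONAL_RULES)
        if not mandatory <= self.enabled:
            missing = sorted(mandatory - self.enabled)
            raise ValueError(f"rules {missing} cannot be disabled")

    @classmethod
    def default(cls, skip_g1: bool = False, skip_g4b: bool = False) -> "GuidelineSet":
        enabled = set(ALL_RULES)
        if skip_g1:
            enabled.discard("G1")
        if skip_g4b:
            enabled.discard("G4b")
        return cls(frozenset(enabled))

    def on(self, rule: str) -> bool:
        return rule in self.enabled


def _issue(rule: str, row: int, prev: str | None, cur: str | None) -> ValidationIssue:
    return ValidationIssue(rule_id=rule, row=row, observed=(prev, cur), message=RULE_TEXT[rule])


def validate(recording: Recording, guidelines: GuidelineSet | None = None) -> list[ValidationIssue]:
    """Check a recording's label sequence against the marking guidelines.

    Returns issues ordered by row; a single bad transition may violate more
    than one rule and then yields one issue per rule.  The empty list means
    the sequence is grammatical.
    """
    g = guidelines or GuidelineSet()
    labels = list(recording.labels)
    n = len(labels)
    issues: list[ValidationIssue] = []

    if g.on("G1") and n > 0 and labels[0] != wf.NP:
        issues.append(_issue("G1", 0, None, labels[0]))
    if g.on("G11") and not recording.terminated:
        issues.append(_issue("G11", 0, None, labels[-1] if labels else None))

    for i in range(n):
        cur = labels[i]
        prev = labels[i - 1] if i > 0 else None
        nxt = labels[i + 1] if i + 1 < n else None

        if prev is not None and cur == prev:
            issues.append(_issue("DUP", i, prev, cur))
        if prev == wf.NP and cur != wf.C:
            issues.append(_issue("G2", i, prev, cur))
        if cur == wf.E2 and prev != wf.E1:
            issues.append(_issue("G3", i, prev, cur))
        if cur == wf.PD:
            if prev != wf.C:
                issues.append(_issue("G4", i, prev, cur))
            # G5: II-1 must be followed by II-2 then II-3; the terminal mark
            # may legitimately cut a group short, so a missing successor at
            # the very end of the recording is not an issue
            if nxt is not None and nxt != wf.PD2:
                issues.append(_issue("G5", i + 1, cur, nxt))
        if cur == wf.PD2:
            if prev not in (wf.PD, wf.PPD):
                issues.append(_issue("G5", i, prev, cur))
            if nxt is not None and nxt != wf.PD3:
                issues.append(_issue("G5", i + 1, cur, nxt))
        if cur == wf.PD3:
            if prev != wf.PD2:
                issues.append(_issue("G5", i, prev, cur))
            # end of a pd group: successor must be C or Np (terminal also fine)
            if nxt is not None and nxt not in (wf.C, wf.NP) and prev == wf.PD2 and i >= 2 and labels[i - 2] == wf.PD:
                issues.append(_issue("G4", i + 1, cur, nxt))
        if cur == wf.F:
            if prev != wf.C:
                issues.append(_issue("G6", i, prev, cur))
            if nxt is not None and nxt not in (wf.NP, wf.C):
                issues.append(_issue("G7", i + 1, cur, nxt))
        if cur == wf.G:
            if prev != wf.C:
                issues.append(_issue("G8", i, prev, cur))
            if nxt is not None and nxt not in (wf.NP, wf.C):
                issues.append(_issue("G9", i + 1, cur, nxt))
        if cur == wf.E1 and nxt is not None and nxt not in (wf.E1E, wf.E2, wf.C, wf.NP):
            issues.append(_issue("G10", i + 1, cur, nxt))
        if g.on("G4b") and cur in (wf.D, wf.PPD) and prev != wf.C:
            issues.append(_issue("G4b", i, prev, cur))

    issues.sort(key=lambda iss: (iss.row, ALL_RULES.index(iss.rule_id)))
    return issues


def error_report(issues_by_file: dict[str, list[ValidationIssue]]) -> str:
    """Human-readable batch report.

    The headline follows the workbook's wording with X = total issue count;
    each file with issues gets a block listing its position, name and rows.
    """
    total = sum(len(v) for v in issues_by_file.values())
    if total == 0:
        lines = ["All files valid: no wrong marks were detected."]
        return "\n".join(lines)
    lines = [f"You must review the sequence: '{total}' wrong marks were detected"]
    for pos, (name, issues) in enumerate(issues_by_file.items(), start=1):
        if not issues:
            continue
        lines.append(f"File {pos}: {name} ({len(issues)} issue{'s' if len(issues) != 1 else ''})")
        for iss in issues:
            lines.append(f"  {iss}")
    return "\n".join(lines)


def issues_frame(issues_by_file: dict[str, list[ValidationIssue]]) -> pd.DataFrame:
    """Machine-readable issue export (file, row, rule_id, previous, current)."""
    rows = []
    for name, issues in issues_by_file.items():
        for iss in issues:
            rows.append(
                {
                    "file": name,
                    "row": iss.row,
                    "rule_id": iss.rule_id,
                    "previous": iss.observed[0],
                    "current": iss.observed[1],
                    "message": iss.message,
                }
            )
    return pd.DataFrame(rows, columns=["file", "row", "rule_id", "previous", "current", "message"])
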