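"""Higher-order structure over the period sequence.

From the flat list of labelled periods this module derives:

* **probes** — maximal runs of non-Np periods (every Np ends a probe), with
  the brief-probe flag (duration < 3 min);
* **potential-drop groups** — a pd (or p-pd) onset with its II-2 / II-3
  subphase periods;
* **phloem phases** — maximal contiguous runs of E1/E2 activity, with
  whether the phase reaches ingestion (E2);
* **period class tags** — sustained E2 (> 10 min), single E1 (phase never
  reaching E2), fractionating E1 (E1 between two E2s of the same phase),
  phase-initial E1 followed by E2, whole-phase E12 pseudo-periods, and
  single D (D not followed by E1).

Thresholds are strict inequalities exactly as printed in the variable
definitions: a 3.0-min probe is not brief and a 10.0-min E2 is not sustained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import waveforms as wf
from .model import Period, Recording

BRIEF_PROBE_MIN = 3.0   # probes shorter than this are "brief"
SUSTAINED_E2_MIN = 10.0  # E2 longer than this is "sustained"


@dataclass(frozen=True)
class Probe:
    index: int
    start: float
    duration: float
    periods: tuple[Period, ...]
    brief: bool

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class PdGroup:
    """One potential-drop group: onset (subphase II-1) plus optional II-2/II-3."""

    probe_index: int
    start: float
    kind: str  # "standard-pd" or "p-pd"
    dur_II1: float
    dur_II2: float | None
    dur_II3: float | None

    @property
    def total(self) -> float:
        return self.dur_II1 + (self.dur_II2 or 0.0) + (self.dur_II3 or 0.0)

    @property
    def end(self) -> float:
        return self.start + self.total

    @property
    def complete(self) -> bool:
        return self.dur_II2 is not None and self.dur_II3 is not None


@dataclass(frozen=True)
class PhloemPhase:
    """Maximal contiguous run of E1/E2 periods within one probe."""

    start: float
    duration: float
    periods: tuple[Period, ...]
    reaches_E2: bool

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def e1_total(self) -> float:
        return sum(p.duration for p in self.periods if p.label == wf.E1)

    @property
    def e2_total(self) -> float:
        return sum(p.duration for p in self.periods if p.label == wf.E2)


@dataclass
class PeriodClassTags:
    """Index sets (into recording.periods) for the derived period classes."""

    sE2: set[int] = field(default_factory=set)
    sgE1: set[int] = field(default_factory=set)
    frE1: set[int] = field(default_factory=set)
    initial_E1_followed_E2: set[int] = field(default_factory=set)
    sgD: set[int] = field(default_factory=set)
    #: per phase reaching E2: (start, duration) of the whole-phase E12 pseudo-period
    E12: list[tuple[float, float]] = field(default_factory=list)


def find_probes(recording: Recording) -> list[Probe]:
    """Maximal runs of non-Np periods, in order of occurrence."""
    probes: list[Probe] = []
    run: list[Period] = []
    for p in recording.periods:
        if p.label == wf.NP:
            if run:
                probes.append(_mk_probe(len(probes), run))
                run = []
        else:
            run.append(p)
    if run:
        probes.append(_mk_probe(len(probes), run))
    return probes


def _mk_probe(index: int, run: list[Period]) -> Probe:
    dur = sum(p.duration for p in run)
    return Probe(index=index, start=run[0].start, duration=dur, periods=tuple(run), brief=dur < BRIEF_PROBE_MIN)


def group_pd_subphases(recording: Recording) -> list[PdGroup]:
    """One group per pd / p-pd onset, with whatever subphases were marked.

    A group whose II-2 or II-3 mark is absent is still emitted, with the
    missing subphases as None (the validator reports the G5 issue separately).
    """
    periods = recording.periods
    groups: list[PdGroup] = []
    i = 0
    n = len(periods)
    while i < n:
        p = periods[i]
        if p.label in (wf.PD, wf.PPD):
            kind = "standard-pd" if p.label == wf.PD else "p-pd"
            d2 = d3 = None
            j = i + 1
            if j < n and periods[j].label == wf.PD2:
                d2 = periods[j].duration
                j += 1
                if j < n and periods[j].label == wf.PD3:
                    d3 = periods[j].duration
                    j += 1
            groups.append(
                PdGroup(
                    probe_index=p.probe_index if p.probe_index is not None else -1,
                    start=p.start,
                    kind=kind,
                    dur_II1=p.duration,
                    dur_II2=d2,
                    dur_II3=d3,
                )
            )
            i = j
        else:
            i += 1
    return groups


def find_phloem_phases(recording: Recording) -> list[PhloemPhase]:
    """Maximal contiguous E1/E2 runs (never spanning probes: any non-phloem
    label, including Np, breaks the run)."""
    phases: list[PhloemPhase] = []
    run: list[Period] = []
    for p in recording.periods:
        if p.label in wf.PHLOEM_LABELS:
            run.append(p)
        else:
            if run:
                phases.append(_mk_phase(run))
                run = []
    if run:
        phases.append(_mk_phase(run))
    return phases


def _mk_phase(run: list[Period]) -> PhloemPhase:
    return PhloemPhase(
        start=run[0].start,
        duration=sum(p.duration for p in run),
        periods=tuple(run),
        reaches_E2=any(p.label == wf.E2 for p in run),
    )


def classify_periods(
    recording: Recording,
    phases: list[PhloemPhase] | None = None,
    sE2_threshold: float = SUSTAINED_E2_MIN,
    brief_threshold: float = BRIEF_PROBE_MIN,
) -> PeriodClassTags:
    """Tag derived period classes.

    * ``sE2``: E2 periods strictly longer than ``sE2_threshold`` minutes.
    * ``sgE1``: E1 periods in a phloem phase that never reaches E2.
    * ``frE1``: E1 periods strictly between two E2 periods of the same phase.
    * ``initial_E1_followed_E2``: the first E1 of each phase that reaches E2.
    * ``E12``: one whole-phase pseudo-period per phase reaching E2.
    * ``sgD``: D periods not immediately followed by E1.
    """
    if phases is None:
        phases = find_phloem_phases(recording)
    tags = PeriodClassTags()
    periods = recording.periods
    index_of = {id(p): i for i, p in enumerate(periods)}

    for i, p in enumerate(periods):
        if p.label == wf.E2 and p.duration > sE2_threshold:
            tags.sE2.add(i)
        if p.label == wf.D:
            nxt = periods[i + 1] if i + 1 < len(periods) else None
            if nxt is None or nxt.label != wf.E1:
                tags.sgD.add(i)

    for phase in phases:
        idx = [index_of[id(p)] for p in phase.periods]
        if not phase.reaches_E2:
            for i, p in zip(idx, phase.periods):
                if p.label == wf.E1:
                    tags.sgE1.add(i)
            continue
        tags.E12.append((phase.start, phase.duration))
        labels = [p.label for p in phase.periods]
        first_e1 = next((k for k, lab in enumerate(labels) if lab == wf.E1), None)
        if first_e1 is not None and any(lab == wf.E2 for lab in labels[first_e1 + 1:]):
            tags.initial_E1_followed_E2.add(idx[first_e1])
        for k, lab in enumerate(labels):
            if lab != wf.E1:
                continue
            has_e2_before = any(l2 == wf.E2 for l2 in labels[:k])
            has_e2_after = any(l2 == wf.E2 for l2 in labels[k + 1:])
            if has_e2_before and has_e2_after:
                tags.frE1.add(idx[k])
    return tags
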