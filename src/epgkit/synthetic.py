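"""Synthetic annotation generator and targeted grammar-violation injection.

No public repository of marked EPG recordings exists, so every other module
is exercised against synthetic recordings: grammatical mark sequences built
from a probabilistic behavioural model of a phloem feeder on a host plant.
The generator emulates the *structure* of real recordings — alternating
non-probing and probing bouts, pathway activity punctuated by potential-drop
groups, occasional xylem (G) and derailed-stylet (F) bouts, phloem phases
that may or may not reach sustained ingestion, and the aphid (p-pd) or
psyllid (D) use of annotation code 11 — while making no quantitative claim
about any real species: period durations are log-normal with preset medians
chosen only to be of realistic magnitude (potential drops of a few seconds,
pathway bouts of minutes, ingestion bouts up to hours).

The generated sequence is truncated at the configured total duration by the
terminal mark, exactly as a real 8-h recording would be, and the realized
composition (every label and duration actually emitted) is returned as
ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import waveforms as wf
from .errors import GenerationError, InjectionSkip
from .model import Recording
from .io_annotations import periods_from_marks, marks_from_recording
from .model import Mark

#: per-label log-normal duration parameters: (median minutes, sigma of log)
DEFAULT_DURATIONS: dict[str, tuple[float, float]] = {
    wf.NP: (2.0, 1.0),
    wf.C: (2.5, 0.8),
    wf.PD: (0.05, 0.3),    # subphase II-1, a few seconds
    wf.PD2: (0.03, 0.3),
    wf.PD3: (0.02, 0.3),
    wf.PPD: (0.08, 0.3),
    wf.D: (1.0, 0.5),
    wf.E1E: (0.8, 0.5),
    wf.E1: (1.5, 0.7),
    wf.E2: (12.0, 1.2),    # passive ingestion, may last hours
    wf.F: (6.0, 0.8),
    wf.G: (5.0, 0.8),
}


@dataclass(frozen=True)
class GeneratorProfile:
    """Study conditions for one synthetic recording.

    The defaults describe an 8-h aphid recording; the psyllid preset swaps
    the code-11 waveform from p-pd to D.
    """

    seed: int = 0
    total_duration: float = 480.0  # 8-h recording
    preset: str = "aphid"  # "aphid" (p-pd enabled) | "psyllid" (D enabled)
    durations: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    #: potential-drop groups per minute of pathway activity
    pd_rate_per_min_C: float = 0.8
    #: mean number of within-probe elements beyond the opening pathway bout
    mean_elements_per_probe: float = 2.0
    #: chance a phloem phase reaches ingestion (E2)
    p_reach_E2: float = 0.7
    #: mean number of extra E1/E2 alternations after the first E2 (fractionation)
    mean_fractionations: float = 0.5
    #: chance a phloem phase is preceded by extracellular salivation (E1e)
    p_E1e_before_phase: float = 0.3
    #: chance a code-11 event (p-pd / D) leads into a phloem phase
    p_code11_into_phase: float = 0.5
    #: element-type weights once a cycle is not a potential drop:
    #: (phloem phase, F bout, G bout, code-11 event)
    element_weights: tuple[float, float, float, float] = (0.45, 0.15, 0.15, 0.25)

    def __post_init__(self):
        if self.preset not in ("aphid", "psyllid"):
            raise GenerationError(f"unknown preset {self.preset!r}")
        if self.total_duration <= 0:
            raise GenerationError("total_duration must be positive")
        if not (0 <= self.p_reach_E2 <= 1):
            raise GenerationError("p_reach_E2 must be a probability")

    @property
    def code11_label(self) -> str:
        return wf.PPD if self.preset == "aphid" else wf.D

    def code_map(self) -> wf.CodeMap:
        return wf.CodeMap(code11=self.code11_label)


@dataclass(frozen=True)
class GroundTruth:
    """The composition actually emitted (post-truncation)."""

    sequence: tuple[tuple[str, float], ...]  # (label, duration) in order

    def count(self, label: str) -> int:
        return sum(1 for lab, _ in self.sequence if lab == label)

    def total(self, label: str) -> float:
        return sum(d for lab, d in self.sequence if lab == label)

    def durations(self, label: str) -> list[float]:
        return [d for lab, d in self.sequence if lab == label]

    @property
    def n_pd_groups(self) -> int:
        return sum(1 for lab, _ in self.sequence if lab == wf.PD)

    @property
    def n_code11(self) -> int:
        return sum(1 for lab, _ in self.sequence if lab in (wf.PPD, wf.D))


def _dur(rng: np.random.Generator, profile: GeneratorProfile, label: str) -> float:
    median, sigma = profile.durations[label]
    return float(median * math.exp(sigma * rng.standard_normal()))


def _phloem_phase(rng, profile) -> list[str]:
    labels = []
    if rng.random() < profile.p_E1e_before_phase:
        labels.append(wf.E1E)
    labels.append(wf.E1)
    if rng.random() < profile.p_reach_E2:
        labels.append(wf.E2)
        for _ in range(rng.poisson(profile.mean_fractionations)):
            labels += [wf.E1, wf.E2]
    return labels


def _probe_labels(rng, profile) -> list[str]:
    """One probe: cycles of pathway + element, closed by a bare pathway bout."""
    labels: list[str] = []
    n_elements = 1 + int(rng.poisson(profile.mean_elements_per_probe))
    for _ in range(n_elements):
        labels.append(wf.C)
        c_dur_hint = profile.durations[wf.C][0]
        p_pd = 1.0 - math.exp(-profile.pd_rate_per_min_C * c_dur_hint)
        if rng.random() < p_pd:
            labels += [wf.PD, wf.PD2, wf.PD3]
            continue
        w = np.asarray(profile.element_weights, dtype=float)
        kind = rng.choice(4, p=w / w.sum())
        if kind == 0:
            labels += _phloem_phase(rng, profile)
        elif kind == 1:
            labels.append(wf.F)
        elif kind == 2:
            labels.append(wf.G)
        else:
            labels.append(profile.code11_label)
            if rng.random() < profile.p_code11_into_phase:
                labels.append(wf.E1)
                if rng.random() < profile.p_reach_E2:
                    labels.append(wf.E2)
    labels.append(wf.C)  # trailing pathway closes the probe
    return labels


def generate_recording(profile: GeneratorProfile) -> tuple[Recording, GroundTruth]:
    """Generate one grammatical recording plus its realized composition.

    Deterministic under a fixed profile (the seed is part of the profile).
    The behavioural sequence alternates non-probing and probing bouts until
    the configured total duration is reached; the final period is cut by the
    terminal mark.
    """
    rng = np.random.default_rng(profile.seed)
    seq: list[tuple[str, float]] = []
    t = 0.0
    guard = 0
    while t < profile.total_duration:
        guard += 1
        if guard > 100000:
            raise GenerationError("profile generates implausibly many periods")
        seq.append((wf.NP, _dur(rng, profile, wf.NP)))
        t += seq[-1][1]
        if t >= profile.total_duration:
            break
        for label in _probe_labels(rng, profile):
            d = _dur(rng, profile, label)
            seq.append((label, d))
            t += d
        # (may overshoot; truncation below trims the excess)

    # truncate at total_duration
    out: list[tuple[str, float]] = []
    t = 0.0
    for label, d in seq:
        if t + d >= profile.total_duration:
            cut = profile.total_duration - t
            if cut > 0:
                out.append((label, cut))
            break
        out.append((label, d))
        t += d
    if not out:
        raise GenerationError("total_duration too short to fit a single period")

    marks = []
    t = 0.0
    code_map = profile.code_map()
    for label, d in out:
        marks.append(Mark(code=code_map.code(label), time=t))
        t += d
    marks.append(Mark(code=wf.TERMINAL_CODE, time=profile.total_duration))
    recording = periods_from_marks(
        marks, code_map, file_name=f"synthetic_{profile.preset}_{profile.seed}.ana",
        treatment=1,
    )
    # rebuild ground truth from the recording so float round-trip is exact
    truth = GroundTruth(sequence=tuple((p.label, p.duration) for p in recording.periods))
    return recording, truth


# ---------------------------------------------------------------------------
# violation injection

def inject_violation(
    recording: Recording, rule_id: str, seed: int = 0
) -> tuple[Recording, int]:
    """Minimally edit a valid recording to violate one named rule.

    Returns the edited recording and the row at which the injected rule's
    issue is expected.  Editing may incidentally violate further rules (a
    single bad mark often breaks two guidelines); the named rule is
    guaranteed to fire at the returned row.  Raises :class:`InjectionSkip`
    when the recording offers no site for the requested violation.
    """
    rng = np.random.default_rng(seed)
    labels = list(recording.labels)
    n = len(labels)

    def pick(candidates):
        if not candidates:
            raise InjectionSkip(f"no site to inject {rule_id} in this recording")
        return candidates[int(rng.integers(len(candidates)))]

    if rule_id == "G11":
        return replace(recording, terminated=False), 0

    if rule_id == "G1":
        if n == 0 or labels[0] != wf.NP:
            raise InjectionSkip("recording does not start with Np")
        labels[0] = wf.C
        return recording.with_labels(labels), 0

    if rule_id == "G2":
        i = pick([i for i in range(n - 1) if labels[i] == wf.NP])
        labels[i + 1] = wf.E1
        return recording.with_labels(labels), i + 1

    if rule_id == "G3":
        i = pick([i for i in range(1, n) if labels[i] == wf.E2 and labels[i - 1] == wf.E1])
        labels[i - 1] = wf.C
        return recording.with_labels(labels), i

    if rule_id == "G4":
        i = pick([i for i in range(1, n) if labels[i] == wf.PD and labels[i - 1] == wf.C])
        labels[i - 1] = wf.E1E
        return recording.with_labels(labels), i

    if rule_id == "G4b":
        i = pick([i for i in range(1, n) if labels[i] in (wf.D, wf.PPD) and labels[i - 1] == wf.C])
        labels[i - 1] = wf.E1E
        return recording.with_labels(labels), i

    if rule_id == "G5":
        i = pick([i for i in range(n - 2)
                  if labels[i] == wf.PD and labels[i + 1] == wf.PD2 and labels[i + 2] == wf.PD3])
        labels[i + 1], labels[i + 2] = wf.PD3, wf.PD2
        return recording.with_labels(labels), i + 1

    if rule_id in ("G6", "G8"):
        target = wf.F if rule_id == "G6" else wf.G
        i = pick([i for i in range(1, n) if labels[i] == target and labels[i - 1] == wf.C])
        labels[i - 1] = wf.E1E
        return recording.with_labels(labels), i

    if rule_id in ("G7", "G9"):
        target = wf.F if rule_id == "G7" else wf.G
        i = pick([i for i in range(n - 1) if labels[i] == target and labels[i + 1] in (wf.C, wf.NP)])
        labels[i + 1] = wf.E1
        return recording.with_labels(labels), i + 1

    if rule_id == "G10":
        i = pick([i for i in range(n - 1) if labels[i] == wf.E1
                  and labels[i + 1] in (wf.E1E, wf.E2, wf.C, wf.NP)])
        labels[i + 1] = wf.F
        return recording.with_labels(labels), i + 1

    if rule_id == "DUP":
        i = pick(list(range(1, n)))
        labels[i] = labels[i - 1]
        return recording.with_labels(labels), i

    raise InjectionSkip(f"unknown rule id {rule_id!r}")


# ---------------------------------------------------------------------------
# truncation oracle suite

@dataclass(frozen=True)
class TruncationCase:
    """One artificial truncated-final-period scenario plus its brute-force
    true-median range (upper bound is inf when fewer than two complete
    periods exist)."""

    untruncated: tuple[float, ...]
    truncated_obs: float
    oracle_low: float
    oracle_high: float


def brute_force_median_range(
    untruncated: list[float], truncated_obs: float, grid_max: float = 1e6, grid_n: int = 4001
) -> tuple[float, float]:
    """Enumerate median(untruncated + [T]) over a dense grid T in
    [truncated_obs, grid_max] and return (min, max) of the medians."""
    from .truncation import _median

    grid = np.concatenate([
        np.linspace(truncated_obs, grid_max, grid_n),
        np.asarray(list(untruncated) + [truncated_obs], dtype=float),
    ])
    grid = grid[grid >= truncated_obs]
    meds = [_median(list(untruncated) + [float(T)]) for T in grid]
    lo, hi = min(meds), max(meds)
    if len(untruncated) <= 1:
        hi = math.inf  # median grows without bound as the true duration does
    return lo, hi


def generate_truncation_suite(seed: int = 0) -> list[TruncationCase]:
    """Scenarios mirroring artificially truncated phloem-ingestion files:
    1, 2 or 3 complete E1–E2 period pairs followed by a truncated final E2,
    each paired with its enumerated true-median range."""
    rng = np.random.default_rng(seed)
    cases: list[TruncationCase] = []
    for n_prior in (1, 2, 3):
        for scenario in ("truncated-longest", "truncated-middling"):
            prior = sorted(float(x) for x in rng.uniform(2.0, 40.0, size=n_prior))
            if scenario == "truncated-longest":
                t_obs = prior[-1] * (1.0 + float(rng.uniform(0.1, 1.0)))
            else:
                t_obs = float(rng.uniform(1.0, prior[-1]))
            lo, hi = brute_force_median_range(prior, t_obs)
            cases.append(TruncationCase(tuple(prior), t_obs, lo, hi))
    return cases
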