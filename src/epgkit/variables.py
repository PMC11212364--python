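"""Per-recording computation of the 127-variable registry.

The engine works on a segmented recording (probes, potential-drop groups,
phloem phases, period class tags) and applies the missing-data conventions
of the standardized variable list:

* counts and sums of an absent waveform are 0; its mean / median / longest
  are missing;
* time-from-recording-start variables with no defining event are set to the
  total recording duration; time-from-first-probe variables to the span from
  first-probe start to the end of the recording; within-probe times are
  missing;
* before-an-event counts with no event become the total count; after-an-event
  counts are missing;
* ratio variables with an undefined denominator are missing.

When the truncated-wave criterion is enabled, the mean and median of exactly
the waveform whose final period is cut by the terminal mark are replaced by
the estimates of :mod:`epgkit.truncation`; all other variables use plain
statistics over observed durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import waveforms as wf
from .errors import ValidationFailed
from .model import Recording
from .registry import REGISTRY, TREATMENT_SPECS
from .segmentation import (
    PdGroup,
    PeriodClassTags,
    PhloemPhase,
    Probe,
    classify_periods,
    find_phloem_phases,
    find_probes,
    group_pd_subphases,
)
from .truncation import WaveformAdjustment, apply_truncation_criterion, _median


@dataclass(frozen=True)
class VariableResult:
    """One registry variable for one recording."""

    acronym: str
    value: float | None
    missing_reason: str | None = None  # waveform-absent | rule-applied | undefined-denominator
    truncation_flag: str | None = None

    @property
    def missing(self) -> bool:
        return self.value is None


@dataclass
class ComputeOptions:
    truncated_criterion: bool = False
    mean_policy: str = "longest-include"
    sE2_threshold: float = 10.0
    brief_threshold: float = 3.0
    #: E1 index formula: "onset" mirrors the E2 index (share of time in E1
    #: from first E1 onset to end of recording); "balance" uses
    #: 100*s_E1/(s_E1+s_E2)
    e1_index_formula: str = "onset"
    order: list[str] | None = None


@dataclass
class Segmented:
    """A recording together with its derived structures."""

    recording: Recording
    probes: list[Probe]
    pd_groups: list[PdGroup]
    phases: list[PhloemPhase]
    tags: PeriodClassTags
    adjustment: WaveformAdjustment | None = None


def segment(recording: Recording, options: ComputeOptions | None = None) -> Segmented:
    options = options or ComputeOptions()
    phases = find_phloem_phases(recording)
    seg = Segmented(
        recording=recording,
        probes=find_probes(recording),
        pd_groups=group_pd_subphases(recording),
        phases=phases,
        tags=classify_periods(recording, phases, options.sE2_threshold, options.brief_threshold),
        adjustment=apply_truncation_criterion(
            recording, enabled=options.truncated_criterion, mean_policy=options.mean_policy
        ),
    )
    return seg


# ---------------------------------------------------------------------------
# small result helpers

def _value(acr, v, flag=None):
    return VariableResult(acr, float(v), truncation_flag=flag)


def _missing(acr, reason="waveform-absent", flag=None):
    return VariableResult(acr, None, missing_reason=reason, truncation_flag=flag)


def _mean(vals):
    return sum(vals) / len(vals)


def _family_durations(seg: Segmented) -> dict[str, list[float]]:
    """Duration lists per statistical family (base waveforms + derived)."""
    rec = seg.recording
    per = rec.periods
    fam: dict[str, list[float]] = {
        "Np": rec.durations(wf.NP),
        "Pr": [p.duration for p in seg.probes],
        "C": rec.durations(wf.C),
        "F": rec.durations(wf.F),
        "G": rec.durations(wf.G),
        "E1e": rec.durations(wf.E1E),
        "D": rec.durations(wf.D),
        "E1": rec.durations(wf.E1),
        "E2": rec.durations(wf.E2),
        "sgE1": [per[i].duration for i in sorted(seg.tags.sgE1)],
        "frE1": [per[i].duration for i in sorted(seg.tags.frE1)],
        "sE2": [per[i].duration for i in sorted(seg.tags.sE2)],
        "E12": [d for _, d in seg.tags.E12],
        "pd": [g.total for g in seg.pd_groups if g.kind == "standard-pd"],
        "p-pd": [g.total for g in seg.pd_groups if g.kind == "p-pd"],
    }
    return fam


_TRUNC_FAMILIES = {wf.NP: "Np", wf.C: "C", wf.F: "F", wf.G: "G",
                   wf.E1E: "E1e", wf.D: "D", wf.E1: "E1", wf.E2: "E2"}


def _family_stats(acr_prefixes, family, vals, seg) -> list[VariableResult]:
    """Emit n_/a_/m_/s_/mx_ results for one family, honouring truncation."""
    n_a, a_a, m_a, s_a, mx_a = acr_prefixes
    out = [_value(n_a, len(vals)), ]
    adj = seg.adjustment
    adjusted = adj is not None and _TRUNC_FAMILIES.get(adj.label) == family
    if vals:
        if adjusted:
            if adj.mean is None:
                out.append(_missing(a_a, "rule-applied", flag=adj.mean_flag))
            else:
                out.append(_value(a_a, adj.mean, flag=adj.mean_flag))
            out.append(_value(m_a, adj.median, flag=adj.median_method))
        else:
            out.append(_value(a_a, _mean(vals)))
            out.append(_value(m_a, _median(vals)))
        out.append(_value(s_a, sum(vals)))
        if mx_a:
            flag = None
            if adjusted and max(vals) == seg.recording.periods[-1].duration:
                flag = "max-is-truncated"
            out.append(_value(mx_a, max(vals), flag=flag))
    else:
        out.append(_missing(a_a))
        out.append(_missing(m_a))
        out.append(_value(s_a, 0.0))
        if mx_a:
            out.append(_missing(mx_a))
    return out


# ---------------------------------------------------------------------------
# event locators

def _first_period(seg, predicate):
    for i, p in enumerate(seg.recording.periods):
        if predicate(i, p):
            return i, p
    return None, None


def _first_E(seg):
    return _first_period(seg, lambda i, p: p.label in wf.PHLOEM_LABELS)


def _first_E2(seg):
    return _first_period(seg, lambda i, p: p.label == wf.E2)


def _first_sE2(seg):
    return _first_period(seg, lambda i, p: i in seg.tags.sE2)


def _probe_of(seg, period):
    if period is None or period.probe_index is None:
        return None
    return seg.probes[period.probe_index]


def _time_in_C_before(seg, probe, t):
    """Sum of C durations inside ``probe`` before time ``t``."""
    total = 0.0
    for p in probe.periods:
        if p.label == wf.C and p.start < t:
            total += min(p.end, t) - p.start
    return total


# ---------------------------------------------------------------------------
# the five compute groups

def compute_nonsequential(seg: Segmented, options: ComputeOptions | None = None) -> list[VariableResult]:
    """Counts, means, medians, sums and maxima per waveform family."""
    fam = _family_durations(seg)
    out: list[VariableResult] = []
    out += _family_stats(("n_Np", "a_Np", "m_Np", "s_Np", "mx_Np"), "Np", fam["Np"], seg)
    out += _family_stats(("n_Pr", "a_Pr", "m_Pr", "s_Pr", None), "Pr", fam["Pr"], seg)
    out.append(_value("n_bPr", sum(1 for p in seg.probes if p.brief)))
    for name in ("C", "F", "G", "E1e"):
        out += _family_stats((f"n_{name}", f"a_{name}", f"m_{name}", f"s_{name}", None), name, fam[name], seg)
    out += _family_stats(("n_D", "a_D", "m_D", "s_D", None), "D", fam["D"], seg)
    out.append(_value("n_sgD", len(seg.tags.sgD)))
    out += _family_stats(("n_sgE1", "a_sgE1", "m_sgE1", "s_sgE1", "mx_sgE1"), "sgE1", fam["sgE1"], seg)
    out += _family_stats(("n_frE1", "a_frE1", "m_frE1", "s_frE1", "mx_frE1"), "frE1", fam["frE1"], seg)
    out += _family_stats(("n_E1", "a_E1", "m_E1", "s_E1", "mx_E1"), "E1", fam["E1"], seg)
    out += _family_stats(("n_E12", "a_E12", "m_E12", "s_E12", "mx_E12"), "E12", fam["E12"], seg)
    out += _family_stats(("n_E2", "a_E2", "m_E2", "s_E2", "mx_E2"), "E2", fam["E2"], seg)
    out += _family_stats(("n_sE2", "a_sE2", "m_sE2", "s_sE2", None), "sE2", fam["sE2"], seg)
    return out


def compute_sequential_times(seg: Segmented, options: ComputeOptions | None = None) -> list[VariableResult]:
    """Times to first occurrences from the three conventional starting points."""
    rec = seg.recording
    out: list[VariableResult] = []
    probes = seg.probes

    if probes:
        out.append(_value("t > 1Pr", probes[0].start))
    else:
        out.append(VariableResult("t > 1Pr", rec.total_duration, truncation_flag="rule:set-total-duration"))

    locators = (
        ("t > 1E", _first_E),
        ("t > 1E12", lambda s: _first_E12(s)),
        ("t > 1E2", _first_E2),
        ("t > 1sE2", _first_sE2),
    )
    for acr, locate in locators:
        if not probes:
            out.append(_missing(acr, "rule-applied"))
            continue
        _, p = locate(seg)
        if p is None:
            out.append(VariableResult(acr, rec.total_duration - probes[0].start,
                                      truncation_flag="rule:set-first-probe-to-end"))
        else:
            out.append(_value(acr, p.start - probes[0].start))

    for acr, locate in (("tPr > 1E/1Pr", _first_E), ("tPr > 1E2/1Pr", _first_E2),
                        ("tPr > 1sE2/1Pr", _first_sE2)):
        _, p = locate(seg)
        probe = _probe_of(seg, p)
        if probe is None:
            out.append(_missing(acr, "rule-applied"))
        else:
            out.append(_value(acr, p.start - probe.start))
    return out


def _first_E12(seg):
    """First phloem phase that reaches ingestion, as a pseudo-period locator."""
    for phase in seg.phases:
        if phase.reaches_E2:
            return None, phase.periods[0]
    return None, None


def compute_sequential_counts_durations(seg: Segmented, options: ComputeOptions | None = None) -> list[VariableResult]:
    """Before/after-event counts and durations of the phloem-related variables."""
    rec = seg.recording
    probes = seg.probes
    per = rec.periods
    out: list[VariableResult] = []

    _, firstE = _first_E(seg)
    _, firstE2 = _first_E2(seg)
    i_sE2, first_sE2 = _first_sE2(seg)

    # --- before/after probe counts
    def before_counts(acr_all, acr_brief, ref_period):
        if ref_period is None or ref_period.probe_index is None:
            flag = "rule:set-total-count"
            yield VariableResult(acr_all, float(len(probes)), truncation_flag=flag)
            if acr_brief:
                yield VariableResult(acr_brief, float(sum(1 for p in probes if p.brief)), truncation_flag=flag)
        else:
            k = ref_period.probe_index
            yield _value(acr_all, k)
            if acr_brief:
                yield _value(acr_brief, sum(1 for p in probes[:k] if p.brief))

    out += list(before_counts("n_Pr > 1E", "n_brPr > 1E", firstE))
    out += list(before_counts("n_Pr > 1E2", None, firstE2))
    out += list(before_counts("n_Pr > 1sE2", None, first_sE2))

    if first_sE2 is None:
        out.append(VariableResult("n_E2 > 1sE2", float(len(rec.durations(wf.E2))),
                                  truncation_flag="rule:set-total-count"))
    else:
        out.append(_value("n_E2 > 1sE2",
                          sum(1 for i, p in enumerate(per) if p.label == wf.E2 and i < i_sE2)))

    def after_counts(acr, ref_period, brief_only=False):
        if ref_period is None or ref_period.probe_index is None:
            return _missing(acr, "rule-applied")
        k = ref_period.probe_index
        rest = probes[k + 1:]
        if brief_only:
            return _value(acr, sum(1 for p in rest if p.brief))
        return _value(acr, len(rest))

    out.append(after_counts("n_Pr.after1E", firstE))
    out.append(after_counts("n_bPr.after1E", firstE, brief_only=True))
    out.append(after_counts("n_ Pr < 1sE2", first_sE2))

    # --- durations
    if probes:
        out.append(_value("d_1Pr", probes[0].duration))
    else:
        out.append(_missing("d_1Pr"))

    np_durs = rec.durations(wf.NP)
    out.append(_value("d_2Np", np_durs[1]) if len(np_durs) >= 2 else _missing("d_2Np"))

    out.append(_value("d_1st_E", seg.phases[0].duration) if seg.phases else _missing("d_1st_E"))
    out.append(_value("d_1st_E2", firstE2.duration) if firstE2 is not None else _missing("d_1st_E2"))

    if firstE is None:
        out.append(_missing("s_np.1E", "rule-applied"))
    else:
        out.append(_value("s_np.1E", sum(p.duration for p in per
                                         if p.label == wf.NP and p.start < firstE.start)))

    # time in C before the first E of selected probes
    def c_before_first_E(probe):
        first = next((p for p in probe.periods if p.label in wf.PHLOEM_LABELS), None)
        if first is None:
            return None
        return _time_in_C_before(seg, probe, first.start)

    probe_of_firstE = _probe_of(seg, firstE)
    out.append(_value("tC > 1E/1Pr", c_before_first_E(probe_of_firstE))
               if probe_of_firstE is not None else _missing("tC > 1E/1Pr", "rule-applied"))

    probe_of_first_sE2 = _probe_of(seg, first_sE2)
    if probe_of_first_sE2 is None:
        out.append(_missing("tC > 1sE2/1Pr", "rule-applied"))
    else:
        out.append(_value("tC > 1sE2/1Pr", _time_in_C_before(seg, probe_of_first_sE2, first_sE2.start)))

    c_times = [c_before_first_E(p) for p in probes]
    c_times = [t for t in c_times if t is not None]
    if c_times:
        out.append(_value("atC > 1E/Pr", _mean(c_times)))
        out.append(_value("mntC > 1E/Pr", min(c_times)))
    else:
        out.append(_missing("atC > 1E/Pr", "rule-applied"))
        out.append(_missing("mntC > 1E/Pr", "rule-applied"))

    # E1 periods immediately followed by (sustained) E2
    d_e1_e2 = [per[i].duration for i in range(len(per) - 1)
               if per[i].label == wf.E1 and per[i + 1].label == wf.E2]
    d_e1_se2 = [per[i].duration for i in range(len(per) - 1)
                if per[i].label == wf.E1 and (i + 1) in seg.tags.sE2]
    out.append(_value("d_E1followedbyE2", sum(d_e1_e2)) if d_e1_e2 else _missing("d_E1followedbyE2", "rule-applied"))
    out.append(_value("d_E1followedbysE2", sum(d_e1_se2)) if d_e1_se2 else _missing("d_E1followedbysE2", "rule-applied"))

    init_e1 = [per[i].duration for i in sorted(seg.tags.initial_E1_followed_E2)]
    out.append(_value("a_1st E1_followed_E2", _mean(init_e1)) if init_e1
               else _missing("a_1st E1_followed_E2", "rule-applied"))

    e2_by_phase = [ph.e2_total for ph in seg.phases if ph.reaches_E2]
    out.append(_value("a_s_E2/phloem_ph", _mean(e2_by_phase)) if e2_by_phase
               else _missing("a_s_E2/phloem_ph", "rule-applied"))
    return out


def compute_potential_indices(seg: Segmented, options: ComputeOptions | None = None) -> list[VariableResult]:
    """Proportion-of-time indices over behaviourally defined denominators."""
    options = options or ComputeOptions()
    rec = seg.recording
    out: list[VariableResult] = []
    s_Pr = sum(p.duration for p in seg.probes)
    sums = {lab: sum(rec.durations(lab)) for lab in (wf.C, wf.F, wf.G, wf.E1, wf.E2)}

    for lab, acr in ((wf.C, "%probtimeinC"), (wf.F, "%probtimeinF"), (wf.G, "%probtimeinG"),
                     (wf.E1, "%probtimeinE1"), (wf.E2, "%probtimeinE2")):
        if s_Pr > 0:
            out.append(_value(acr, 100.0 * sums[lab] / s_Pr))
        else:
            out.append(_missing(acr, "undefined-denominator"))

    out.append(_value("E2/C_ratio", sums[wf.E2] / sums[wf.C]) if sums[wf.C] > 0
               else _missing("E2/C_ratio", "undefined-denominator"))

    _, firstE1 = _first_period(seg, lambda i, p: p.label == wf.E1)
    if firstE1 is None:
        out.append(_missing("E1_index", "rule-applied"))
    elif options.e1_index_formula == "balance":
        denom = sums[wf.E1] + sums[wf.E2]
        out.append(_value("E1_index", 100.0 * sums[wf.E1] / denom) if denom > 0
                   else _missing("E1_index", "undefined-denominator"))
    else:
        denom = rec.total_duration - firstE1.start
        out.append(_value("E1_index", 100.0 * sums[wf.E1] / denom) if denom > 0
                   else _missing("E1_index", "undefined-denominator"))

    n_e1 = len(rec.durations(wf.E1))
    out.append(_value("frE1_ratio", len(seg.tags.frE1) / n_e1) if n_e1 > 0
               else _missing("frE1_ratio", "undefined-denominator"))

    _, firstE2 = _first_E2(seg)
    if firstE2 is None:
        out.append(_missing("E2_index", "rule-applied"))
    else:
        denom = rec.total_duration - firstE2.start
        out.append(_value("E2_index", 100.0 * sums[wf.E2] / denom) if denom > 0
                   else _missing("E2_index", "undefined-denominator"))

    n_e2 = len(rec.durations(wf.E2))
    out.append(_value("%_sE2", 100.0 * len(seg.tags.sE2) / n_e2) if n_e2 > 0
               else _missing("%_sE2", "undefined-denominator"))

    if seg.phases:
        failing = sum(1 for ph in seg.phases if not ph.reaches_E2)
        out.append(_value("%Phloem_ph_fail", 100.0 * failing / len(seg.phases)))
    else:
        out.append(_missing("%Phloem_ph_fail", "undefined-denominator"))
    return out


def compute_pd_variables(seg: Segmented, options: ComputeOptions | None = None) -> list[VariableResult]:
    """Potential-drop group statistics, timing and per-probe summaries."""
    rec = seg.recording
    out: list[VariableResult] = []
    std = [g for g in seg.pd_groups if g.kind == "standard-pd"]
    ppd = [g for g in seg.pd_groups if g.kind == "p-pd"]

    def stats(prefixes, vals):
        n_a, a_a, m_a, s_a = prefixes
        res = [_value(n_a, len(vals))] if n_a else []
        if vals:
            res += [_value(a_a, _mean(vals)), _value(m_a, _median(vals)), _value(s_a, sum(vals))]
        else:
            res += [_missing(a_a), _missing(m_a), _value(s_a, 0.0)]
        return res

    out += stats(("n_pd", "a_pd", "m_pd", "s_pd"), [g.total for g in std])

    s_C = sum(rec.durations(wf.C))
    out.append(_value("n_pd/minC", len(std) / s_C) if s_C > 0
               else _missing("n_pd/minC", "undefined-denominator"))

    for sub, attr in (("II-1", "dur_II1"), ("II-2", "dur_II2"), ("II-3", "dur_II3")):
        vals = [getattr(g, attr) for g in std if getattr(g, attr) is not None]
        out += stats((None, f"a_pd {sub}", f"m_pd {sub}", f"s_pd {sub}"), vals)

    if std:
        out.append(_value("t > 1pd", std[0].start))
    else:
        out.append(VariableResult("t > 1pd", rec.total_duration, truncation_flag="rule:set-total-duration"))

    first_probe_pds = [g for g in std if g.probe_index == 0]
    if seg.probes and first_probe_pds:
        out.append(_value("t > 1pd/1Pr", first_probe_pds[0].start - seg.probes[0].start))
    else:
        out.append(_missing("t > 1pd/1Pr", "rule-applied"))

    # per-probe first-pd latencies
    latencies = []
    probes_with_pd = set()
    for g in std:
        if g.probe_index >= 0:
            probes_with_pd.add(g.probe_index)
    for idx in sorted(probes_with_pd):
        first = min(g.start for g in std if g.probe_index == idx)
        latencies.append(first - seg.probes[idx].start)
    if latencies:
        out.append(_value("at > 1pd/Pr", _mean(latencies)))
        out.append(_value("m_Pr > 1pd", _median(latencies)))
        out.append(_value("mnt_1pd/1pd", min(latencies)))
    else:
        out.append(_missing("at > 1pd/Pr", "rule-applied"))
        out.append(_missing("m_Pr > 1pd", "rule-applied"))
        out.append(_missing("mnt_1pd/1pd", "rule-applied"))

    out.append(_value("n_pd/1Pr", len(first_probe_pds)) if seg.probes else _missing("n_pd/1Pr", "rule-applied"))

    if seg.probes:
        out.append(_value("%_Pr_pd", 100.0 * len(probes_with_pd) / len(seg.probes)))
    else:
        out.append(_missing("%_Pr_pd", "undefined-denominator"))

    if std:
        out.append(_value("n_Pr > 1pd", min(g.probe_index for g in std)))
    else:
        out.append(VariableResult("n_Pr > 1pd", float(len(seg.probes)), truncation_flag="rule:set-total-count"))

    first5 = std[:5]
    ii3 = sum(g.dur_II3 for g in first5 if g.dur_II3 is not None)
    flag = "fewer-than-5-pds" if len(std) < 5 else None
    out.append(VariableResult("s_pdII-3/5pd", float(ii3), truncation_flag=flag))

    out += stats(("n_p-pd", "a_p-pd", "m_p-pd", "s_p-pd"), [g.total for g in ppd])
    return out


def compute_all(
    recording: Recording,
    options: ComputeOptions | None = None,
    issues=None,
    force: bool = False,
) -> list[VariableResult]:
    """Compute the full 127-variable registry for one recording, in order.

    ``issues`` may carry the validator's output; any unresolved issue blocks
    computation unless ``force`` is set.
    """
    options = options or ComputeOptions()
    if issues and not force:
        raise ValidationFailed(
            f"recording {recording.file_name!r} has {len(issues)} unresolved "
            "sequence issues; fix them or pass force=True",
            issues=issues,
        )
    seg = segment(recording, options)
    results: list[VariableResult] = []
    results += compute_nonsequential(seg, options)
    results += compute_sequential_times(seg, options)
    results += compute_sequential_counts_durations(seg, options)
    results += compute_potential_indices(seg, options)
    results += compute_pd_variables(seg, options)

    by_acr = {r.acronym: r for r in results}
    missing = [s.acronym for s in REGISTRY if s.acronym not in by_acr]
    extra = [a for a in by_acr if a not in {s.acronym for s in REGISTRY}]
    if missing or extra:  # internal consistency guard
        raise RuntimeError(f"registry mismatch: missing={missing} extra={extra}")
    from .registry import ordered_acronyms

    return [by_acr[a] for a in ordered_acronyms(options.order)]


def treatment_percentages(results_per_recording: list[list[VariableResult]]) -> list[VariableResult]:
    """Treatment-level shares of insects showing E2 / sustained E2.

    Takes the per-recording registry results of every recording in one
    treatment; each recording is one insect (the statistical replicate).
    """
    if not results_per_recording:
        raise ValueError("treatment_percentages needs at least one recording")

    def has(results, acronym):
        r = next(x for x in results if x.acronym == acronym)
        return r.value is not None and r.value > 0

    n = len(results_per_recording)
    with_e2 = sum(1 for res in results_per_recording if has(res, "n_E2"))
    with_se2 = sum(1 for res in results_per_recording if has(res, "n_sE2"))
    return [
        VariableResult("%_E2/Tr", 100.0 * with_e2 / n),
        VariableResult("%_sE2/Tr", 100.0 * with_se2 / n),
    ]
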