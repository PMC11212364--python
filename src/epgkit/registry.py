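"""Declarative registry of the 127 per-recording feeding-behaviour variables.

Each entry names one variable of the standardized EPG variable list: its
acronym (``n_`` count, ``a_`` mean, ``m_`` median, ``s_`` sum, ``mx_``
longest, ``t >`` time-to, ``d_`` duration-of, ``%`` proportion), its full
descriptive name, its category, whether the Sarria workbook computes the
same variable (53 of the 127 are shared), and the rule applied when the
defining event is absent from the recording:

* ``zero``                  — counts and sums of an absent waveform are 0
* ``missing``               — mean/median/longest of an absent waveform, and
                              every after-an-event or within-probe variable
* ``set-total-duration``    — time-from-recording-start variables with no
                              event are set to the total recording duration
* ``set-first-probe-to-end``— time-from-first-probe variables with no event
                              span first-probe start to end of recording
* ``set-total-count``       — before-an-event counts with no event become
                              the total count
* ``defined``               — always computable on a non-degenerate recording

Two treatment-level percentages (share of insects showing E2 / sustained
E2) are computed across recordings and therefore live outside this
per-recording registry; see :func:`epgkit.variables.treatment_percentages`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

CATEGORIES = (
    "nonsequential",
    "sequential-time",
    "sequential-count",
    "sequential-duration",
    "potential-index",
    "pd",
)


@dataclass(frozen=True)
class VariableSpec:
    acronym: str
    description: str
    category: str
    shared_with_sarria: bool
    missing_rule: str


def _v(acronym, description, category, shared, rule):
    return VariableSpec(acronym, description, category, shared, rule)


# canonical order follows the published variable table
REGISTRY: tuple[VariableSpec, ...] = (
    # --- non-probing -------------------------------------------------------
    _v("n_Np", "Number of periods of non-probing (Np)", "nonsequential", True, "zero"),
    _v("a_Np", "Average duration of Np periods", "nonsequential", True, "missing"),
    _v("m_Np", "Median duration of Np periods", "nonsequential", False, "missing"),
    _v("s_Np", "Sum duration of all periods of Np", "nonsequential", True, "zero"),
    _v("mx_Np", "Maximum Np period duration", "nonsequential", False, "missing"),
    _v("d_2Np", "Duration of the second non-probe period", "sequential-duration", True, "missing"),
    # --- probes ------------------------------------------------------------
    _v("n_Pr", "Number of probes (Pr)", "nonsequential", True, "zero"),
    _v("a_Pr", "Average probe duration", "nonsequential", False, "missing"),
    _v("m_Pr", "Median probe duration", "nonsequential", False, "missing"),
    _v("s_Pr", "Sum duration of all probes", "nonsequential", True, "zero"),
    _v("d_1Pr", "Duration of 1st probe", "sequential-duration", True, "missing"),
    _v("n_bPr", "Number of short probes (< 3 min)", "nonsequential", True, "zero"),
    # --- pathway -----------------------------------------------------------
    _v("n_C", "Number of periods of C", "nonsequential", True, "zero"),
    _v("a_C", "Average duration of C periods", "nonsequential", True, "missing"),
    _v("m_C", "Median duration of C periods", "nonsequential", False, "missing"),
    _v("s_C", "Sum duration of all periods of C", "nonsequential", True, "zero"),
    # --- derailed stylet mechanics ----------------------------------------
    _v("n_F", "Number of periods of F", "nonsequential", True, "zero"),
    _v("a_F", "Average duration of F periods", "nonsequential", True, "missing"),
    _v("m_F", "Median duration of F periods", "nonsequential", False, "missing"),
    _v("s_F", "Sum duration of all periods of F", "nonsequential", True, "zero"),
    # --- xylem ingestion ---------------------------------------------------
    _v("n_G", "Number of periods of G", "nonsequential", True, "zero"),
    _v("a_G", "Average duration of G periods", "nonsequential", True, "missing"),
    _v("m_G", "Median duration G periods", "nonsequential", False, "missing"),
    _v("s_G", "Sum duration of all periods of G", "nonsequential", True, "zero"),
    # --- extracellular salivation -----------------------------------------
    _v("n_E1e", "Number of periods of E1e", "nonsequential", True, "zero"),
    _v("a_E1e", "Average duration of E1e periods", "nonsequential", True, "missing"),
    _v("m_E1e", "Median duration of E1e periods", "nonsequential", False, "missing"),
    _v("s_E1e", "Sum duration of all periods of E1e", "nonsequential", True, "zero"),
    # --- first phloem contact (psyllids) ----------------------------------
    _v("n_D", "Number of periods of D", "nonsequential", False, "zero"),
    _v("a_D", "Average duration of D periods", "nonsequential", False, "missing"),
    _v("m_D", "Median duration of D periods", "nonsequential", False, "missing"),
    _v("s_D", "Sum duration of all periods of D", "nonsequential", False, "zero"),
    _v("n_sgD", "Number of periods of single D", "nonsequential", False, "zero"),
    # --- phloem phase ------------------------------------------------------
    _v("d_1st_E", "Duration of the first phloem phase", "sequential-duration", True, "missing"),
    _v("n_sgE1", "Number of periods of single E1", "nonsequential", True, "zero"),
    _v("a_sgE1", "Average duration sgE1 periods", "nonsequential", False, "missing"),
    _v("m_sgE1", "Median duration sgE1 periods", "nonsequential", False, "missing"),
    _v("s_sgE1", "Sum duration of all periods of sgE1", "nonsequential", True, "zero"),
    _v("mx_sgE1", "Longest period of sgE1", "nonsequential", False, "missing"),
    _v("n_frE1", "Number of periods of frE1", "nonsequential", False, "zero"),
    _v("a_frE1", "Average duration of frE1 periods", "nonsequential", False, "missing"),
    _v("m_frE1", "Median duration of frE1 periods", "nonsequential", False, "missing"),
    _v("s_frE1", "Sum duration of all periods of frE1", "nonsequential", False, "zero"),
    _v("mx_frE1", "Longest period of frE1", "nonsequential", False, "missing"),
    _v("n_E1", "Number of periods of E1", "nonsequential", True, "zero"),
    _v("a_E1", "Average duration of E1 periods", "nonsequential", True, "missing"),
    _v("m_E1", "Median duration of E1 periods", "nonsequential", False, "missing"),
    _v("s_E1", "Sum duration of all periods of E1", "nonsequential", True, "zero"),
    _v("mx_E1", "Longest period of E1", "nonsequential", False, "missing"),
    _v("a_1st E1_followed_E2", "Mean duration of initial E1 in phloem phase", "sequential-duration", False, "missing"),
    _v("n_E12", "Number of periods of E12", "nonsequential", False, "zero"),
    _v("a_E12", "Average duration of E12 periods", "nonsequential", False, "missing"),
    _v("m_E12", "Median duration of E12 periods", "nonsequential", False, "missing"),
    _v("s_E12", "Sum duration of all periods of E12", "nonsequential", False, "zero"),
    _v("mx_E12", "Longest period of E12", "nonsequential", False, "missing"),
    _v("n_E2", "Number of periods of E2", "nonsequential", True, "zero"),
    _v("a_E2", "Average duration of E2 periods", "nonsequential", True, "missing"),
    _v("m_E2", "Median duration of E2 periods", "nonsequential", False, "missing"),
    _v("s_E2", "Sum duration of all periods of E2", "nonsequential", True, "zero"),
    _v("a_s_E2/phloem_ph", "Mean duration of E2 per phloem phase", "sequential-duration", False, "missing"),
    _v("mx_E2", "Longest period of E2", "nonsequential", True, "missing"),
    _v("d_1st_E2", "Duration of the 1st E2 in the recording", "sequential-duration", True, "missing"),
    _v("n_sE2", "Number of periods of sE2", "nonsequential", True, "zero"),
    _v("a_sE2", "Average duration of sE2 periods", "nonsequential", False, "missing"),
    _v("m_sE2", "Median duration of sE2 periods", "nonsequential", False, "missing"),
    _v("s_sE2", "Sum duration of all periods of sE2", "nonsequential", False, "zero"),
    # --- sequential: times -------------------------------------------------
    _v("t > 1Pr", "Time to 1st probe from start of recording", "sequential-time", True, "set-total-duration"),
    _v("t > 1E", "Time to 1st E from start of 1st probe", "sequential-time", True, "set-first-probe-to-end"),
    _v("t > 1E12", "Time to the 1st E12 from start of 1st probe", "sequential-time", False, "set-first-probe-to-end"),
    _v("t > 1E2", "Time to the 1st E2 from start of 1st probe", "sequential-time", True, "set-first-probe-to-end"),
    _v("t > 1sE2", "Time to 1st sE2 from start of 1st probe", "sequential-time", False, "set-first-probe-to-end"),
    _v("tPr > 1E/1Pr", "Time from the beginning of that probe to 1st E", "sequential-time", True, "missing"),
    _v("tPr > 1E2/1Pr", "Time from the beginning of that probe to 1st E2", "sequential-time", True, "missing"),
    _v("tPr > 1sE2/1Pr", "Time from the beginning of that probe to 1st sE2", "sequential-time", True, "missing"),
    # --- sequential: durations --------------------------------------------
    _v("tC > 1E/1Pr", "Time in C to 1stE in 1st probe with E", "sequential-duration", False, "missing"),
    _v("tC > 1sE2/1Pr", "Time in C to 1st sE2 in 1st probe with sE2", "sequential-duration", False, "missing"),
    _v("atC > 1E/Pr", "Average time in C to 1stE in probes with E", "sequential-duration", False, "missing"),
    _v("mntC > 1E/Pr", "Minimum time in C to 1st E in probes with E", "sequential-duration", True, "missing"),
    _v("s_np.1E", "Total duration of non-probing before the 1st E in the recording", "sequential-duration", True, "missing"),
    # --- sequential: counts ------------------------------------------------
    _v("n_Pr > 1E", "Number of probes before 1st E in the recording", "sequential-count", True, "set-total-count"),
    _v("n_brPr > 1E", "Number of brief probes (< 3min) before 1st E in the recording", "sequential-count", True, "set-total-count"),
    _v("n_Pr > 1E2", "Number of probes before 1st E2 in the recording", "sequential-count", False, "set-total-count"),
    _v("n_Pr > 1sE2", "Number of probes before 1st sE2 in the recording", "sequential-count", False, "set-total-count"),
    _v("n_E2 > 1sE2", "Number of E2 before 1st sE2 in the recording", "sequential-count", False, "set-total-count"),
    _v("n_Pr.after1E", "Number of probes after 1st E in the recording", "sequential-count", True, "missing"),
    _v("n_bPr.after1E", "Number of brief probes (< 3 min) after 1st E in the recording", "sequential-count", False, "missing"),
    _v("n_ Pr < 1sE2", "Number of probes after 1st sE2 in the recording", "sequential-count", False, "missing"),
    _v("d_E1followedbyE2", "Duration of E1 followed by E2", "sequential-duration", False, "missing"),
    _v("d_E1followedbysE2", "Duration of E1 followed by sE2", "sequential-duration", False, "missing"),
    # --- potential indices -------------------------------------------------
    _v("E2/C_ratio", "E2/C ratio", "potential-index", False, "missing"),
    _v("E1_index", "E1 index", "potential-index", False, "missing"),
    _v("frE1_ratio", "E fractioning ratio", "potential-index", False, "missing"),
    _v("E2_index", "E2 index", "potential-index", True, "missing"),
    _v("%probtimeinC", "% of probing time spent in C", "potential-index", True, "missing"),
    _v("%probtimeinF", "% of probing time spent in F", "potential-index", True, "missing"),
    _v("%probtimeinG", "% of probing time spent in G", "potential-index", True, "missing"),
    _v("%probtimeinE1", "% of probing time spent in E1", "potential-index", True, "missing"),
    _v("%probtimeinE2", "% of probing time spent in E2", "potential-index", True, "missing"),
    _v("%_sE2", "% of E2s that are sustained E2s (> 10 min)", "potential-index", True, "missing"),
    _v("%Phloem_ph_fail", "% of phloem phases that fail to achieve ingestion", "potential-index", False, "missing"),
    # --- potential drops ---------------------------------------------------
    _v("n_pd", "Number of pds", "pd", True, "zero"),
    _v("n_pd/minC", "Number of pds per minute of pathway phase", "pd", False, "missing"),
    _v("a_pd", "Average duration of pds", "pd", True, "missing"),
    _v("m_pd", "Median duration of pds", "pd", False, "missing"),
    _v("s_pd", "Sum duration of all pds", "pd", True, "zero"),
    _v("a_pd II-1", "Average pd II-1 duration", "pd", False, "missing"),
    _v("m_pd II-1", "Median pd II-1 duration", "pd", False, "missing"),
    _v("s_pd II-1", "Sum of time pd II-1 periods", "pd", False, "zero"),
    _v("a_pd II-2", "Average pd II-2 duration", "pd", False, "missing"),
    _v("m_pd II-2", "Median pd II-2 duration", "pd", False, "missing"),
    _v("s_pd II-2", "Sum of time pd II-2 periods", "pd", False, "zero"),
    _v("a_pd II-3", "Average pd II-3 duration", "pd", False, "missing"),
    _v("m_pd II-3", "Median pd II-3 duration", "pd", False, "missing"),
    _v("s_pd II-3", "Sum of time pd II-3 periods", "pd", False, "zero"),
    _v("t > 1pd", "Time to 1st pd", "pd", False, "set-total-duration"),
    _v("t > 1pd/1Pr", "Time to 1st pd in 1st probe", "pd", False, "missing"),
    _v("at > 1pd/Pr", "Average time to 1st pd in a probe for all probes with pds", "pd", False, "missing"),
    _v("m_Pr > 1pd", "Median time to 1st pd in a probe for all probes with pds", "pd", False, "missing"),
    _v("mnt_1pd/1pd", "Minimum time to 1st pd in a probe among all probes with pds", "pd", False, "missing"),
    _v("n_pd/1Pr", "Number of pds in 1st probe", "pd", False, "missing"),
    _v("%_Pr_pd", "% probes with at least one pd", "pd", False, "missing"),
    _v("n_Pr > 1pd", "Number of probes before 1st pd", "pd", False, "set-total-count"),
    _v("s_pdII-3/5pd", "Sum duration of II-3 in 1st 5 pds", "pd", False, "zero"),
    _v("n_p-pd", "Number of phloem pds", "pd", False, "zero"),
    _v("a_p-pd", "Average duration of p-pd", "pd", False, "missing"),
    _v("m_p-pd", "Median duration of p-pd", "pd", False, "missing"),
    _v("s_p-pd", "Total duration summed over all phloem pds", "pd", False, "zero"),
)

#: treatment-level variables (computed across the recordings of a treatment)
TREATMENT_SPECS: tuple[VariableSpec, ...] = (
    _v("%_E2/Tr", "% insects with E2", "potential-index", False, "defined"),
    _v("%_sE2/Tr", "% insects with sE2", "potential-index", False, "defined"),
)

ACRONYMS: tuple[str, ...] = tuple(spec.acronym for spec in REGISTRY)
_BY_ACRONYM = {spec.acronym: spec for spec in REGISTRY}


def get(acronym: str) -> VariableSpec:
    try:
        return _BY_ACRONYM[acronym]
    except KeyError:
        raise ConfigError(f"unknown variable acronym {acronym!r}") from None


def shared_with_sarria() -> tuple[VariableSpec, ...]:
    return tuple(s for s in REGISTRY if s.shared_with_sarria)


def ordered_acronyms(order: list[str] | None = None, available: list[str] | None = None) -> list[str]:
    """Resolve a (possibly partial) user ordering against the registry.

    Acronyms listed in ``order`` come first; the remainder follow in
    canonical registry order.  Unknown acronyms raise :class:`ConfigError`.
    """
    base = list(ACRONYMS)
    if available is not None:
        extras = [a for a in available if a not in _BY_ACRONYM]
        base = [a for a in base if a in set(available)] + extras
    if not order:
        return base
    for a in order:
        if a not in _BY_ACRONYM:
            raise ConfigError(f"unknown variable acronym {a!r} in ordering")
    rest = [a for a in base if a not in set(order)]
    return [a for a in order if a in set(base)] + rest


def reference_table() -> str:
    """Markdown reference of the registry (acronym, name, category, rules)."""
    lines = [
        "| Acronym | Variable | Category | Shared with Sarria | Missing rule |",
        "|---|---|---|---|---|",
    ]
    for s in REGISTRY:
        lines.append(
            f"| {s.acronym} | {s.description} | {s.category} | "
            f"{'yes' if s.shared_with_sarria else 'no'} | {s.missing_rule} |"
        )
    return "\n".join(lines)
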