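"""Waveform labels and the integer code map used in annotation files.

EPG acquisition software stores a recording's behavioural annotation as an
ordered list of (integer code, timestamp) marks.  Each code denotes the onset
of one waveform; the label vocabulary covers the behaviours of phloem-feeding
hemipterans:

* ``Np``     non-probing (stylets out of the tissue)
* ``C``      intercellular stylet pathway
* ``pd``     standard potential drop, onset = subphase II-1
* ``pdII-2``/``pdII-3``  the later potential-drop subphases
* ``D``      first phloem contact (psyllids)
* ``p-pd``   phloem potential drop (aphids); shares code 11 with ``D``
* ``E1e``    putative extracellular watery salivation
* ``E1``     salivation into sieve elements
* ``E2``     passive phloem sap ingestion
* ``F``      derailed stylet mechanics
* ``G``      active xylem ingestion
* ``T``      terminal mark closing the recording (code 99)
"""

from __future__ import annotations

from dataclasses import dataclass, field

NP = "Np"
C = "C"
PD = "pd"          # potential-drop onset == subphase II-1
PD2 = "pdII-2"
PD3 = "pdII-3"
D = "D"
PPD = "p-pd"
E1E = "E1e"
E1 = "E1"
E2 = "E2"
F = "F"
G = "G"
T = "T"

#: every label a Period may carry (terminal mark excluded — it is a boundary)
PERIOD_LABELS = (NP, C, PD, PD2, PD3, D, PPD, E1E, E1, E2, F, G)

#: labels forming a phloem phase
PHLOEM_LABELS = frozenset({E1, E2})

#: labels belonging to a potential-drop subphase group
PD_GROUP_LABELS = frozenset({PD, PD2, PD3, PPD})

TERMINAL_CODE = 99
CODE11 = 11

#: default numeric code assignment; only 11 (D / p-pd) and 99 (T) are fixed by
#: convention, the rest are configurable.
DEFAULT_CODES = {
    1: NP,
    2: C,
    3: E1E,
    4: E1,
    5: E2,
    6: F,
    7: G,
    8: PD,
    9: PD2,
    10: PD3,
}


@dataclass(frozen=True)
class CodeMap:
    """Mapping from integer annotation codes to waveform labels.

    ``code11`` selects how the shared code 11 is read: ``"D"`` for psyllid
    recordings (first phloem contact) or ``"p-pd"`` for aphid recordings
    (phloem potential drop).  The mapping must be injective and must route
    code 99 to the terminal mark.
    """

    code11: str = PPD
    codes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self):
        if self.code11 not in (D, PPD):
            raise ValueError(f"code11 mode must be 'D' or 'p-pd', got {self.code11!r}")
        labels = list(self.codes.values())
        if len(set(labels)) != len(labels):
            raise ValueError("code map is not injective")
        for code, label in self.codes.items():
            if code in (CODE11, TERMINAL_CODE):
                raise ValueError(f"code {code} is reserved and cannot be remapped")
            if label not in PERIOD_LABELS:
                raise ValueError(f"unknown waveform label {label!r} for code {code}")

    def label(self, code: int) -> str:
        """Resolve an integer code to its waveform label."""
        if code == TERMINAL_CODE:
            return T
        if code == CODE11:
            return self.code11
        try:
            return self.codes[code]
        except KeyError:
            raise KeyError(f"annotation code {code} is not in the code map") from None

    def code(self, label: str) -> int:
        """Inverse lookup: waveform label to integer code."""
        if label == T:
            return TERMINAL_CODE
        if label == self.code11:
            return CODE11
        for code, lab in self.codes.items():
            if lab == label:
                return code
        raise KeyError(f"label {label!r} has no code in this map")

    @property
    def enabled_labels(self) -> tuple[str, ...]:
        return tuple(self.codes.values()) + (self.code11, T)
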