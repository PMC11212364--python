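"""Run configuration: a single YAML file replaces the workbook's Tools panel.

Example::

    dialect: stylet          # or windaq
    time_unit: seconds       # stylet timestamps; converted to minutes
    code11: p-pd             # or D (psyllids)
    codes: {1: Np, 2: C, 3: E1e, 4: E1, 5: E2, 6: F, 7: G, 8: pd, 9: pdII-2, 10: pdII-3}
    truncated_criterion: true
    mean_policy: longest-include
    skip_g1: false           # insects already probing at recording start
    skip_g4b: false
    transpose: false
    missing_token: ""
    order: [n_Pr, s_E2]      # partial ordering; the rest follow registry order
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from . import waveforms as wf
from .errors import ConfigError
from .validation import GuidelineSet
from .variables import ComputeOptions


@dataclass
class RunOptions:
    dialect: str = "stylet"
    time_unit: str = "seconds"
    code11: str = wf.PPD
    codes: dict[int, str] = field(default_factory=lambda: dict(wf.DEFAULT_CODES))
    truncated_criterion: bool = False
    mean_policy: str = "longest-include"
    sE2_threshold: float = 10.0
    brief_threshold: float = 3.0
    e1_index_formula: str = "onset"
    skip_g1: bool = False
    skip_g4b: bool = False
    transpose: bool = False
    missing_token: str = ""
    order: list[str] | None = None
    force: bool = False
    temporal_mode: str = "by-hour"
    hours: list[int] | None = None

    def code_map(self) -> wf.CodeMap:
        return wf.CodeMap(code11=self.code11, codes=dict(self.codes))

    def guidelines(self) -> GuidelineSet:
        return GuidelineSet.default(skip_g1=self.skip_g1, skip_g4b=self.skip_g4b)

    def compute_options(self) -> ComputeOptions:
        return ComputeOptions(
            truncated_criterion=self.truncated_criterion,
            mean_policy=self.mean_policy,
            sE2_threshold=self.sE2_threshold,
            brief_threshold=self.brief_threshold,
            e1_index_formula=self.e1_index_formula,
            order=self.order,
        )


_FIELDS = set(RunOptions.__dataclass_fields__)


def load_config(path) -> RunOptions:
    """Load a YAML config file into :class:`RunOptions`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "codes" in data:
        data["codes"] = {int(k): str(v) for k, v in data["codes"].items()}
    opts = RunOptions(**data)
    opts.code_map()  # validate early
    opts.guidelines()
    return opts
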