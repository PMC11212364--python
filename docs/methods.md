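# Methods

## Data model

A recording is an ordered list of labelled half-open periods
`[start, start + duration)` in real minutes, tiling `[0, total_duration)`
with no gaps or overlaps.  Periods come from successive differencing of the
annotation marks; the terminal mark (code 99) is a boundary, not a period,
and always cuts the final period short, so every recording carries
`last_period_truncated = True`.  Annotation code 11 is shared between two
waveforms and is resolved by a mode flag: `p-pd` (aphid phloem potential
drop) or `D` (psyllid first phloem contact).  Only codes 11 and 99 are fixed;
the remaining code→label assignments are configurable.

## Grammar validation

The marking guidelines form a transition grammar over period labels,
implemented as an always-on rule engine (rules G2–G11 plus duplicate-mark
detection) with two optional rules:

* **G1** (recording starts with `Np`) can be disabled for insects already
  probing at recording start.
* **G4b** is this package's rule id for the code-11 waveforms: the published
  guidelines give no grammar for `D`/`p-pd`, so they are validated like the
  potential-drop context (preceded by `C`) under a separate, disableable id.

Interpretation choices where the guideline text is ambiguous:

* "pd … followed by C or Np" is enforced after the *complete* subphase group
  (II-1, II-2, II-3), since the subphase rule mandates the internal order;
  enforcing it on the onset period alone would contradict the subphase rule.
* A single bad transition may violate several rules (e.g. `Np → E2` breaks
  both the `Np`-successor and the `E2`-predecessor rules); every violated
  rule is reported, because the original workbook highlights cells rather
  than rule identities and reporting both is strictly more informative.
* A successor requirement is waived at the very end of the recording: the
  terminal mark may legitimately cut a potential-drop group (or an F/G bout)
  before its successor could be marked.
* Successors of `E1e` are unconstrained (the guidelines are silent).

Validation never raises on content; issues carry the rule id, the row of the
second element of the offending transition (row 0 for G1/G11) and the label
pair.  Any issue blocks variable computation unless `force` is passed.

## Segmentation

* **Probe**: maximal run of non-`Np` periods; every `Np` ends a probe.
  Brief probe: duration `< 3` min, strict, boundary excluded.
* **Potential-drop group**: a `pd`/`p-pd` onset plus its marked II-2/II-3
  subphase periods; incomplete groups are kept and flagged rather than
  dropped (the validator reports the subphase issue separately).
* **Phloem phase**: maximal contiguous run of `E1`/`E2` periods.  `E1e` and
  `D` are not phase members; they precede a phase.  Phases cannot span
  probes because any other label breaks contiguity.
* **Derived classes**: sustained E2 (`> 10` min, strict); single E1 (the E1
  of a phase that never reaches `E2`); fractionating E1 (strictly between
  two `E2` periods of its phase); phase-initial E1 followed by E2; E12
  pseudo-periods (one per phase reaching `E2`, spanning the whole phase);
  single D (a `D` not immediately followed by `E1`).

## The variable registry

The registry is a declarative table of 127 per-recording variables in the
field's standard acronym scheme, each with its category, Sarria-overlap flag
(53 shared / 74 unique) and missing-data rule.  Design choices where the
published variable list names a variable without defining it:

* `E1_index` mirrors the only index defined in prose (the E2 index): share
  of time in `E1` from first `E1` onset to the end of the recording; the
  alternative `100·s_E1/(s_E1+s_E2)` is available via
  `ComputeOptions(e1_index_formula="balance")`.
* `frE1_ratio` = `n_frE1 / n_E1`, missing when no `E1` exists.
* `d_1st_E` is the duration of the first phloem *phase* (contiguous
  `E1`+`E2`), not of the first `E1` period alone.
* `a_s_E2/phloem_ph` is the mean over phases-with-E2 of the per-phase `E2`
  total.
* `d_2Np` (duration of the second non-probing period) is the registry's
  acronym for a variable the source table lists without one.
* `n_pd` counts standard potential-drop groups only; `p-pd` groups are a
  disjoint family, keeping `s_pd + s_p-pd` additive.
* `mx_` variables use the observed duration as-is even when the maximum is
  the truncated final period (a maximum cannot be corrected without the
  unknown true value); the result is flagged.
* The two treatment-level percentages (share of insects with `E2` /
  sustained `E2`) are computed across the recordings of a treatment by
  `treatment_percentages` and are not per-recording registry members.

Missing-data conventions (applied per variable, with the reason recorded):
counts and sums of an absent waveform are 0 while its mean/median/longest
are missing; times measured from the recording start with no defining event
are set to the total recording duration; times from the first probe to the
span from first-probe start to the end of the recording; within-probe times
are missing; before-an-event counts fall back to the total count,
after-an-event counts are missing; ratios with zero denominators are
missing.  A recording with no probes leaves every probe-referenced variable
missing.

## Truncated-wave criterion

For the single waveform whose final period abuts the terminal mark (and
only for it), the median is estimated from the rank of the observed
truncated duration `t` among the `k` complete durations:

* `k ≥ 2` and the range `[median(x ∪ {t}), lim_{T→∞} median(x ∪ {T})]`
  collapses (which happens whenever `t ≥ max(x)`): the estimate is exact.
* range finite but open: midpoint, the least-biased point estimate.
* `k = 1`: the single complete duration (flagged `fallback`);
  `k = 0`: the observed lower bound (flagged `lower-bound`).  Both branches
  are explicit, configurable and always flagged in the output metadata.

Even-count medians use the mean of the two middle values.  The mean policy
defaults to `longest-include`: the truncated observation enters the mean
only when it is the longest observation, where excluding it would typically
bias the mean down even further; `include` (always an underestimate) and
`exclude` are available.  The criterion applies only to the period closed by
the terminal mark, not to periods cut by temporal-analysis windows, unless
explicitly extended (`truncate_window_cuts`).

## Temporal analyses

By-hour windows are `[60(h−1), 60h)` minutes; cumulative windows `[0, 60h)`;
a final partial hour is permitted.  A period spanning a boundary is split,
each window counting its own fragment as one period — so by-hour counts may
sum to more than the full-recording count, while durations always partition
exactly and the final cumulative window reproduces the full-recording
results identically.  Attributing whole periods to their starting window is
available via `split="start"`.  Event tables (WDE) list every period of one
waveform with provenance; the per-insect mean (WDEI) equals the recording's
`a_` variable and is the correct statistical replicate.

## Synthetic generator

With no public repository of marked recordings, tests run on synthetic
recordings built from a probabilistic behavioural model: alternating
non-probing and probing bouts; probes open with pathway and cycle through
elements — potential-drop groups at a configurable rate per minute of
pathway (default 0.8/min), phloem phases that reach ingestion with
probability 0.7, F and G bouts, and code-11 events that lead into a phase
half the time — closing with a pathway bout, so every transition satisfies
the grammar by construction.  Durations are log-normal with preset medians
chosen to be of realistic magnitude only (non-probing 2 min, pathway
2.5 min, potential-drop subphases a few seconds, salivation 1.5 min,
ingestion 12 min with heavy tail, F/G several minutes); the defaults emulate
an 8-h aphid recording, and no quantitative claim is made about any real
species.  The generator emulates annotation *structure*, not voltage
signals, waveform misclassification, electrode artefacts, or real
inter-individual variability — so passing tests demonstrate the engine's
arithmetic and grammar handling, not biological fidelity.

Violation injection edits a valid sequence minimally to break one named
rule at a seeded position and returns the edited row; an edit may
incidentally break a second rule (exactly as real mis-marks do), and tests
assert that the injected rule fires at the edited row.

## Numerical choices and problem sizes

All times are double-precision minutes; written annotation files carry 10
decimal places so a write/read round-trip preserves periods to 1e-9 min.
Equivalence tests compare the engine against an independent naive
reimplementation (plain rescans of the raw period list, standard-library
statistics) at 1e-9 min on 100 seeded recordings; the truncation estimator
is checked against a brute-force enumeration of `median(x ∪ {T})` over a
dense grid `T ∈ [t, 10^6]` (the extremes sit at the grid endpoints, so the
enumeration is exact).  The acceptance script uses 300 recordings for
validator soundness, 40 injections per rule, 500 truncation cases and 50
equivalence recordings — sizes at which every check is exhaustive for this
generator while the whole script runs in seconds.

## Known limitations

* The estimator treats only the single end-of-recording truncation; it is
  not a survival-analysis treatment of censored bouts, and multi-censoring
  is out of scope.
* Several registry definitions reconstructed from acronym conventions
  (`E1_index`, `frE1_ratio`, `a_s_E2/phloem_ph`, the single-D rule) are
  explicit package choices, configurable where alternatives are plausible,
  not claims about the original workbook's internals.
* Raw-signal processing, waveform classification and cross-treatment
  statistics are out of scope; results export to CSV/XLSX for analysis in
  R or similar.
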