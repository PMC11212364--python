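# epgkit

Standardized feeding-behaviour variables from electrical penetration graph
(EPG) annotations of piercing-sucking insects.

## The problem

The EPG technique records voltage waveforms while an aphid, psyllid or other
phloem feeder probes a plant; each waveform corresponds to a behaviour:
non-probing (`Np`), intercellular pathway (`C`), brief intracellular
potential drops (`pd`, with subphases II-1/II-2/II-3, and the aphid phloem
variant `p-pd`), first phloem contact (`D`, psyllids), extracellular
salivation (`E1e`), phloem salivation (`E1`), phloem ingestion (`E2`),
derailed stylet mechanics (`F`) and xylem ingestion (`G`).  Analysts mark
waveform onsets in acquisition software, producing an annotation file of
(code, timestamp) events closed by a terminal mark (code 99).  Turning those
event logs into the field's standardized variables — counts, mean/median/sum
durations, sequential latencies, and potential indices such as the E2 index
— is tedious and error-prone by hand.

`epgkit` is a scriptable engine for that computation.  It

* parses Stylet+-style text and Windaq-style CSV annotation exports into a
  common period model (real minutes, half-open intervals tiling the
  recording);
* validates the mark sequence against the standard marking guidelines
  (e.g. *Np is always followed by C*, *E2 is always preceded by E1*, the
  pd subphase order II-1, II-2, II-3) and reports located, rule-identified
  issues;
* computes a registry of **127 per-recording variables** (53 of which
  overlap the widely used Sarria workbook), applying the standard
  missing-data conventions, plus treatment-level percentages;
* applies the **truncated-wave criterion** to the final period, which the
  end-of-recording mark always cuts short;
* recomputes everything by hour or cumulatively, and exports per-event
  (WDE) and per-insect (WDEI) tables.

## The truncated-wave criterion

The last period of a recording has an unknown true duration; only a lower
bound `t` is observed.  The median depends on ranks, not magnitudes, so with
complete durations `x_1..x_k`:

* if `k ≥ 2` and `t ≥ max(x_i)`, the median including `t` **is** the true
  median, whatever the unknown duration (method `include-exact`);
* otherwise the true median lies in the computable range
  `[median(x ∪ {t}), lim_{T→∞} median(x ∪ {T})]` and the estimator reports
  the midpoint of that range (method `midpoint`);
* with `k ≤ 1` the range is unbounded; the estimate falls back to the single
  complete duration (`fallback`) or the observed lower bound (`lower-bound`),
  always flagged.

Means have no rank argument — including `t` always underestimates the true
mean — so three explicit policies are provided (`include`, `exclude`,
`longest-include`, the default), each recording the branch taken.

## Worked example

```python
from epgkit import ComputeOptions, GeneratorProfile, compute_all, generate_recording

recording, _ = generate_recording(GeneratorProfile(seed=2, preset="aphid"))
results = compute_all(recording, ComputeOptions(truncated_criterion=True))
```

Running `python examples/compute_variables.py` prints:

```
recording: synthetic_aphid_2.ana, 480 min, 290 periods
variables computed: 127
  n_Pr             = 22.000
  s_Pr             = 425.637
  n_pd             = 54.000
  t > 1E2          = 86.159
  s_E2             = 72.342
  %probtimeinE2    = 16.996
  E2_index         = 18.482
```

This synthetic aphid probed 22 times for 425.6 of 480 min, performed 54
potential drops, first ingested phloem sap 86.2 min after its first probe,
and spent 72.3 min ingesting — 17.0 % of probing time, and 18.5 % of the
time available after ingestion first began (the E2 index).  The other
examples cover sequence validation (`validate_sequence.py`), the truncation
estimator on hand-checkable numbers (`truncated_median.py`) and temporal
slicing (`temporal_analysis.py`).

A thin CLI wraps the same library:

```bash
epgkit fixtures --seed 1 --n 3 --outdir fx/          # synthetic files
epgkit validate fx/*.ana                             # guideline check
epgkit compute fx/*.ana --truncated --out results.csv
epgkit temporal fx/aphid_1.ana --mode cumulative --out hourly.csv
epgkit events fx/*.ana --waveform E2 --out events.csv
epgkit registry                                      # variable reference
```

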