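"""By-hour and cumulative recomputation of the registry, plus event tables.

Shows how phloem ingestion accumulates over an 8-h recording and how the
per-event (WDE) and per-insect (WDEI) views differ.
"""

from epgkit import (
    GeneratorProfile,
    compute_temporal,
    events_table,
    generate_recording,
    wdei,
)

recording, _ = generate_recording(GeneratorProfile(seed=2, preset="aphid"))

print("hour   s_E2/h   cumulative s_E2")
cumulative = compute_temporal(recording, mode="cumulative")
by_hour = compute_temporal(recording, mode="by-hour")
for (wb, rb), (wc, rc) in zip(by_hour.items(), cumulative.items()):
    s_by = {r.acronym: r.value for r in rb}["s_E2"]
    s_cum = {r.acronym: r.value for r in rc}["s_E2"]
    print(f"{wb.hour_index:3d} {s_by:9.2f} {s_cum:14.2f}")

events = events_table([recording], "E2")
print(f"\n{len(events)} E2 events (WDE rows); pooled events are pseudo-replicates,")
print(f"so treatment statistics should use the per-insect mean instead:")
print(f"WDEI[E2] = {wdei(recording, 'E2'):.2f} min")

# The by-hour column shows when ingestion happened; the cumulative column is
# non-decreasing and its final value equals the full-recording s_E2.
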