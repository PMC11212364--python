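"""Compute the full 127-variable registry for one synthetic aphid recording.

Generates an 8-h annotated recording, validates its mark sequence, computes
the registry and prints a handful of headline variables.
"""

from epgkit import ComputeOptions, GeneratorProfile, compute_all, generate_recording, validate

recording, _ = generate_recording(GeneratorProfile(seed=2, preset="aphid"))
assert validate(recording) == [], "generated sequences are grammatical by construction"

results = compute_all(recording, ComputeOptions(truncated_criterion=True))
values = {r.acronym: r for r in results}

print(f"recording: {recording.file_name}, {recording.total_duration:.0f} min, "
      f"{len(recording.periods)} periods")
print(f"variables computed: {len(results)}")
for acr in ("n_Pr", "s_Pr", "n_pd", "t > 1E2", "s_E2", "%probtimeinE2", "E2_index",
            "a_E2", "m_E2"):
    r = values[acr]
    shown = "missing" if r.value is None else f"{r.value:.3f}"
    note = f"  [{r.truncation_flag}]" if r.truncation_flag else ""
    print(f"  {acr:16s} = {shown}{note}")

# n_Pr / s_Pr: how often and how long the insect probed; t > 1E2 is the
# latency from the first probe to the first phloem ingestion; %probtimeinE2
# and E2_index measure how much of probing / post-onset time was ingestion.
# a_E2 / m_E2 carry a truncation flag when the recording ends mid-E2.
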