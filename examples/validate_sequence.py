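"""Validate an annotation sequence and show the error report.

Injects a single grammar violation (an E2 not preceded by E1) into a valid
synthetic recording and prints the located, rule-identified issues.
"""

from epgkit import GeneratorProfile, error_report, generate_recording, inject_violation, validate

recording, _ = generate_recording(GeneratorProfile(seed=5, preset="aphid"))
print("valid recording:", len(validate(recording)), "issues")

mutated, row = inject_violation(recording, "G3", seed=5)
issues = validate(mutated)
print(f"after corrupting the mark before the E2 at row {row}:")
print(error_report({mutated.file_name: issues}))

# The headline counts every wrong mark; each line gives the period row, the
# violated guideline and the offending label transition, which is what an
# annotator needs to fix the sequence before variables are computed.
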