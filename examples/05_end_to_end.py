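"""End-to-end orchestration: simulate -> report -> validate -> concordance.

Runs the whole pipeline from a single config document into ./scratch-example
and prints the summary. Re-running with the same seed reproduces every
output byte-for-byte (see outputs_manifest.json checksums).
"""

import json

from ctdnaval import RunConfig, run_end_to_end

config = RunConfig(
    seed=7,
    design={
        "tiers": [2.0, 1.0, 0.5, 0.0],
        "input_ng": [50],
        "replicates": 3,
        "cohort_patients": 12,
    },
)
summary = run_end_to_end(config, "scratch-example")
print(json.dumps(summary, indent=2, sort_keys=True))
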