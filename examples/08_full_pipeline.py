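"""The whole development sequence from one configuration.

simulate -> screen -> calibrate -> item fit -> DIF -> short form ->
CAT study -> reliability, with every stage's item counts and statistics
collected into a machine-readable summary.  Identical configurations
reproduce identical runs.
"""

import json

from probank import run_pipeline

run_dir = run_pipeline({
    "seed": 1,
    "out_dir": "scratch/example_run",
    "simulate": {"n_persons": 600, "n_items": 20, "n_categories": 5},
    "cat": {"n_simulees": 200},
    "retest": {"n_persons": 100},
})

summary = json.loads((run_dir / "summary.json").read_text())
for stage, info in summary["stages"].items():
    print(f"{stage}: {info}")
# The summary records, per stage, how many items went in, how many were
# removed and why, and the headline statistics (fit indices, CAT lengths,
# CAT-SF correlation, alpha, retest ICC).
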