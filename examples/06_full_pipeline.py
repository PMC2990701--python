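"""Run the whole analysis end to end and read the consolidated report.

Equivalent to `snakemap run --seed 1 --out snakemap_out` on the shell.
"""

import json

from snakemap import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="snakemap_out", seed=1))

print("files written to snakemap_out/ (regions, index, flags, fits, report)")
print("national summary:", json.dumps(report["descriptive_rounded"], indent=2))
print("worst-index municipalities:", report["worst_index_municipalities"])
print(f"low-reporters flagged: {report['n_low_reporters']}")
det = report["detection_vs_truth"]["low_reporters"]
print(f"low-reporter detection vs truth: sensitivity={det['sensitivity']}, "
      f"specificity={det['specificity']:.2f}")
# Both detection layers together are the map a control programme would
# use to target active case finding.
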