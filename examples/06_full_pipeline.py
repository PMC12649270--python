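"""The full 33-trial, three-specimen validation pipeline in one call.

Runs simulate → track-markers → emulate-model → kinematics → agreement on
the default demo configuration and prints the pooled agreement table plus
the per-motion stratification.  Takes ~20 s; outputs land in
scratch/full_demo/ (transform CSVs per stage, kinematics tables, report).
"""

import logging
import sys

import pandas as pd

from bvrkin.pipeline import default_demo_config, run_pipeline

logging.basicConfig(stream=sys.stderr, level=logging.WARNING)

cfg = default_demo_config(seed=1)
manifest = run_pipeline(cfg, "scratch/full_demo")
print(f"trials: {manifest.counts['trials']}, "
      f"frames generated: {manifest.counts['frames_generated']}, "
      f"analyzed: {manifest.counts['frames_analyzed']}")

report = pd.read_csv("scratch/full_demo/report.csv")
for analysis in ("pooled", "motion"):
    sub = report[report.analysis == analysis]
    print(f"\n--- {analysis} ---")
    print(sub[["stratum", "dof", "n", "mad", "bias", "loa", "outlier_frac"]]
          .round(3).to_string(index=False))
print("\nPooled MAD in the sub-degree / sub-millimetre range, similar hop vs")
print("drop errors, and ~5% outlier frames reproduce the qualitative picture")
print("of a frozen-specimen biplane videoradiography validation.")
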