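"""Run the whole pipeline (simulate -> phenotype -> select -> validate)
from one config and write the report tables plus a hashed manifest."""

from pathlib import Path

import pandas as pd

from akival import CohortConfig, RunConfig, run_pipeline

out = Path("scratch/example_run")
cfg = RunConfig(
    simulation=CohortConfig(n_patients=3000),
    out_dir=out,
    seed=20,
)
files = run_pipeline(cfg)
report = pd.read_csv(files["report"])
cols = ["row", "n_reference_positive", "n_index_positive", "sensitivity", "ppv", "lr_plus"]
print(report[cols].to_string(index=False))
print(f"\nwrote: {sorted(p.name for p in files.values())}")
# The report has the published table's shape: an overall row, a
# stage-2/3-restricted row, and one row per eGFR / admission / surgery
# stratum. Rerunning with the same seed reproduces every file hash in
# manifest.json byte for byte.
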