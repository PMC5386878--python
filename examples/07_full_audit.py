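"""The full audit, end to end.

Runs every stage on the demo configuration (8 species, 60 genes each, 10
planted transfers) and prints the summary plus the per-method detection
bookkeeping against the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from lgt_audit import pipeline

out = Path("scratch_audit_demo")
config = Path(__file__).with_name("demo_config.yaml")
manifest = pipeline.run_audit(str(config), out)

summary = json.loads((out / "summary.json").read_text())
print(json.dumps(summary, indent=2, sort_keys=True))
print()
print(pd.read_csv(out / "detection.tsv", sep="\t").to_string(index=False))
print("\nEvery output digest is recorded in", out / "manifest.json",
      "- rerunning with the same seed reproduces it byte for byte.")
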