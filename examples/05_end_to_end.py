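"""One-shot pipeline: simulate -> mine -> classify -> masses -> match.

Equivalent to `cyclomine run-all --simulate --out <dir>`; prints the run
report and the molecular-species census recovered from the simulated data.
"""

import json
import tempfile
from pathlib import Path

from cyclomine import PipelineConfig, run_all

with tempfile.TemporaryDirectory() as tmp:
    outdir = run_all(PipelineConfig(seed=1), Path(tmp) / "run", simulate=True)
    print((outdir / "report.txt").read_text())
    summary = json.loads((outdir / "summary.json").read_text())
    print("summary.json:")
    print(json.dumps(summary, indent=2, sort_keys=True))
    print()
    print("With the default generator (2 transcripts per shipped species) the")
    print("census recovers all 46 molecular species in 13 series; the report's")
    print("worked mass table reproduces the cycloviolacin O2 spectrum numbers.")
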