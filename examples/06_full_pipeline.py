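"""The whole study-shaped run from one config, then the contrast summary.

Equivalent to `msiregio run-all --seed 7 --out runs/demo`.
"""

import json
import tempfile
from pathlib import Path

from msiregio import RunConfig, compare_contrasts, run_all

with tempfile.TemporaryDirectory() as td:
    out = Path(td) / "run"
    manifest = run_all(RunConfig(seed=7), out)
    for stage in manifest.stages:
        print(f"{stage['name']:11s} {stage['wall_time_s']:7.2f}s  "
              f"{len(stage['outputs'])} output(s)")
    summary = compare_contrasts(out)
    print(json.dumps({k: v for k, v in summary.items()
                      if not k.endswith("_mzs")}, indent=1))
    print("-> treatment effects are found in the trauma-adjacent contrast")
    print("   and not in the trauma-core contrast, matching the planted design.")
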