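"""Leave-one-out nearest-group-mean classification of treatment from the
mOFC/mlOFC/pSTS gentle-touch time courses (5-35 s window), with a
2,000-draw permutation null per group pair."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["classify"])
RESULTS_DIR.mkdir(exist_ok=True)
(RESULTS_DIR / "classification.json").write_text((RUN_DIR / "classification.json").read_text())
results = json.loads((RUN_DIR / "classification.json").read_text())
for pair, r in results.items():
    print(f"{pair}: accuracy {r['accuracy']:.3f}, permutation p = {r['p_value']:.4f} "
          f"(null mean {r['null_mean']:.3f})")
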