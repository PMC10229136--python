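"""Bootstrap mediation: does the post-treatment plasma OT change carry the
treatment effect on gentle-touch pleasantness? One model per OT route vs
placebo, 2,000 resamples."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["mediate"])
RESULTS_DIR.mkdir(exist_ok=True)
(RESULTS_DIR / "mediation.json").write_text((RUN_DIR / "mediation.json").read_text())
for route, r in json.loads((RUN_DIR / "mediation.json").read_text()).items():
    lo, hi = r["ci_95"]
    print(f"{route}: a={r['a']:.2f} (p={r['p_a']:.3g}), b={r['b']:.3f} (p={r['p_b']:.3g}), "
          f"c'={r['c_prime']:.2f}, indirect={r['indirect']:.3f} [{lo:.3f}, {hi:.3f}]")
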