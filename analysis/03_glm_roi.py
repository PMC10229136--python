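"""First-level GLM (four task regressors + intercept) on the concatenated
sessions, stimulation-minus-rest contrasts, and ROI aggregation."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["glm"])
roi = pd.read_csv(RUN_DIR / "roi.csv")
summary = roi.groupby(["condition", "roi"])["value"].mean().unstack().round(3)
print("mean stimulation-minus-rest contrast per ROI (uM):")
print(summary.to_string())
RESULTS_DIR.mkdir(exist_ok=True)
roi.to_csv(RESULTS_DIR / "roi_contrasts.csv", index=False)
summary.to_csv(RESULTS_DIR / "roi_contrast_summary.csv")
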