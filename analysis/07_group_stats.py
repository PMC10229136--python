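"""Group-level ANOVAs: plasma OT (baseline and change), ratings
(treatment x condition), ROI oxy-Hb (treatment x condition x region) and
autonomic indices, with partial eta-squared."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["stats", "report"])
tables = pd.read_csv(RUN_DIR / "anova_tables.csv")
RESULTS_DIR.mkdir(exist_ok=True)
tables.to_csv(RESULTS_DIR / "anova_tables.csv", index=False)
(RESULTS_DIR / "report.json").write_text((RUN_DIR / "report.json").read_text())
pd.set_option("display.width", 120)
for name, t in tables.groupby("analysis"):
    print(f"\n== {name}")
    print(t.drop(columns="analysis").round(4).to_string(index=False))
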