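"""Autonomic indices per subject and condition: SCR base-to-peak
amplitude, heart rate, HF power, DFA-alpha1."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["autonomic"])
auto = pd.read_csv(RUN_DIR / "autonomic.csv")
summary = auto.groupby(["index", "condition"])["value"].mean().round(3)
print(summary.to_string())
RESULTS_DIR.mkdir(exist_ok=True)
summary.to_csv(RESULTS_DIR / "autonomic_summary.csv")
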