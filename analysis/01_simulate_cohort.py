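"""Generate the synthetic study cohort.

Three treatment arms (intranasal OT, oral OT, placebo), per-subject
oxy-Hb recordings for the gentle-touch and massage sessions, behavioural
ratings, four plasma OT samples, RR-interval and skin-conductance traces.
Also prints the a-priori sample-size calculation the full-size study design
rests on.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS_DIR, RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline
from oxytouch.stats import PowerSpec, anova_sample_size

cfg = make_config()
n_star = anova_sample_size(PowerSpec(k=3, f=0.25, alpha=0.05, power=0.80))
print(f"a-priori total N for 3 groups, f=0.25, alpha=0.05, power=0.80: {n_star}")

run_pipeline(cfg, RUN_DIR, stages=["simulate"])
import pandas as pd

roster = pd.read_csv(RUN_DIR / "roster.csv")
print(f"enrolled {len(roster)}, analyzed {(roster.exclusion_reason == 'none').sum()}")
print(roster[roster.exclusion_reason == "none"].group.value_counts().to_string())
RESULTS_DIR.mkdir(exist_ok=True)
roster.to_csv(RESULTS_DIR / "cohort_roster.csv", index=False)
print(f"wrote cohort to {RUN_DIR} (roster copied to results/)")
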