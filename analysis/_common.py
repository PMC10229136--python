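"""Shared configuration for the numbered analysis drivers.

The drivers run the full study pipeline at desk scale: 12 subjects per arm
(instead of 56/57/58), 2,000 label permutations and 2,000 bootstrap
resamples, which keeps the whole sequence at a few minutes on one CPU while
preserving every structural property of the full-size analysis.
"""

from pathlib import Path

from oxytouch.config import PipelineConfig
from oxytouch.simulate import CohortConfig, INTRANASAL_OT, ORAL_OT, PLC

# bulky per-subject artifacts (SNIRF files, sample-level CSVs) live under
# scratch/; the drivers copy their small summary tables into results/
RUN_DIR = Path(__file__).resolve().parent.parent / "scratch" / "run"
RESULTS_DIR = Path(__file__).resolve().parent.parent / "results"


def make_config() -> PipelineConfig:
    cfg = PipelineConfig(seed=2026)
    cfg.cohort = CohortConfig(
        group_sizes={INTRANASAL_OT: 12, ORAL_OT: 12, PLC: 12},
        n_incomplete=1,
        n_technical=1,
    )
    cfg.classify.n_permutations = 2000
    cfg.mediation.n_boot = 2000
    return cfg
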