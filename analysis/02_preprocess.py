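"""Preprocess every fNIRS recording: polynomial detrend, TDDR motion
correction, 0.01-0.08 Hz zero-phase Butterworth bandpass."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RUN_DIR, make_config

from oxytouch.pipeline import run_pipeline

run_pipeline(make_config(), RUN_DIR, stages=["preprocess"])
n = len(list((RUN_DIR / "preprocessed").glob("*.snirf")))
print(f"preprocessed {n} subject-session recordings -> {RUN_DIR / 'preprocessed'}")
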