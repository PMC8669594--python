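"""Shared configuration and paths for the numbered analysis scripts.

The analysis runs a desk-scale instance of the recording protocol: one
session of 60 trials (10 per condition) at the native 1 kHz rate with a
10:1 source-to-noise amplitude ratio, so every script finishes in seconds
while exercising the full pipeline.
"""

from pathlib import Path

import graspsource as gs

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
DATA = RESULTS / "data"


def analysis_config(seed: int = 1) -> gs.SimConfig:
    return gs.SimConfig(
        n_sessions=1,
        trials_per_task_per_session=10,
        sample_rate=1000.0,
        snr=10.0,
        seed=seed,
    )
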