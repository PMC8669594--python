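"""Graph metrics (DE, DS, M, CC, CPL) at the planning, onset and grasp-peak
time points (-1, 0, 1.4 s) for every condition."""

import pandas as pd

from graspsource import io, netmetrics

from common import RESULTS, analysis_config


def main():
    cfg = analysis_config()
    rows = []
    for task in cfg.tasks:
        tensor = io.load_plv(RESULTS / f"plv_{task}.h5")
        rows.append(
            netmetrics.metrics_timecourse(
                tensor, task, times=(-1.0, 0.0, 1.4), seed=cfg.seed
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(RESULTS / "network_metrics.csv", index=False, float_format="%.10g")
    print(df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
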