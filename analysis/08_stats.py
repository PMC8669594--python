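"""Statistical comparisons: rank-sum significance tracks and the
window-size repeated-measures ANOVA.

Rank-sum: left-BA4a sMRCP of each grasp type versus no-movement at every
time point (uncorrected p < 0.05).  Window sizes: peak accuracies for the
four feature-window lengths over repeated CV runs (as the repeated factor),
compared by one-way RM-ANOVA.
"""

import numpy as np
import pandas as pd

from graspsource import decode, io
from graspsource.stats_report import ranksum_timecourse, rm_anova_window_sizes
from graspsource.synthdata import MOVEMENT_TASKS

from common import RESULTS


def main():
    smrcp = io.load_sources(RESULTS / "smrcp.h5")
    tracks = []
    for task in MOVEMENT_TASKS:
        tr = ranksum_timecourse(smrcp, "BA4a-L", task)
        tracks.append(
            pd.DataFrame(
                dict(roi=tr.roi, condition=task, time_s=tr.times,
                     p_value=tr.p_values, significant=tr.mask.astype(int))
            )
        )
        sig = tr.mask.mean()
        post = tr.mask[tr.times >= 0.5].mean()
        print(f"{task:8s} vs no-movement: {100 * sig:.0f}% of time points "
              f"significant ({100 * post:.0f}% after 0.5 s)")
    pd.concat(tracks, ignore_index=True).to_csv(
        RESULTS / "significance.csv", index=False, float_format="%.10g"
    )

    smrcp16 = decode.resample_sources(smrcp)
    sizes = (1 / 16, 0.5, 1.0, 1.5)
    peaks = []
    for run_seed in (1, 2, 3):  # repeated CV runs as the repeated factor
        df = decode.window_size_experiment(
            smrcp16, sizes=sizes, folds=5, repeats=1, seed=run_seed,
            window_subset=np.arange(0, 88, 4),
        )
        peaks.append(df["peak_accuracy"].to_numpy())
        df.insert(0, "run", run_seed)
        print(df.round(4).to_string(index=False))
    table = np.vstack(peaks)
    F, p = rm_anova_window_sizes(table)
    pd.DataFrame(table, columns=[f"{s:g}s" for s in sizes]).to_csv(
        RESULTS / "window_size_peaks.csv", index=False, float_format="%.10g"
    )
    print(f"window-size RM-ANOVA: F = {F:.2f}, p = {p:.4g}")


if __name__ == "__main__":
    main()
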