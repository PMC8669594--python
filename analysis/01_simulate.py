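"""Simulate the synthetic reach-and-grasp experiment and store it.

Writes one HDF5 recording per session plus the rest block and the
leadfield, and the planted per-trial truth as TSV.
"""

import graspsource as gs
from graspsource import io

from common import DATA, analysis_config


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    cfg = analysis_config()
    sessions, rest, truth, leadfield = gs.simulate_experiment(cfg)
    for rec in sessions:
        io.save_recording(rec, DATA / f"session_{rec.session:02d}.h5")
    io.save_recording(rest, DATA / "rest.h5")
    io.save_leadfield(leadfield, DATA / "leadfield.h5")
    truth.trials.to_csv(DATA / "truth_trials.tsv", sep="\t", index=False)
    print(
        f"simulated {cfg.n_sessions} session(s), {cfg.total_trials} trials, "
        f"{cfg.n_channels} channels at {cfg.sample_rate:.0f} Hz -> {DATA}"
    )


if __name__ == "__main__":
    main()
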