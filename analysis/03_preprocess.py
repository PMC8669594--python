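"""Filter, downsample, epoch and clean the recordings into MRCP epochs.

0.1-40 Hz band-pass -> 100 Hz -> [-3, 3.5) s epochs at onset -> amplitude /
joint-probability / kurtosis rejection -> common average reference ->
0.1-3 Hz MRCP band.  Writes the epoch container.
"""

from graspsource import events, io, preprocess

from common import DATA, RESULTS, analysis_config


def main():
    cfg = analysis_config()
    table = events.read_events_tsv(RESULTS / "events.tsv")
    sets = []
    for s in range(cfg.n_sessions):
        rec = io.load_recording(DATA / f"session_{s:02d}.h5")
        sets.append(preprocess.preprocess_session(rec, table[table["session"] == s]))
    epochs = preprocess.concatenate(sets)
    io.save_epochs(epochs, RESULTS / "epochs.h5")
    print(
        f"{epochs.n_trials} epochs retained, {epochs.n_channels} channels, "
        f"{epochs.data.shape[2]} samples at {epochs.rate:.0f} Hz"
    )


if __name__ == "__main__":
    main()
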