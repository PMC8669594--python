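"""Shared fixtures: one planted synthetic experiment carried through the chain.

The session-scoped bundle simulates a single high-SNR session at the native
1 kHz rate and runs it through event detection, preprocessing and source
imaging once, so decoding, connectivity and statistics tests can reuse the
same source epochs.
"""

import numpy as np
import pandas as pd
import pytest

import graspsource as gs
from graspsource import decode, events, inverse, preprocess


@pytest.fixture(scope="session")
def planted_bundle():
    cfg = gs.SimConfig(
        n_sessions=1,
        trials_per_task_per_session=10,
        sample_rate=1000.0,
        snr=10.0,
        seed=11,
    )
    sessions, rest, truth, leadfield = gs.simulate_experiment(cfg)
    return dict(
        config=cfg, sessions=sessions, rest=rest, truth=truth, leadfield=leadfield
    )


@pytest.fixture(scope="session")
def planted_events(planted_bundle):
    rec = planted_bundle["sessions"][0]
    truth = planted_bundle["truth"]
    tr = truth.trials[truth.trials["session"] == rec.session]
    wrong = (tr["executed_task"] != tr["task"]).to_numpy()
    table = events.build_event_table(rec)
    table = events.apply_discard_rules(table, wrong_movement=wrong)
    return events.assign_pseudo_onsets(table)


@pytest.fixture(scope="session")
def planted_epochs(planted_bundle, planted_events):
    rec = planted_bundle["sessions"][0]
    return preprocess.preprocess_session(rec, planted_events)


@pytest.fixture(scope="session")
def planted_smrcp(planted_bundle, planted_epochs):
    rest_proc = preprocess.preprocess_rest(planted_bundle["rest"])
    cov = inverse.estimate_noise_cov(rest_proc)
    op = inverse.sloreta_operator(planted_bundle["leadfield"], cov, snr=3.0)
    return inverse.apply_inverse(planted_epochs, op)


@pytest.fixture(scope="session")
def planted_smrcp16(planted_smrcp):
    return decode.resample_sources(planted_smrcp)


@pytest.fixture(scope="session")
def grasp_interval(planted_bundle):
    """Mean planted grasp interval (seconds relative to movement onset)."""
    tr = planted_bundle["truth"].trials
    move = tr["task"] != "no-movement"
    start = (tr.loc[move, "grasp_start_t"] - tr.loc[move, "onset_t"]).mean()
    end = (tr.loc[move, "grasp_end_t"] - tr.loc[move, "onset_t"]).mean()
    return float(start), float(end)


def make_source_epochs(
    data: np.ndarray, rate: float = 100.0, t0: float = -3.0, labels=None
) -> inverse.SourceEpochs:
    """Hand-built SourceEpochs for connectivity/statistics tests."""
    n_tr, n_roi, n_s = data.shape
    if labels is None:
        labels = np.array(["palmar"] * n_tr)
    from graspsource.atlas import ROI_LABELS

    return inverse.SourceEpochs(
        data=np.asarray(data, float),
        roi_labels=tuple(ROI_LABELS[:n_roi]),
        labels=np.asarray(labels),
        time=t0 + np.arange(n_s) / rate,
        rate=rate,
    )
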