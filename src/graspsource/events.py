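"""Movement-onset detection and behavioural trial validation.

Movement onset is the rising edge of the button channel (the subject lifts
off the press button to reach) and movement end its falling edge; the grasp
interval comes from the force-transducer edges.  No-movement trials receive
a pseudo-onset: the "go" cue plus the subject's mean reaction time over
valid movement trials.  Trials violating one of four behavioural rules are
flagged for discard:

R1  button released before the "go" cue
R2  no return to the button within 5 s of "go"
R3  reaction time above 1.5 s
R4  wrong movement executed (decidable only from simulation ground truth)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import NO_MOVEMENT, Recording

FLAGS = ("OK", "R1", "R2", "R3", "R4")

RETURN_LIMIT_S = 5.0
REACTION_LIMIT_S = 1.5


def detect_edges(
    signal: np.ndarray,
    rate: float,
    threshold: float | None = None,
    hysteresis_s: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Rising/falling crossing times of a 1-D auxiliary channel.

    The default threshold is half the channel's dynamic range; crossings
    closer than ``hysteresis_s`` to the previous edge are treated as bounce
    and ignored.  Returns ``(rising_times, falling_times)`` in seconds.
    """
    x = np.asarray(signal, float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("auxiliary signal must be finite")
    if threshold is None:
        lo, hi = x.min(), x.max()
        if hi <= lo:  # constant signal: no edges
            return np.array([]), np.array([])
        threshold = 0.5 * (lo + hi)
    above = x >= threshold
    change = np.flatnonzero(np.diff(above.astype(np.int8)))
    rising, falling, last = [], [], -np.inf
    for i in change:
        t = (i + 1) / rate
        if t - last < hysteresis_s:
            continue
        (rising if above[i + 1] else falling).append(t)
        last = t
    return np.asarray(rising), np.asarray(falling)


def build_event_table(rec: Recording, threshold: float | None = None) -> pd.DataFrame:
    """Per-trial event table from the button and force channels.

    Each scheduled trial is searched between its own start and the next
    trial's start for a button rise (onset), the subsequent fall (end), and
    the force rise/fall (grasp interval).  Missing edges are NaN and are
    resolved by :func:`apply_discard_rules`.
    """
    b_rise, b_fall = detect_edges(rec.button, rec.rate, threshold)
    f_rise, f_fall = detect_edges(rec.force, rec.rate, threshold)
    cues = rec.cues.reset_index(drop=True)
    # trial windows: from 3 s before the task cue to the next trial's window
    window_start = cues["cue_t"].to_numpy() - 3.0
    window_end = np.r_[window_start[1:], rec.duration]

    rows = []
    for i, cue in cues.iterrows():
        w0, w1 = window_start[i], window_end[i]
        onset = _first_in(b_rise, w0, w1)
        end = _first_in(b_fall, onset if np.isfinite(onset) else w0, w1)
        g0 = _first_in(f_rise, w0, w1)
        g1 = _first_in(f_fall, g0 if np.isfinite(g0) else w0, w1)
        rows.append(
            dict(
                session=rec.session,
                trial=int(cue["trial"]),
                task=cue["task"],
                cue_t=float(cue["cue_t"]),
                go_t=float(cue["go_t"]),
                onset_t=onset,
                end_t=end,
                grasp_start_t=g0,
                grasp_end_t=g1,
            )
        )
    table = pd.DataFrame(rows)
    table["reaction_time"] = table["onset_t"] - table["go_t"]
    table.loc[table["task"] == NO_MOVEMENT, "reaction_time"] = np.nan
    return table


def _first_in(times: np.ndarray, lo: float, hi: float) -> float:
    sel = times[(times > lo) & (times < hi)]
    return float(sel[0]) if sel.size else np.nan


def apply_discard_rules(
    table: pd.DataFrame, wrong_movement: np.ndarray | None = None
) -> pd.DataFrame:
    """Flag every trial with exactly one of OK/R1/R2/R3/R4.

    ``wrong_movement`` is an optional boolean mask (simulation ground truth);
    without it R4 is a no-op, as wrong movements cannot be detected from the
    recording alone.  Movement trials with no button edges are unusable and
    flagged R2 (never returned because never released -- no valid onset).
    Idempotent: re-applying to a flagged table yields the same flags.
    """
    t = table.copy()
    move = t["task"] != NO_MOVEMENT
    flag = np.where(move.to_numpy(), "", "OK").astype(object)

    onset = t["onset_t"].to_numpy()
    end = t["end_t"].to_numpy()
    go = t["go_t"].to_numpy()
    rt = t["reaction_time"].to_numpy()

    for i in np.flatnonzero(move.to_numpy()):
        if np.isfinite(onset[i]) and onset[i] < go[i]:
            flag[i] = "R1"
        elif not np.isfinite(onset[i]) or not np.isfinite(end[i]) or (
            end[i] > go[i] + RETURN_LIMIT_S
        ):
            flag[i] = "R2"
        elif rt[i] > REACTION_LIMIT_S:
            flag[i] = "R3"
        elif wrong_movement is not None and wrong_movement[i]:
            flag[i] = "R4"
        else:
            flag[i] = "OK"
    t["flag"] = flag
    return t


def assign_pseudo_onsets(table: pd.DataFrame) -> pd.DataFrame:
    """Give no-movement trials ``onset_t = go_t + mean valid reaction time``.

    The mean is over movement trials flagged OK; raises if there are none.
    """
    if "flag" not in table:
        raise ValueError("apply_discard_rules must run before pseudo-onset assignment")
    t = table.copy()
    move_ok = (t["task"] != NO_MOVEMENT) & (t["flag"] == "OK")
    if not move_ok.any():
        raise ValueError("no valid movement trials to estimate mean reaction time")
    mean_rt = float(t.loc[move_ok, "reaction_time"].mean())
    nm = t["task"] == NO_MOVEMENT
    t.loc[nm, "onset_t"] = t.loc[nm, "go_t"] + mean_rt
    t.loc[nm, "reaction_time"] = mean_rt
    return t


def segment_phases(row: pd.Series) -> dict[str, tuple[float, float]] | None:
    """Four behavioural phases of one valid movement trial.

    react = [go, onset]; reach = [onset, grasp start]; grasp = [grasp start,
    grasp end]; return = [grasp end, movement end].  Returns None (trial
    invalid) if force edges are missing or fall outside [onset, end].
    """
    go, onset, end = row["go_t"], row["onset_t"], row["end_t"]
    g0, g1 = row["grasp_start_t"], row["grasp_end_t"]
    if not all(np.isfinite(v) for v in (go, onset, end, g0, g1)):
        return None
    if not (onset <= g0 <= g1 <= end):
        return None
    return {
        "react": (go, onset),
        "reach": (onset, g0),
        "grasp": (g0, g1),
        "return": (g1, end),
    }


def annotate_recording(
    rec: Recording, wrong_movement: np.ndarray | None = None
) -> pd.DataFrame:
    """Full event chain for one recording: detect, flag, pseudo-onset."""
    table = build_event_table(rec)
    table = apply_discard_rules(table, wrong_movement=wrong_movement)
    return assign_pseudo_onsets(table)


def write_events_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
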