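"""Synthetic reach-and-grasp EEG experiments with known ground truth.

This module emulates a cue-based recording protocol for six conditions
(five natural grasps -- palmar, pinch, push, twist, plug -- plus a
no-movement control).  Each trial lasts 12 s: an attention beep at 0 s, the
task cue at 3 s, the "go" cue at 5 s, and the movement (reach, grasp,
return) completed within 5 s of "go".  Sessions hold a randomised, balanced
sequence of trials; a 10-s rest recording with sensor noise only is produced
for noise-covariance estimation.

Condition-specific low-frequency source waveforms (movement-related cortical
potentials) are placed in motor and visual regions with left-hemisphere
lateralisation, projected to the sensors through a leadfield, scaled to
microvolts and mixed with spatially correlated 1/f noise.  A configurable
fraction of trials violates each behavioural discard rule so that rejection
logic can be exercised against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import N_ROIS, ROI_LABELS, roi_index

TASKS = ("palmar", "pinch", "push", "twist", "plug", "no-movement")
MOVEMENT_TASKS = TASKS[:5]
NO_MOVEMENT = "no-movement"

#: 10-20-style names for the default 40-channel montage.
CHANNEL_NAMES_40 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4", "O1", "O2",
)

#: Sensor-space scale: microvolts produced per unit of source amplitude
#: through a unit-norm leadfield column.
SENSOR_GAIN_UV = 2.0
#: Reference source amplitude defining the SNR normalisation.
REFERENCE_SOURCE_AMP = 5.0

DISCARD_RULES = ("R1", "R2", "R3", "R4")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment (defaults follow the protocol).

    ``snr`` is the amplitude ratio between the sensor projection of a
    reference-amplitude source and the sensor noise RMS; ``np.inf`` disables
    noise.  ``amplitude_sd_frac`` controls inter-trial variability of the
    source waveform scale (fractional SD of a mean-1 factor).
    ``contamination`` maps discard-rule codes (R1..R4) to the fraction of
    movement trials planted to violate that rule; ``artifact_fraction`` adds
    a >100 uV spike to that fraction of trials to exercise amplitude
    rejection.
    """

    n_channels: int = 40
    n_sources: int = 48
    sample_rate: float = 1000.0
    n_sessions: int = 8
    trials_per_task_per_session: int = 10
    tasks: tuple[str, ...] = TASKS
    reaction_time_mean: float = 0.5
    reaction_time_sd: float = 0.1
    snr: float = 5.0
    amplitude_sd_frac: float = 0.2
    contamination: dict[str, float] = field(default_factory=dict)
    artifact_fraction: float = 0.0
    trial_duration: float = 12.0
    cue_time: float = 3.0
    go_time: float = 5.0
    rest_duration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_sources < N_ROIS:
            raise ValueError(f"n_sources must be >= {N_ROIS} (one per ROI)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("n_sessions", "trials_per_task_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        bad = set(self.contamination) - set(DISCARD_RULES)
        if bad:
            raise ValueError(f"unknown discard rules in contamination: {bad}")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def trials_per_session(self) -> int:
        return self.trials_per_task_per_session * self.n_tasks

    @property
    def total_trials(self) -> int:
        return self.n_sessions * self.trials_per_session


@dataclass
class Leadfield:
    """Forward gain matrix (channels x sources) with a source-to-ROI map."""

    gain: np.ndarray
    source_rois: tuple[str, ...]
    ch_names: tuple[str, ...]

    def __post_init__(self):
        if self.gain.shape != (len(self.ch_names), len(self.source_rois)):
            raise ValueError("gain shape inconsistent with labels")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield gain must be finite")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    def roi_source_indices(self, roi: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.source_rois) == roi)
        if idx.size == 0:
            raise ValueError(f"ROI {roi!r} has no sources in this leadfield")
        return idx


@dataclass
class GroundTruth:
    """Planted quantities the pipeline should recover.

    ``roi_templates`` maps each condition to a (24, T) source waveform on
    ``template_times`` (seconds relative to movement onset).
    ``coupled_roi_pairs`` lists (roi_a, roi_b, coupling) used to plant
    phase-locked oscillations for connectivity recovery.  ``trials`` is
    filled by :func:`simulate_experiment` with per-trial timing, amplitude
    factors, executed task and the planted discard rule (``OK`` if clean).
    """

    roi_templates: dict[str, np.ndarray]
    template_times: np.ndarray
    coupled_roi_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    coupled_osc_amp: float = 2.0
    background_osc_amp: float = 0.7
    trials: pd.DataFrame | None = None

    def __post_init__(self):
        T = self.template_times.size
        for task, tpl in self.roi_templates.items():
            if tpl.shape != (N_ROIS, T):
                raise ValueError(
                    f"template for {task!r} has shape {tpl.shape}, "
                    f"expected ({N_ROIS}, {T})"
                )
        for a, b, c in self.coupled_roi_pairs:
            roi_index(a), roi_index(b)
            if c < 0:
                raise ValueError("coupling strength must be >= 0")


@dataclass
class Recording:
    """Continuous multichannel recording of one session (or the rest block).

    ``eeg`` is channels x samples in microvolts; ``button`` is a release
    indicator that rises at movement onset and falls at movement end;
    ``force`` rises during the grasp.  ``cues`` lists the scheduled trials
    (columns: trial, task, cue_t, go_t, absolute seconds).
    """

    eeg: np.ndarray
    button: np.ndarray
    force: np.ndarray
    rate: float
    ch_names: tuple[str, ...]
    cues: pd.DataFrame
    session: int = 0

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


# ---------------------------------------------------------------------------
# Leadfield generation


def generate_leadfield(
    n_channels: int,
    n_sources: int,
    seed: int = 0,
    kind: str = "random",
) -> Leadfield:
    """Build a deterministic leadfield with unit-norm columns.

    ``kind="random"`` draws Gaussian columns; ``kind="dipole"`` places
    electrodes on the upper half of a unit sphere and scalar current dipoles
    inside it, using the infinite-homogeneous-medium dipole potential for a
    spatially structured alternative; ``kind="identity"`` (requires
    ``n_channels == n_sources``) is the identity gain used in analytic tests.
    Sources are tagged with the 24 ROI labels round-robin so every ROI gets
    at least one source.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if n_sources < N_ROIS:
        raise ValueError(f"n_sources must be >= {N_ROIS}: every ROI needs a source")
    rng = np.random.default_rng(seed)
    if kind == "identity":
        if n_channels != n_sources:
            raise ValueError("identity leadfield requires n_channels == n_sources")
        gain = np.eye(n_channels)
    elif kind == "random":
        gain = rng.standard_normal((n_channels, n_sources))
    elif kind == "dipole":
        gain = _dipole_gain(n_channels, n_sources, rng)
    else:
        raise ValueError(f"unknown leadfield kind {kind!r}")
    if kind != "identity":
        gain = gain / np.linalg.norm(gain, axis=0, keepdims=True)
    rois = tuple(ROI_LABELS[i % N_ROIS] for i in range(n_sources))
    names = _channel_names(n_channels)
    return Leadfield(gain=gain, source_rois=rois, ch_names=names)


def _dipole_gain(n_channels: int, n_sources: int, rng: np.random.Generator):
    # electrodes on the upper unit hemisphere
    az = rng.uniform(0, 2 * np.pi, n_channels)
    el = rng.uniform(np.deg2rad(10), np.pi / 2, n_channels)
    elec = np.c_[np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    # dipoles at 70-85% radius with random orientation
    r = rng.uniform(0.70, 0.85, n_sources)
    az = rng.uniform(0, 2 * np.pi, n_sources)
    el = rng.uniform(0, np.pi / 2, n_sources)
    pos = r[:, None] * np.c_[
        np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)
    ]
    q = rng.standard_normal((n_sources, 3))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    gain = np.empty((n_channels, n_sources))
    for j in range(n_sources):
        d = elec - pos[j]
        dist3 = np.linalg.norm(d, axis=1) ** 3
        gain[:, j] = d @ q[j] / (4 * np.pi * dist3)
    return gain


def _channel_names(n_channels: int) -> tuple[str, ...]:
    if n_channels <= len(CHANNEL_NAMES_40):
        return CHANNEL_NAMES_40[:n_channels]
    extra = tuple(f"EXT{i}" for i in range(n_channels - len(CHANNEL_NAMES_40)))
    return CHANNEL_NAMES_40 + extra


# ---------------------------------------------------------------------------
# Ground-truth templates

#: (peak amplitude, peak latency s) of the motor deflection per grasp type.
_MOTOR_PARAMS = {
    "palmar": (10.0, 1.40),
    "pinch": (8.0, 1.20),
    "push": (6.0, 1.70),
    "twist": (9.0, 1.55),
    "plug": (7.0, 1.85),
}


def default_ground_truth(config: SimConfig) -> GroundTruth:
    """Condition templates on [-3, 6) s around onset at the recording rate.

    Movement conditions carry a negative motor deflection peaking near 1.5 s
    after onset in left BA4a/BA6 (right hemisphere attenuated to 35%,
    modelling contralateral control of the right hand), a smaller
    somatosensory response, and a visual response during the reach (0-1 s).
    The no-movement condition has exactly zero motor templates and a weak
    visual response.  Left BA4a-BA6 is the default planted coupled pair for
    connectivity recovery.
    """
    rate = config.sample_rate
    t = np.arange(round(-3.0 * rate), round(6.0 * rate)) / rate
    templates: dict[str, np.ndarray] = {}
    for task in config.tasks:
        tpl = np.zeros((N_ROIS, t.size))
        if task != NO_MOVEMENT:
            amp, peak = _MOTOR_PARAMS.get(task, (8.0, 1.5))
            bump = _gauss(t, peak, 0.35)
            ramp = _gauss(t, peak - 0.6, 0.8)  # slow pre-peak negativity
            motor = -(amp * bump + 0.25 * amp * ramp)
            for h, lat in (("L", 1.0), ("R", 0.35)):
                tpl[roi_index(f"BA4a-{h}")] += lat * motor
                tpl[roi_index(f"BA6-{h}")] += 0.8 * lat * np.roll(
                    motor, -round(0.15 * rate)
                )
                tpl[roi_index(f"BA2-{h}")] += 0.4 * lat * -amp * _gauss(t, 1.0, 0.4)
            vis_amp = 3.0
        else:
            vis_amp = 1.0
        vis = vis_amp * _gauss(t, 0.5, 0.30)
        for h in ("L", "R"):
            tpl[roi_index(f"V1-{h}")] += vis
            tpl[roi_index(f"V2-{h}")] += 0.8 * vis
        templates[task] = tpl
    return GroundTruth(
        roi_templates=templates,
        template_times=t,
        coupled_roi_pairs=[("BA4a-L", "BA6-L", 1.0)],
    )


def zero_ground_truth(config: SimConfig) -> GroundTruth:
    """All-zero source activity (no templates, no oscillations): with
    ``snr = inf`` every EEG channel is identically zero."""
    rate = config.sample_rate
    t = np.arange(round(-3.0 * rate), round(6.0 * rate)) / rate
    templates = {task: np.zeros((N_ROIS, t.size)) for task in config.tasks}
    return GroundTruth(
        roi_templates=templates,
        template_times=t,
        coupled_roi_pairs=[],
        background_osc_amp=0.0,
    )


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


# ---------------------------------------------------------------------------
# Experiment simulation


def simulate_experiment(
    config: SimConfig,
    truth: GroundTruth | None = None,
    leadfield: Leadfield | None = None,
) -> tuple[list[Recording], Recording, GroundTruth, Leadfield]:
    """Simulate all sessions plus the rest block.

    Returns ``(sessions, rest, truth, leadfield)``; ``truth.trials`` is
    filled with the planted per-trial schedule.  Identical ``(config,
    truth)`` reproduce the output bit for bit.
    """
    if leadfield is None:
        leadfield = generate_leadfield(
            config.n_channels, config.n_sources, seed=config.seed
        )
    if leadfield.n_channels != config.n_channels:
        raise ValueError("leadfield channel count does not match config")
    if truth is None:
        truth = default_ground_truth(config)
    if truth.template_times.size < 2 or not np.isclose(
        1.0 / (truth.template_times[1] - truth.template_times[0]),
        config.sample_rate,
    ):
        raise ValueError("template time axis must be sampled at config.sample_rate")

    master = np.random.SeedSequence(config.seed)
    session_seeds = master.spawn(config.n_sessions + 1)
    schedule = _plan_trials(config, np.random.default_rng(master.spawn(1)[0]))

    sessions = []
    for s in range(config.n_sessions):
        rng = np.random.default_rng(session_seeds[s])
        sessions.append(
            _render_session(config, truth, leadfield, schedule, s, rng)
        )
    rest = _render_rest(config, leadfield, np.random.default_rng(session_seeds[-1]))
    truth = replace(truth, trials=schedule)
    return sessions, rest, truth, leadfield


def _plan_trials(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomised balanced schedule with planted timing and rule violations."""
    rows = []
    for s in range(config.n_sessions):
        order = np.repeat(config.tasks, config.trials_per_task_per_session)
        rng.shuffle(order)
        for i, task in enumerate(order):
            start = i * config.trial_duration
            rows.append(
                dict(
                    session=s,
                    trial=i,
                    task=task,
                    executed_task=task,
                    start_t=start,
                    cue_t=start + config.cue_time,
                    go_t=start + config.go_time,
                )
            )
    df = pd.DataFrame(rows)

    move = df["task"] != NO_MOVEMENT
    n_move = int(move.sum())
    rt = rng.normal(config.reaction_time_mean, config.reaction_time_sd, len(df))
    rt = np.clip(rt, 0.15, 1.2)
    amp = np.clip(rng.normal(1.0, config.amplitude_sd_frac, len(df)), 0.2, None)

    df["planted_rule"] = "OK"
    move_idx = np.flatnonzero(move.to_numpy())
    rng.shuffle(move_idx)
    pos = 0
    for rule in DISCARD_RULES:
        frac = config.contamination.get(rule, 0.0)
        k = int(round(frac * n_move))
        chosen = move_idx[pos : pos + k]
        pos += k
        df.loc[chosen, "planted_rule"] = rule
    # R4 violations also need a wrong executed movement
    r4 = df.index[df["planted_rule"] == "R4"]
    for i in r4:
        others = [t for t in MOVEMENT_TASKS if t != df.at[i, "task"]]
        df.at[i, "executed_task"] = others[rng.integers(len(others))]
    # R3: reaction time beyond 1.5 s; R1: button release before "go"
    r3 = df["planted_rule"] == "R3"
    rt[r3.to_numpy()] = 1.6 + 0.4 * rng.random(int(r3.sum()))
    r1 = df["planted_rule"] == "R1"
    rt[r1.to_numpy()] = -(0.2 + 0.3 * rng.random(int(r1.sum())))

    df["reaction_time"] = np.where(move, rt, np.nan)
    df["amp_scale"] = amp
    df["onset_t"] = np.where(move, df["go_t"] + rt, np.nan)

    reach = np.clip(rng.normal(1.0, 0.1, len(df)), 0.6, 1.5)
    grasp = np.clip(rng.normal(1.0, 0.1, len(df)), 0.6, 1.5)
    ret = np.clip(rng.normal(0.9, 0.1, len(df)), 0.5, 1.4)
    df["grasp_start_t"] = df["onset_t"] + reach
    df["grasp_end_t"] = df["grasp_start_t"] + grasp
    df["end_t"] = df["grasp_end_t"] + ret
    # R2: no return to the button within 5 s of "go"
    r2 = (df["planted_rule"] == "R2").to_numpy()
    df.loc[r2, "end_t"] = df.loc[r2, "go_t"] + 5.3 + 0.4 * rng.random(int(r2.sum()))
    df.loc[r2, "grasp_end_t"] = np.minimum(
        df.loc[r2, "grasp_end_t"], df.loc[r2, "end_t"] - 0.2
    )
    for c in ("grasp_start_t", "grasp_end_t", "end_t"):
        df.loc[~move, c] = np.nan

    n_art = int(round(config.artifact_fraction * len(df)))
    art = np.zeros(len(df), bool)
    art[rng.choice(len(df), size=n_art, replace=False)] = True
    df["planted_artifact"] = art
    return df


def _render_session(config, truth, leadfield, schedule, session, rng):
    rate = config.sample_rate
    n = round(config.trials_per_session * config.trial_duration * rate)
    roi_act = np.zeros((N_ROIS, n))
    button = np.zeros(n)
    force = np.zeros(n)
    sched = schedule[schedule["session"] == session]

    t0 = truth.template_times[0]
    Ttpl = truth.template_times.size
    coupled = {roi_index(a) for a, b, _ in truth.coupled_roi_pairs} | {
        roi_index(b) for a, b, _ in truth.coupled_roi_pairs
    }
    seg = np.arange(round(config.trial_duration * rate)) / rate

    for row in sched.itertuples():
        i0 = round(row.start_t * rate)
        i1 = i0 + seg.size
        onset_local = (
            row.onset_t - row.start_t
            if np.isfinite(row.onset_t)
            else config.go_time + config.reaction_time_mean
        )
        # place the condition template, aligned to onset
        tpl = truth.roi_templates[row.executed_task]
        a = round((onset_local + t0) * rate)  # template start in segment samples
        lo, hi = max(a, 0), min(a + Ttpl, seg.size)
        if hi > lo:
            roi_act[:, i0 + lo : i0 + hi] += (
                row.amp_scale * tpl[:, lo - a : hi - a]
            )
        # phase-locked oscillations: coupled pairs share one phase,
        # every other ROI gets an independent random-phase component
        for ra, rb, c in truth.coupled_roi_pairs:
            ph = rng.uniform(0, 2 * np.pi)
            w = 2 * np.pi * 2.0
            osc = truth.coupled_osc_amp * np.sin(w * seg + ph)
            roi_act[roi_index(ra), i0:i1] += c * osc
            roi_act[roi_index(rb), i0:i1] += c * osc
        for r in range(N_ROIS):
            if r in coupled:
                continue
            f = rng.uniform(1.0, 3.0)
            ph = rng.uniform(0, 2 * np.pi)
            roi_act[r, i0:i1] += truth.background_osc_amp * np.sin(
                2 * np.pi * f * seg + ph
            )
        # auxiliary channels
        if row.task != NO_MOVEMENT and np.isfinite(row.onset_t):
            _set_high(button, rate, row.onset_t, row.end_t, n)
            if row.planted_rule != "R2" or np.isfinite(row.grasp_end_t):
                _set_high(force, rate, row.grasp_start_t, row.grasp_end_t, n)

    src = roi_act[[roi_index(r) for r in leadfield.source_rois], :]
    eeg = SENSOR_GAIN_UV * (leadfield.gain @ src)
    eeg += _sensor_noise(config, eeg.shape, rng)

    for row in sched.itertuples():
        if row.planted_artifact:
            ch = rng.integers(config.n_channels)
            at = round((row.go_t + 1.0) * rate)
            w = round(0.05 * rate)
            idx = np.arange(max(at - w, 0), min(at + w, n))
            eeg[ch, idx] += 180.0 * _gauss(idx / rate, at / rate, 0.01)

    cues = sched[["trial", "task", "cue_t", "go_t"]].reset_index(drop=True)
    return Recording(
        eeg=eeg,
        button=button,
        force=force,
        rate=rate,
        ch_names=leadfield.ch_names,
        cues=cues,
        session=session,
    )


def _set_high(sig: np.ndarray, rate: float, t_on: float, t_off: float, n: int):
    if not (np.isfinite(t_on) and np.isfinite(t_off)):
        return
    a, b = round(t_on * rate), round(t_off * rate)
    sig[max(a, 0) : min(b, n)] = 1.0


def _sensor_noise(config: SimConfig, shape, rng: np.random.Generator):
    """Spatially mixed 1/f Gaussian noise at the RMS implied by ``snr``."""
    if np.isinf(config.snr):
        return np.zeros(shape)
    target_rms = SENSOR_GAIN_UV * REFERENCE_SOURCE_AMP / config.snr
    n_ch, n = shape
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, 1.0 / config.sample_rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    colored = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n, axis=1)
    mix = np.eye(n_ch) + 0.5 * rng.standard_normal((n_ch, n_ch)) / np.sqrt(n_ch)
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    noise = mix @ colored
    rms = np.sqrt(np.mean(noise**2))
    return noise * (target_rms / rms)


def _render_rest(config, leadfield, rng) -> Recording:
    n = round(config.rest_duration * config.sample_rate)
    eeg = _sensor_noise(config, (config.n_channels, n), rng)
    return Recording(
        eeg=eeg,
        button=np.zeros(n),
        force=np.zeros(n),
        rate=config.sample_rate,
        ch_names=leadfield.ch_names,
        cues=pd.DataFrame(columns=["trial", "task", "cue_t", "go_t"]),
        session=-1,
    )
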