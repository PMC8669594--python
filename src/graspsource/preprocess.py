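"""Filtering, resampling, epoching, trial rejection and referencing.

The chain that turns a raw recording into movement-related cortical
potential (MRCP) epochs: 0.1-40 Hz zero-phase band-pass, downsample to
100 Hz, epoch around movement onset, reject trials by amplitude (+-100 uV),
joint probability and kurtosis (5 SD), common-average reference, and a
final 0.1-3 Hz band-pass isolating the MRCP band.

All intervals are half-open: ``[a, b)`` at rate ``r`` holds
``round((b - a) * r)`` samples.  Epochs are cut at [-3, 3.5) s around
onset -- one second wider than the [-2, 3.5) temporal region of interest
(tROI) -- so a causal 1-s feature window exists for every tROI time point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal as sps
from scipy.stats import kurtosis as _kurtosis

from .synthdata import Recording

EPOCH_WINDOW = (-3.0, 3.5)
TROI = (-2.0, 3.5)
WORK_RATE = 100.0
MRCP_BAND = (0.1, 3.0)
BROAD_BAND = (0.1, 40.0)
AMP_THRESHOLD_UV = 100.0
STAT_SD = 5.0

REJECT_CODES = ("OK", "AMP", "JP", "KURT")


@dataclass
class EpochSet:
    """Trials x channels x samples with labels and a rejection mask."""

    data: np.ndarray
    labels: np.ndarray
    time: np.ndarray
    rate: float
    reject_mask: np.ndarray  # per-trial code in REJECT_CODES
    troi: tuple[float, float] = TROI

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        dt = np.diff(self.time)
        if self.time.size != self.data.shape[2] or np.any(dt <= 0):
            raise ValueError("time axis must match samples and increase strictly")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def retained(self) -> "EpochSet":
        """Epochs surviving rejection."""
        keep = self.reject_mask == "OK"
        return replace(
            self,
            data=self.data[keep],
            labels=self.labels[keep],
            reject_mask=self.reject_mask[keep],
        )

    def troi_slice(self) -> slice:
        a = int(round((self.troi[0] - self.time[0]) * self.rate))
        n = int(round((self.troi[1] - self.troi[0]) * self.rate))
        return slice(a, a + n)


def butter_zero_phase(
    x: np.ndarray,
    low: float,
    high: float | None,
    rate: float,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth filter (order-``order`` design, forward-backward).

    ``low = 0`` gives a low-pass, ``high = None`` a high-pass.  The
    forward-backward application doubles the effective magnitude order and
    cancels the phase response.
    """
    nyq = rate / 2.0
    if low < 0 or (high is not None and (high <= low or high >= nyq)):
        raise ValueError(f"band ({low}, {high}) Hz invalid for rate {rate} Hz")
    if low == 0 and high is None:
        raise ValueError("at least one band edge required")
    if low == 0:
        sos = sps.butter(order, high, btype="lowpass", fs=rate, output="sos")
    elif high is None:
        sos = sps.butter(order, low, btype="highpass", fs=rate, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def resample(x: np.ndarray, rate: float, target_rate: float, axis: int = -1):
    """Polyphase anti-aliased downsampling; upsampling is refused."""
    if target_rate > rate:
        raise ValueError("only downsampling is supported")
    if target_rate == rate:
        return np.asarray(x, float).copy()
    frac = Fraction(target_rate / rate).limit_denominator(1000)
    # sharp Kaiser design keeps passband ripple ~1e-7; linear padding avoids
    # edge transients on slow signals
    return sps.resample_poly(
        x, frac.numerator, frac.denominator, axis=axis,
        window=("kaiser", 14.0), padtype="line",
    )


def epoch(
    eeg: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float] = EPOCH_WINDOW,
) -> EpochSet:
    """Cut epochs around onset times (half-open ``[window[0], window[1])``).

    Onsets whose window exceeds the recording are dropped with a warning
    entry removed from labels as well.
    """
    onsets = np.asarray(onsets, float)
    labels = np.asarray(labels)
    n_samp = int(round((window[1] - window[0]) * rate))
    time = window[0] + np.arange(n_samp) / rate
    data, kept = [], []
    for i, t in enumerate(onsets):
        a = int(round((t + window[0]) * rate))
        if a < 0 or a + n_samp > eeg.shape[1]:
            continue
        data.append(eeg[:, a : a + n_samp])
        kept.append(i)
    if not data:
        raise ValueError("no onset has full window support in the recording")
    arr = np.stack(data)
    return EpochSet(
        data=arr,
        labels=labels[kept],
        time=time,
        rate=rate,
        reject_mask=np.full(arr.shape[0], "OK", dtype=object),
    )


def reject_trials(
    epochs: EpochSet,
    amp_threshold_uv: float = AMP_THRESHOLD_UV,
    stat_sd: float = STAT_SD,
) -> EpochSet:
    """Flag trials by amplitude, joint probability and kurtosis.

    AMP: any sample beyond ``+-amp_threshold_uv``.  JP: the trial's mean
    negative log-likelihood under per-channel empirical Gaussians (fit
    across all trials) deviates more than ``stat_sd`` SDs from the
    trial-population mean.  KURT: likewise for the trial's mean channel
    kurtosis.  Degenerate spread (SD = 0) flags nothing.  Data are kept;
    only the mask is set.
    """
    if epochs.n_trials < 8:
        raise ValueError("need >= 8 trials for rejection statistics")
    x = epochs.data
    mask = np.array(epochs.reject_mask, dtype=object, copy=True)

    amp_bad = np.max(np.abs(x), axis=(1, 2)) > amp_threshold_uv

    mu = x.mean(axis=(0, 2), keepdims=True)
    sd = x.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    nll = 0.5 * ((x - mu) / sd) ** 2 + np.log(sd)
    jp_stat = nll.mean(axis=(1, 2))
    jp_bad = _deviates(jp_stat, stat_sd)

    kurt_stat = _kurtosis(x, axis=2, fisher=True, bias=True).mean(axis=1)
    kurt_bad = _deviates(kurt_stat, stat_sd)

    mask[jp_bad] = "JP"
    mask[kurt_bad] = "KURT"  # kurtosis is the more specific statistic
    mask[amp_bad] = "AMP"  # amplitude takes precedence
    if np.all(mask != "OK"):
        raise ValueError("all trials rejected")
    return replace(epochs, reject_mask=mask)


def _deviates(stat: np.ndarray, n_sd: float) -> np.ndarray:
    sd = stat.std()
    if sd == 0:
        return np.zeros(stat.size, bool)
    return np.abs(stat - stat.mean()) > n_sd * sd


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (idempotent)."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def car_matrix(x: np.ndarray) -> np.ndarray:
    """Common-average-reference a channels x samples array."""
    if x.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return x - x.mean(axis=0, keepdims=True)


def mrcp_band(epochs: EpochSet) -> EpochSet:
    """Restrict epochs to the 0.1-3 Hz MRCP band (zero phase)."""
    data = butter_zero_phase(epochs.data, *MRCP_BAND, rate=epochs.rate)
    return replace(epochs, data=data)


def preprocess_session(
    rec: Recording,
    events: pd.DataFrame,
    work_rate: float = WORK_RATE,
    amp_threshold_uv: float = AMP_THRESHOLD_UV,
    stat_sd: float = STAT_SD,
) -> EpochSet:
    """Full chain for one session's recording.

    Order: 0.1-40 Hz -> downsample -> epoch valid trials at onset (or
    pseudo-onset) -> reject -> common average reference -> 0.1-3 Hz.
    ``events`` must already carry flags and pseudo-onsets.
    """
    valid = events[events["flag"] == "OK"]
    eeg = butter_zero_phase(rec.eeg, *BROAD_BAND, rate=rec.rate)
    eeg = resample(eeg, rec.rate, work_rate)
    ep = epoch(
        eeg,
        work_rate,
        valid["onset_t"].to_numpy(),
        valid["task"].to_numpy(),
    )
    ep = reject_trials(ep, amp_threshold_uv=amp_threshold_uv, stat_sd=stat_sd)
    ep = ep.retained()
    ep = common_average_reference(ep)
    return mrcp_band(ep)


def preprocess_rest(rec: Recording, work_rate: float = WORK_RATE) -> np.ndarray:
    """Rest block through the same chain (no epoching): returns ch x samples."""
    eeg = butter_zero_phase(rec.eeg, *BROAD_BAND, rate=rec.rate)
    eeg = resample(eeg, rec.rate, work_rate)
    eeg = car_matrix(eeg)
    return butter_zero_phase(eeg, *MRCP_BAND, rate=work_rate)


def concatenate(sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets from several sessions (same layout required)."""
    first = sets[0]
    for s in sets[1:]:
        if s.data.shape[1:] != first.data.shape[1:] or s.rate != first.rate:
            raise ValueError("epoch sets differ in layout")
    return replace(
        first,
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        reject_mask=np.concatenate([s.reject_mask for s in sets]),
    )
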