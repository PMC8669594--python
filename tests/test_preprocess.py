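"""Filtering, resampling, epoching, rejection and referencing."""

import numpy as np
import pytest

from graspsource import preprocess as pp
from graspsource.preprocess import EpochSet


def make_epochs(data, rate=100.0, t0=-3.0, labels=None):
    n_tr, _, n_s = data.shape
    return EpochSet(
        data=np.asarray(data, float),
        labels=np.array(["palmar"] * n_tr) if labels is None else labels,
        time=t0 + np.arange(n_s) / rate,
        rate=rate,
        reject_mask=np.full(n_tr, "OK", dtype=object),
    )


class TestButterZeroPhase:
    def test_dc_blocked_by_mrcp_band(self):
        x = np.full(5000, 7.0)
        y = pp.butter_zero_phase(x, 0.1, 3.0, rate=100.0)
        assert np.max(np.abs(y)) < 1e-3 * 7.0

    def test_passband_gain_of_1hz_sine(self):
        # the 0.1 Hz edge has a ~10 s transient, so use a long signal and
        # generous trimming before the quadrature projection at exactly 1 Hz
        rate = 100.0
        t = np.arange(0, 200, 1 / rate)
        y = pp.butter_zero_phase(np.sin(2 * np.pi * 1.0 * t), 0.1, 3.0, rate=rate)
        mid, tm = y[4000:-4000], t[4000:-4000]
        a = 2 * np.mean(mid * np.sin(2 * np.pi * tm))
        b = 2 * np.mean(mid * np.cos(2 * np.pi * tm))
        assert 0.95 <= np.hypot(a, b) <= 1.0 + 1e-4

    def test_zero_phase_impulse_symmetry(self):
        # forward-backward filtering has a symmetric impulse response
        x = np.zeros(6001)
        x[3000] = 1.0
        y = pp.butter_zero_phase(x, 1.0, 10.0, rate=100.0)
        assert np.allclose(y[3000:], y[3000::-1][: y.size - 3000], atol=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.butter_zero_phase(np.zeros(100), 0.1, 60.0, rate=100.0)


class TestResample:
    def test_88_samples_from_5p5s_at_16hz(self):
        x = np.zeros(550)  # 5.5 s at 100 Hz, half-open
        assert pp.resample(x, 100.0, 16.0).shape[-1] == 88

    def test_constant_preserved(self):
        y = pp.resample(np.full(1000, 3.5), 1000.0, 100.0)
        assert np.allclose(y, 3.5, atol=1e-9)

    def test_sine_matches_analytic(self):
        t = np.arange(0, 10, 1e-3)
        y = pp.resample(np.sin(2 * np.pi * 2 * t), 1000.0, 100.0)
        t100 = np.arange(y.size) / 100.0
        err = np.abs(y - np.sin(2 * np.pi * 2 * t100))[50:-50]
        assert err.max() < 1e-3

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            pp.resample(np.zeros(100), 100.0, 200.0)


class TestEpoch:
    def test_sample_counts_and_troi(self):
        eeg = np.zeros((3, 10000))
        ep = pp.epoch(eeg, 100.0, onsets=[50.0], labels=np.array(["palmar"]))
        assert ep.data.shape == (1, 3, 650)
        sl = ep.troi_slice()
        assert sl.stop - sl.start == 550

    def test_onset_without_support_dropped(self):
        eeg = np.random.default_rng(0).standard_normal((2, 2000))
        ep = pp.epoch(eeg, 100.0, onsets=[1.0, 10.0], labels=np.array(["a", "b"]))
        assert ep.data.shape[0] == 1 and ep.labels.tolist() == ["b"]

    def test_constant_channel_stays_constant(self):
        eeg = np.vstack([np.full(10000, 4.2), np.zeros(10000)])
        ep = pp.epoch(eeg, 100.0, onsets=[50.0], labels=np.array(["x"]))
        assert np.allclose(ep.data[0, 0], 4.2)


class TestRejectTrials:
    def test_amplitude_spike_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 10, (12, 4, 200))
        data[3, 2, 50] = 150.0
        ep = pp.reject_trials(make_epochs(data))
        assert ep.reject_mask[3] == "AMP"
        assert np.sum(ep.reject_mask == "AMP") == 1

    def test_identical_trials_not_flagged(self):
        data = np.tile(np.sin(np.linspace(0, 6, 200)) * 20, (10, 3, 1))
        ep = pp.reject_trials(make_epochs(data))
        assert (ep.reject_mask == "OK").all()

    def test_planted_heavy_tail_flagged_kurt(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, (101, 4, 300))
        spikes = rng.standard_t(1, size=300) * 5
        data[50] = np.clip(spikes, -90, 90)  # heavy-tailed but under amp limit
        ep = pp.reject_trials(make_epochs(data))
        assert ep.reject_mask[50] == "KURT"

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 25, (20, 4, 200))
        lo = pp.reject_trials(make_epochs(data), amp_threshold_uv=70)
        hi = pp.reject_trials(make_epochs(data), amp_threshold_uv=100)
        assert set(np.flatnonzero(hi.reject_mask == "AMP")) <= set(
            np.flatnonzero(lo.reject_mask == "AMP")
        )

    def test_all_rejected_is_an_error(self):
        data = np.full((8, 2, 100), 200.0)
        with pytest.raises(ValueError, match="all trials"):
            pp.reject_trials(make_epochs(data))

    def test_too_few_trials_is_an_error(self):
        with pytest.raises(ValueError, match=">= 8"):
            pp.reject_trials(make_epochs(np.zeros((5, 2, 100))))


class TestCommonAverageReference:
    def test_balanced_channels_unchanged(self):
        data = np.stack([np.ones((2, 100)), -np.ones((2, 100))], axis=1)
        ep = pp.common_average_reference(make_epochs(data))
        assert np.allclose(ep.data, data)

    def test_identical_channels_become_zero(self):
        data = np.tile(np.random.default_rng(0).standard_normal(100), (5, 3, 1))
        ep = pp.common_average_reference(make_epochs(data))
        assert np.allclose(ep.data, 0.0)

    def test_channel_sum_vanishes_and_idempotent(self):
        data = np.random.default_rng(4).standard_normal((6, 8, 120))
        ep = pp.common_average_reference(make_epochs(data))
        assert np.max(np.abs(ep.data.sum(axis=1))) < 1e-10
        again = pp.common_average_reference(ep)
        assert np.allclose(again.data, ep.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.common_average_reference(make_epochs(np.zeros((3, 1, 50))))


class TestSessionChain:
    def test_preprocessed_epochs_shape_and_band(self, planted_epochs):
        ep = planted_epochs
        assert ep.rate == 100.0
        assert ep.data.shape[2] == 650
        assert (ep.reject_mask == "OK").all()  # retained() already applied
        assert np.max(np.abs(ep.data)) <= 100.0
        # channel mean is zero after CAR... filtering preserves the null space
        assert np.max(np.abs(ep.data.sum(axis=1))) < 1e-6

    def test_epoch_counts_match_valid_events(self, planted_events, planted_epochs):
        n_valid = int((planted_events["flag"] == "OK").sum())
        assert planted_epochs.n_trials <= n_valid
        assert planted_epochs.n_trials >= n_valid - 5
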