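"""Feature extraction, shrinkage LDA, CV curves and chance level."""

import numpy as np
import pytest
from scipy.special import comb

from graspsource import decode
from graspsource.atlas import ROI_LABELS

from conftest import make_source_epochs


def smrcp16_from(data, t0=-3.0):
    return make_source_epochs(data, rate=16.0, t0=t0)


class TestDesignArithmetic:
    @pytest.mark.parametrize(
        "troi,rate,expected",
        [((-2.0, 3.5), 16.0, 88), ((0.0, 1.0), 16.0, 16), ((-2.0, 3.5), 100.0, 550)],
    )
    def test_count_models(self, troi, rate, expected):
        assert decode.count_models(troi, rate) == expected

    def test_192_features_per_model(self):
        data = np.zeros((4, 24, 104))
        X, _ = decode.extract_features(smrcp16_from(data), t_end=0.0)
        assert X.shape == (4, 192)

    def test_half_second_window_gives_96_features(self):
        data = np.zeros((4, 24, 104))
        X, _ = decode.extract_features(smrcp16_from(data), t_end=0.0, window_s=0.5)
        assert X.shape == (4, 96)

    def test_constant_source_gives_constant_features(self):
        data = np.full((3, 24, 104), 2.5)
        X, _ = decode.extract_features(smrcp16_from(data), t_end=1.0)
        assert np.allclose(X, 2.5)

    def test_window_before_epoch_start_rejected(self):
        data = np.zeros((3, 24, 104))
        with pytest.raises(ValueError, match="outside"):
            decode.extract_features(smrcp16_from(data), t_end=-2.5)

    def test_window_ends_cover_half_open_troi(self):
        ends = decode.window_ends()
        assert ends.size == 88
        assert ends[0] == pytest.approx(-2.0 + 1 / 16)
        assert ends[-1] == pytest.approx(3.5)


class TestFitSlda:
    def test_separable_blobs_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 192)), rng.normal(8, 1, (10, 192))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = decode.fit_slda(X, y)
        assert (model.predict(X) == y).all()

    def test_more_features_than_samples_still_fits(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 192))
        y = np.array(["a", "b", "c"] * 4)
        model = decode.fit_slda(X, y)
        assert model.predict(X).shape == (12,)

    def test_underpopulated_class_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError):
            decode.fit_slda(X, np.array(["a", "a", "b"]))


def exact_chance_oracle(n, k_classes, alpha):
    """Smallest k/n with P(X >= k) <= alpha by direct CDF summation."""
    p = 1.0 / k_classes
    for k in range(n + 1):
        upper = sum(
            comb(n, j, exact=True) * p**j * (1 - p) ** (n - j)
            for j in range(k, n + 1)
        )
        if upper <= alpha:
            return k / n
    return 1.0


class TestChanceLevel:
    def test_matches_exact_summation_oracle(self):
        for n, k in [(60, 6), (120, 6), (30, 4)]:
            assert decode.chance_level(n, k) == pytest.approx(
                exact_chance_oracle(n, k, 0.05)
            )

    def test_480_trials_six_classes_near_paper_scale(self):
        # 95/480 ~ 0.198: the adjusted six-class chance level at full size
        # (exact binomial: P(X >= 95) = 0.040 <= 0.05 < 0.051 = P(X >= 94))
        assert decode.chance_level(480, 6) == pytest.approx(95 / 480)
        assert decode.chance_level(480, 6) == pytest.approx(
            exact_chance_oracle(480, 6, 0.05)
        )

    def test_single_class_is_certain(self):
        assert decode.chance_level(100, 1) == 1.0

    def test_converges_to_uniform_guess_rate(self):
        assert decode.chance_level(10**6, 6) == pytest.approx(1 / 6, abs=1e-3)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            decode.chance_level(100, 6, alpha=1.5)


@pytest.fixture(scope="module")
def separable():
    """Six classes, discriminable only after t = 1 s."""
    rng = np.random.default_rng(2)
    labels = np.repeat([f"c{i}" for i in range(6)], 15)
    data = rng.normal(0, 1, (90, 24, 104))
    t = -3.0 + np.arange(104) / 16.0
    post = np.flatnonzero(t >= 1.0)
    for i in range(6):
        sel = np.flatnonzero(labels == f"c{i}")
        data[np.ix_(sel, [i % 24], post)] += 6.0
    return smrcp16_from(data), labels


class TestCrossValidation:
    def test_separated_conditions_reach_high_accuracy(self, separable):
        sm, labels = separable
        sm = make_source_epochs(sm.data, rate=16.0, t0=-3.0, labels=labels)
        res = decode.cross_validated_curves(
            sm, folds=5, repeats=2, seed=0, window_subset=np.arange(0, 88, 8)
        )
        late = res.window_ends >= 2.0
        assert res.accuracy[late].min() > 0.9
        assert res.accuracy[res.window_ends < 0.5].max() < 0.5

    def test_confusion_conservation_and_precision_range(self, separable):
        sm, labels = separable
        sm = make_source_epochs(sm.data, rate=16.0, t0=-3.0, labels=labels)
        res = decode.cross_validated_curves(
            sm, folds=5, repeats=2, seed=1, window_subset=np.arange(0, 88, 16)
        )
        counts = np.array([(labels == c).sum() for c in res.classes])
        for w in range(res.window_ends.size):
            conf = res.confusion[w]
            assert np.allclose(conf.sum(axis=1), counts)
            assert res.accuracy[w] == pytest.approx(np.trace(conf) / counts.sum())
        assert np.all((res.precision >= 0) & (res.precision <= 1))

    def test_seeded_determinism(self, separable):
        sm, labels = separable
        sm = make_source_epochs(sm.data, rate=16.0, t0=-3.0, labels=labels)
        kw = dict(folds=5, repeats=2, seed=42, window_subset=np.arange(0, 88, 16))
        r1 = decode.cross_validated_curves(sm, **kw)
        r2 = decode.cross_validated_curves(sm, **kw)
        assert np.array_equal(r1.accuracy, r2.accuracy)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_class_smaller_than_folds_rejected(self):
        data = np.zeros((8, 24, 104))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        sm = make_source_epochs(data, rate=16.0, t0=-3.0, labels=labels)
        with pytest.raises(ValueError, match="fewer trials"):
            decode.cross_validated_curves(sm, folds=5)


class TestWindowSizes:
    def test_one_sample_window_has_24_features(self):
        data = np.random.default_rng(3).standard_normal((2, 24, 104))
        X, _ = decode.extract_features(
            smrcp16_from(data), t_end=0.0, window_s=1 / 16, step_s=1 / 16
        )
        assert X.shape == (2, 24)

    def test_repeated_sizes_give_identical_rows(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(["a", "b"], 10)
        data = rng.standard_normal((20, 24, 104))
        data[labels == "b", 0, 60:] += 4
        sm = make_source_epochs(data, rate=16.0, t0=-3.0, labels=labels)
        df = decode.window_size_experiment(
            sm, sizes=(0.5, 0.5), folds=5, repeats=1, seed=0,
            window_subset=np.arange(0, 88, 16),
        )
        assert df.iloc[0]["peak_accuracy"] == df.iloc[1]["peak_accuracy"]
        assert df.iloc[0]["peak_time"] == df.iloc[1]["peak_time"]
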