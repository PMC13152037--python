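"""Metrics, fold aggregation, and the SNR noise harness."""

import numpy as np
import pytest

from coughscope.audio import Segment
from coughscope.evaluation import (add_noise_at_snr, aggregate_folds, confusion_matrix,
                                   evaluate_segments, metrics_from_confusion,
                                   noise_robustness_eval)


class TestConfusionMatrix:
    def test_perfect_classifier_is_diagonal(self, rng):
        y = rng.integers(0, 5, 40)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag(np.bincount(y, minlength=5)))

    def test_hand_enumerated_two_class(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], n_classes=2)
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_total_conserved_on_random_labelings(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 50))
            yt, yp = rng.integers(0, 5, n), rng.integers(0, 5, n)
            assert confusion_matrix(yt, yp).total == n

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1])

    def test_one_vs_rest_accounting(self, rng):
        yt, yp = rng.integers(0, 5, 200), rng.integers(0, 5, 200)
        cm = confusion_matrix(yt, yp)
        c = cm.counts
        for k in range(5):
            tp = c[k, k]
            assert tp + (c[k].sum() - tp) == c[k].sum()  # TP+FN = row total
            assert tp + (c[:, k].sum() - tp) == c[:, k].sum()  # TP+FP = col total


class TestMetrics:
    def test_diagonal_matrix_gives_perfect_scores(self):
        cm = confusion_matrix([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == 100.0
        assert np.allclose(rep.precision, 100.0)
        assert np.allclose(rep.recall, 100.0)
        assert np.allclose(rep.f1, 100.0)
        assert np.allclose(rep.specificity, 100.0)

    def test_hand_computed_binary_example(self):
        # TP=8, FN=2, FP=1, TN=9 for class 0
        cm = confusion_matrix([0] * 10 + [1] * 10, [0] * 8 + [1] * 2 + [0] * 1 + [1] * 9,
                              n_classes=2)
        rep = metrics_from_confusion(cm)
        assert rep.precision[0] == pytest.approx(88.89, abs=0.01)
        assert rep.recall[0] == pytest.approx(80.00, abs=0.01)
        assert rep.f1[0] == pytest.approx(84.21, abs=0.01)
        assert rep.specificity[0] == pytest.approx(90.00, abs=0.01)
        assert rep.accuracy == pytest.approx(85.00, abs=0.01)

    def test_matches_sklearn_on_random_matrices(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(20):
            yt, yp = rng.integers(0, 5, 100), rng.integers(0, 5, 100)
            rep = metrics_from_confusion(confusion_matrix(yt, yp))
            p, r, f, _ = precision_recall_fscore_support(
                yt, yp, labels=range(5), zero_division=0)
            assert np.allclose(rep.precision, p * 100, atol=1e-9)
            assert np.allclose(rep.recall, r * 100, atol=1e-9)
            assert np.allclose(rep.f1, f * 100, atol=1e-9)
            assert rep.accuracy == pytest.approx(100 * np.mean(yt == yp), abs=1e-9)

    def test_macro_f1_recomputable(self, rng):
        yt, yp = rng.integers(0, 5, 80), rng.integers(0, 5, 80)
        rep = metrics_from_confusion(confusion_matrix(yt, yp))
        assert rep.macro_f1 == pytest.approx(rep.f1.mean(), abs=1e-9)

    def test_undefined_ratio_flagged_as_zero(self):
        cm = confusion_matrix([0, 0, 1], [0, 0, 0], n_classes=3)
        rep = metrics_from_confusion(cm)
        assert rep.precision[2] == 0.0 and rep.recall[2] == 0.0
        assert 2 in rep.undefined_flags.get("recall", []) or 2 in rep.undefined_flags.get("precision", [])

    def test_empty_matrix_rejected(self):
        cm = confusion_matrix([], [], n_classes=3)
        with pytest.raises(ValueError):
            metrics_from_confusion(cm)

    def test_permutation_invariance(self, rng):
        yt, yp = rng.integers(0, 5, 60), rng.integers(0, 5, 60)
        perm = rng.permutation(60)
        a = metrics_from_confusion(confusion_matrix(yt, yp))
        b = metrics_from_confusion(confusion_matrix(yt[perm], yp[perm]))
        assert np.array_equal(a.f1, b.f1) and a.accuracy == b.accuracy


class TestAggregateFolds:
    def test_identical_values_zero_spread(self):
        agg = aggregate_folds([84, 84, 84, 84, 84])
        assert agg.sd == 0.0
        assert agg.ci_low == agg.ci_high == 84.0

    def test_direct_evaluation(self):
        agg = aggregate_folds([80, 82, 84, 86, 88])
        assert agg.mean == 84.0
        assert agg.sd == pytest.approx(np.sqrt(10), abs=1e-9)
        assert agg.ci_low == pytest.approx(81.23, abs=0.01)
        assert agg.ci_high == pytest.approx(86.77, abs=0.01)
        assert agg.ci_low_t < agg.ci_low  # t interval is wider at k=5

    def test_ci_width_monotone_in_sd(self, rng):
        widths = []
        for scale in (1.0, 2.0, 4.0):
            vals = 80 + scale * rng.normal(size=5)
            agg = aggregate_folds(vals)
            widths.append((agg.sd, agg.ci_high - agg.ci_low))
        widths.sort()
        assert widths[0][1] <= widths[1][1] <= widths[2][1]

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([84])


class TestAddNoise:
    def _measure_snr(self, clean, noisy):
        noise = noisy.samples - clean.samples
        return 10 * np.log10(np.mean(clean.samples**2) / np.mean(noise**2))

    def test_vanishing_noise_limit(self, rng):
        s = Segment(rng.normal(size=48_000), 16_000)
        noisy = add_noise_at_snr(s, 100.0, seed=1)
        rel = np.sqrt(np.mean((noisy.samples - s.samples) ** 2) / np.mean(s.samples**2))
        assert rel < 1e-4

    @pytest.mark.parametrize("snr", [30.0, 20.0, 10.0])
    def test_realized_snr_within_half_db(self, snr, rng):
        s = Segment(rng.normal(size=48_000), 16_000)
        noisy = add_noise_at_snr(s, snr, seed=2)
        assert abs(self._measure_snr(s, noisy) - snr) < 0.5

    def test_seeded_determinism(self, rng):
        s = Segment(rng.normal(size=1000), 16_000)
        a = add_noise_at_snr(s, 20, seed=9)
        b = add_noise_at_snr(s, 20, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_zero_segment_rejected(self):
        with pytest.raises(ValueError):
            add_noise_at_snr(Segment(np.zeros(100), 16_000), 20)


@pytest.fixture(scope="module")
def trained(tiny_dataset, tiny_net_cfg):
    from coughscope.training import TrainConfig, train_model

    segments, x, y, _ = tiny_dataset
    tr = np.arange(len(y)) % 2 == 0
    model, _ = train_model(x[tr], y[tr], x[~tr], y[~tr],
                           TrainConfig(epochs=2, seed=1), tiny_net_cfg)
    val_segments = [segments[i] for i in np.nonzero(~tr)[0]]
    return model, val_segments, y[~tr]


class TestNoiseRobustness:

    def test_table_shape_and_noiseless_row(self, trained):
        model, segs, y = trained
        table = noise_robustness_eval(model, segs, y, image_size=32,
                                      snr_list=[30, 20], seed=0)
        assert len(table) == 3
        plain = evaluate_segments(model, segs, y, image_size=32)
        assert table.iloc[0]["f1"] == plain.macro_f1
        assert table.iloc[0]["accuracy"] == plain.accuracy
        assert np.isnan(table.iloc[0]["snr_db"])

    def test_empty_test_set_rejected(self, trained):
        model, _, _ = trained
        with pytest.raises(ValueError):
            noise_robustness_eval(model, [], np.array([]), image_size=32)
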