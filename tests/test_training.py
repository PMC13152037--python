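"""Fold construction, loss, schedule, training loop and prediction contracts."""

import numpy as np
import pytest

from coughscope.nn import NetworkConfig
from coughscope.nn.optim import step_lr
from coughscope.training import (TrainConfig, cross_entropy_loss, cross_validate,
                                 evaluate_accuracy, make_folds, predict, train_model)


class TestMakeFolds:
    def test_2610_samples_five_equal_folds(self):
        ids = [f"s{i}" for i in range(2610)]
        labels = [i % 5 for i in range(2610)]
        plan = make_folds(ids, labels, k=5, seed=0)
        assert plan.fold_sizes() == [522] * 5

    def test_partition_property(self, rng):
        ids = list(range(103))
        labels = rng.integers(0, 5, 103)
        plan = make_folds(ids, labels, k=5, seed=1)
        all_ids = [sid for f in range(5) for sid in plan.fold_ids(f)]
        assert sorted(all_ids) == ids  # union is everything, no overlap
        assert max(plan.fold_sizes()) - min(plan.fold_sizes()) <= 1

    def test_stratification_within_one_sample(self, rng):
        labels = np.repeat(np.arange(5), [50, 40, 30, 20, 15])
        ids = np.arange(len(labels))
        plan = make_folds(ids, labels, k=5, seed=3)
        fold_of = np.array([plan.assignment[i] for i in ids])
        for c in range(5):
            per_fold = [np.sum((fold_of == f) & (labels == c)) for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_seed_determinism(self):
        ids = list(range(60))
        labels = [i % 5 for i in range(60)]
        a = make_folds(ids, labels, seed=5)
        b = make_folds(ids, labels, seed=5)
        assert a.assignment == b.assignment
        assert any(make_folds(ids, labels, seed=s).assignment != a.assignment
                   for s in range(6, 16))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], [0, 1, 2], k=5)


class TestCrossEntropyLoss:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy_loss([0, 1, 0, 0, 0], [0, 1, 0, 0, 0]) == 0.0

    def test_uniform_prediction_ln5(self):
        p = [0, 0, 1, 0, 0]
        q = [0.2] * 5
        assert abs(cross_entropy_loss(p, q) - np.log(5)) < 1e-12

    def test_direct_evaluation(self):
        loss = cross_entropy_loss([0, 1, 0, 0, 0], [0.1, 0.6, 0.1, 0.1, 0.1])
        assert abs(loss - (-np.log(0.6))) < 1e-12

    def test_batch_mean(self):
        p = np.eye(5)[:2]
        q = np.array([[0.6, 0.1, 0.1, 0.1, 0.1], [0.1, 0.6, 0.1, 0.1, 0.1]])
        assert abs(cross_entropy_loss(p, q) - (-np.log(0.6))) < 1e-12

    def test_zero_probability_clamped(self):
        loss = cross_entropy_loss([1, 0], [0.0, 1.0])
        assert np.isfinite(loss) and loss > 20  # -log(1e-12)


class TestSchedule:
    def test_closed_form_over_50_epochs(self):
        for e in range(50):
            assert step_lr(0.001, e) == pytest.approx(0.001 * 0.1 ** (e // 7))

    def test_boundary_epochs(self):
        assert step_lr(0.001, 6) == pytest.approx(0.001)
        assert step_lr(0.001, 7) == pytest.approx(0.0001)


class TestTrainModel:
    def test_missing_class_rejected(self, tiny_dataset, tiny_net_cfg):
        _, x, y, _ = tiny_dataset
        mask = y != 4
        with pytest.raises(ValueError):
            train_model(x[mask], y[mask], x, y, TrainConfig(epochs=1), tiny_net_cfg)

    def test_history_schedule_and_checkpoint_roundtrip(self, tiny_dataset, tiny_net_cfg, tmp_path):
        _, x, y, _ = tiny_dataset
        tr = np.arange(len(y)) % 2 == 0
        ckpt = tmp_path / "best.npz"
        cfg = TrainConfig(epochs=2, seed=3)
        model, hist = train_model(x[tr], y[tr], x[~tr], y[~tr], cfg, tiny_net_cfg,
                                  checkpoint_path=str(ckpt))
        assert hist.lr == [0.001, 0.001]
        assert len(hist.train_loss) == 2
        assert hist.best_epoch in (0, 1)
        # reloading the checkpoint reproduces the recorded best accuracy exactly
        from coughscope.nn import load_checkpoint

        reloaded, meta = load_checkpoint(str(ckpt))
        acc = evaluate_accuracy(reloaded, x[~tr], y[~tr])
        assert acc == hist.best_val_accuracy == meta["best_val_accuracy"]


@pytest.fixture(scope="module")
def fitted(tiny_dataset, tiny_net_cfg):
    _, x, y, _ = tiny_dataset
    tr = np.arange(len(y)) % 2 == 0
    model, _ = train_model(x[tr], y[tr], x[~tr], y[~tr],
                           TrainConfig(epochs=1, seed=0), tiny_net_cfg)
    return model, x


class TestPredict:

    def test_probabilities_sum_to_one(self, fitted):
        model, x = fitted
        _, proba = predict(model, x[:10])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_rule_with_tie_toward_lowest(self, fitted):
        probs = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert probs.argmax() == 0  # documented tie rule

    def test_batch_order_invariance(self, fitted, rng):
        model, x = fitted
        batch = x[:12]
        perm = rng.permutation(12)
        pred, proba = predict(model, batch)
        pred_p, proba_p = predict(model, batch[perm])
        assert np.array_equal(pred[perm], pred_p)
        assert np.allclose(proba[perm], proba_p, atol=1e-6)

    def test_geometry_mismatch_rejected(self, fitted, rng):
        model, _ = fitted
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 1, 48, 48)).astype(np.float32))


def test_cross_validation_covers_every_sample_once(tiny_dataset, tiny_net_cfg):
    _, x, y, _ = tiny_dataset
    plan, hists, oof_pred, oof_proba = cross_validate(
        x, y, k=2, seed=9, cfg=TrainConfig(epochs=1, seed=9), net_cfg=tiny_net_cfg)
    assert np.all(oof_pred >= 0)
    assert len(hists) == 2
    assert sorted(plan.fold_sizes()) == [30, 30]
    assert np.allclose(oof_proba.sum(axis=1), 1.0, atol=1e-6)
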