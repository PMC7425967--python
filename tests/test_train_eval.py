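"""Training protocol invariants and evaluation metrics."""

import numpy as np
import pytest

from mammofusion.backbone import MultiScaleAttentionDenseNet
from mammofusion.fusion import TwoViewFusionNet
from mammofusion.train_eval import (
    TrainConfig,
    compute_metrics,
    finetune_fusion,
    frozen_state_signature,
    make_folds,
    per_lesion_breakdown,
    task_label,
    train_branch,
)


def _labels(cases, task="screening"):
    return np.array([task_label(c, task) for c in cases])


class TestTrainBranch:
    def test_zero_learning_rate_leaves_weights_unchanged(self, small_spec,
                                                         phantom_cases):
        net = MultiScaleAttentionDenseNet(small_spec, seed=0)
        before = {k: v.copy() for k, v in net.state_dict().items()
                  if not k.startswith("final_bn.running")
                  and ".running_" not in k}
        cfg = TrainConfig(lr=0.0, momentum=0.0, weight_decay=0.0,
                          batch_size=4, epochs=1, seed=0)
        train_branch([c.cc for c in phantom_cases], _labels(phantom_cases),
                     net, cfg)
        after = net.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k], err_msg=k)

    def test_seeded_runs_are_identical(self, small_spec, phantom_cases):
        traces = []
        for _ in range(2):
            net = MultiScaleAttentionDenseNet(small_spec, seed=1)
            cfg = TrainConfig(batch_size=4, epochs=1, seed=3)
            _, trace = train_branch([c.cc for c in phantom_cases],
                                    _labels(phantom_cases), net, cfg)
            traces.append(trace)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_loss_decreases_in_trend(self, small_spec, phantom_cases):
        net = MultiScaleAttentionDenseNet(small_spec, seed=2)
        cfg = TrainConfig(lr=0.01, batch_size=4, epochs=6, seed=0)
        _, trace = train_branch([c.cc for c in phantom_cases],
                                _labels(phantom_cases), net, cfg)
        first, last = np.mean(trace[:3]), np.mean(trace[-3:])
        assert last < first

    def test_empty_dataset_rejected(self, small_spec):
        net = MultiScaleAttentionDenseNet(small_spec, seed=0)
        with pytest.raises(ValueError):
            train_branch([], np.array([]), net, TrainConfig(epochs=1))


class TestFinetuneFusion:
    def test_freeze_audit_and_fusion_update(self, small_spec, phantom_cases):
        net = TwoViewFusionNet(small_spec, task="screening", fusion_width=16,
                               seed=0)
        sig_before = frozen_state_signature(net)
        fusion_before = net.fusion.weight.data.copy()
        cfg = TrainConfig(lr=0.01, batch_size=4, epochs=2, seed=0)
        trace = finetune_fusion(list(phantom_cases), _labels(phantom_cases),
                                net, cfg)
        # every convolutional/BN parameter and buffer is bit-identical
        assert frozen_state_signature(net) == sig_before
        # the fusion layer did move
        assert not np.array_equal(net.fusion.weight.data, fusion_before)
        # descent on the training objective at small lr
        assert np.mean(trace[-4:]) <= np.mean(trace[:4])

    def test_empty_dataset_rejected(self, small_spec):
        net = TwoViewFusionNet(small_spec, fusion_width=16, seed=0)
        with pytest.raises(ValueError):
            finetune_fusion([], np.array([]), net, TrainConfig(epochs=1))


class TestMakeFolds:
    def test_exact_stratification(self):
        labels = np.array([0] * 50 + [1] * 50)
        plan = make_folds(labels, k=10, seed=0)
        for fold in range(10):
            _, val = plan.fold_indices(fold)
            assert len(val) == 10
            assert (labels[val] == 0).sum() == 5
            assert (labels[val] == 1).sum() == 5

    def test_partition_properties(self):
        labels = np.array([0] * 23 + [1] * 31)
        plan = make_folds(labels, k=5, seed=1)
        all_val = np.concatenate([plan.fold_indices(f)[1] for f in range(5)])
        assert sorted(all_val) == list(range(54))
        for f in range(5):
            train, val = plan.fold_indices(f)
            assert len(np.intersect1d(train, val)) == 0

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        a = make_folds(labels, k=4, seed=7)
        b = make_folds(labels, k=4, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_small_class_rejected_by_name(self):
        labels = np.array(["big"] * 30 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            make_folds(labels, k=10, seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        rep = compute_metrics(labels, scores)
        assert rep.auc == pytest.approx(1.0)
        assert rep.sensitivity == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # TP=1, FN=1 at threshold 0.5 -> sensitivity 1/2;
        # discordant-pair ordering: 3 of 4 pairs correct -> AUC 3/4
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        rep = compute_metrics(labels, scores, threshold=0.5)
        assert rep.sensitivity == pytest.approx(0.5)
        assert rep.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        rep = compute_metrics(np.array([0, 1, 0, 1]), np.full(4, 0.5))
        assert rep.auc == pytest.approx(0.5)

    def test_single_class_auc_undefined(self):
        rep = compute_metrics(np.ones(5, dtype=int), np.linspace(0.1, 0.9, 5))
        assert rep.auc is None
        rep = compute_metrics(np.zeros(5, dtype=int), np.linspace(0.1, 0.9, 5))
        assert rep.auc is None and rep.sensitivity is None

    def test_roc_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        rep = compute_metrics(labels, scores)
        pts = np.array(rep.roc_points)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_trapezoid_equals_pairwise_ordering_statistic(self, rng):
        # the Mann-Whitney identity, including ties counted one half
        for trial in range(20):
            n = int(rng.integers(8, 120))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            rep = compute_metrics(labels, scores)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            mw = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert rep.auc == pytest.approx(mw, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        rep = compute_metrics(labels, scores)
        assert rep.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 2]), np.array([0.5, 0.5]))


class TestPerLesionBreakdown:
    def test_all_correct_gives_ones(self, phantom_cases):
        preds = ["abnormal" if c.is_abnormal else "normal"
                 for c in phantom_cases]
        out = per_lesion_breakdown(list(phantom_cases), preds, "screening")
        assert out["mass"] == 1.0
        assert out["calcification"] == 1.0

    def test_planted_errors_hit_only_one_subset(self, phantom_cases):
        preds = []
        for c in phantom_cases:
            if c.is_abnormal and c.lesion_type == "calcification":
                preds.append("normal")  # planted miss
            elif c.is_abnormal:
                preds.append("abnormal")
            else:
                preds.append("normal")
        out = per_lesion_breakdown(list(phantom_cases), preds, "screening")
        assert out["mass"] == 1.0
        assert out["calcification"] < 1.0

    def test_subset_counts_recombine(self, phantom_cases):
        rng = np.random.default_rng(0)
        preds = [("abnormal" if rng.random() > 0.3 else "normal")
                 if c.is_abnormal else "normal" for c in phantom_cases]
        out = per_lesion_breakdown(list(phantom_cases), preds, "screening")
        n_mass = sum(1 for c in phantom_cases if c.lesion_type == "mass")
        n_calc = sum(1 for c in phantom_cases
                     if c.lesion_type == "calcification")
        total_correct = sum(
            p == "abnormal" for c, p in zip(phantom_cases, preds)
            if c.is_abnormal)
        recombined = out["mass"] * n_mass + out["calcification"] * n_calc
        assert recombined == pytest.approx(total_correct)
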