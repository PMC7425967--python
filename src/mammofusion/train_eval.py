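"""Training protocol and evaluation metrics.

Training follows a two-phase protocol: each view branch (backbone + its own
softmax head) is first trained on single-view images; the two-view model is
then fine-tuned with every convolutional and batch-norm parameter frozen —
only the fusion layer and classification head are updated, and frozen
branches run with evaluation-mode batch-norm statistics.

The optimizer is momentum SGD (lr 0.001, momentum 0.9, weight decay 1e-4,
mini-batch 16, 300 epochs by default — all overridable for desk-scale
runs). The loss is cross-entropy on the 2-class softmax.

Evaluation provides accuracy, sensitivity (TP / (TP + FN)), an ROC curve
swept over the unique scores, trapezoidal AUC, stratified k-fold plans and
the per-lesion-type accuracy breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .backbone import MultiScaleAttentionDenseNet
from .cases import CasePair
from .fusion import CLASS_NAMES, TwoViewFusionNet, two_view_forward
from .nn import Linear, SGD, Tensor, no_grad, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "EvalReport",
    "train_branch",
    "finetune_fusion",
    "make_folds",
    "compute_metrics",
    "per_lesion_breakdown",
    "evaluate_two_view",
    "frozen_state_signature",
    "task_label",
]


@dataclass
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # fold index per case
    labels: np.ndarray

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one fold."""
        val = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float | None
    roc_points: list[tuple[float, float]]
    auc: float | None
    per_lesion_accuracy: dict[str, float] = field(default_factory=dict)


def task_label(case: CasePair, task: str) -> int:
    """Binary target for a task: screening 1=abnormal; diagnosis 1=malignant."""
    if task == "screening":
        return int(case.label != "normal")
    if task == "diagnosis":
        if case.label == "normal":
            raise ValueError("diagnosis task is defined on abnormal cases only")
        return int(case.label == "malignant")
    raise ValueError(f"unknown task {task!r}")


# ------------------------------------------------------------------ training
def _as_batch(images: list[np.ndarray], idx: np.ndarray) -> Tensor:
    arrs = []
    for i in idx:
        a = np.asarray(images[i], dtype=np.float64)
        if a.ndim == 2:
            a = a[None]
        arrs.append(a)
    return Tensor(np.stack(arrs))


def train_branch(images: list[np.ndarray], labels: np.ndarray,
                 backbone: MultiScaleAttentionDenseNet,
                 cfg: TrainConfig | None = None) -> tuple[Linear, list[float]]:
    """Phase 1: train one view branch (backbone + fresh 2-way head) with SGD.

    Returns the attached head and the per-step loss trace. Aborts with a
    diagnostic on an empty dataset or a non-finite loss.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    labels = np.asarray(labels, dtype=np.intp)
    if len(images) == 0:
        raise ValueError("cannot train on an empty dataset")
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    rng = np.random.default_rng(cfg.seed)
    head = Linear(backbone.feature_dim, 2, rng=rng)
    opt = SGD(backbone.parameters() + head.parameters(), lr=cfg.lr,
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    backbone.train()
    trace: list[float] = []
    n = len(images)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = _as_batch(images, idx)
            logits = head(backbone(x))
            loss = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}, step {start // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(loss.item())
    return head, trace


def frozen_state_signature(net: TwoViewFusionNet) -> dict[str, bytes]:
    """Byte-exact snapshot of every convolutional/BN parameter and buffer in
    both branches — the freeze audit compares this before vs after phase 2."""
    sig: dict[str, bytes] = {}
    for branch_name, branch in (("cc", net.branch_cc), ("mlo", net.branch_mlo)):
        for name, p in branch.named_parameters():
            sig[f"{branch_name}.{name}"] = p.data.tobytes()
        for name, b in branch.named_buffers():
            sig[f"{branch_name}.{name}"] = b.tobytes()
    return sig


def finetune_fusion(cases: list[CasePair], labels: np.ndarray,
                    net: TwoViewFusionNet,
                    cfg: TrainConfig | None = None) -> list[float]:
    """Phase 2: fine-tune the fusion layer + head on two-view pairs.

    Branch parameters are excluded from the optimizer and branches run in
    evaluation mode (frozen BN statistics), so branch features can be
    computed once up front. Returns the per-step loss trace.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    labels = np.asarray(labels, dtype=np.intp)
    if len(cases) == 0:
        raise ValueError("cannot fine-tune on an empty dataset")
    net.branch_cc.eval()
    net.branch_mlo.eval()
    with no_grad():
        f_cc = np.stack([
            net.branch_cc(TwoViewFusionNet._view_tensor(c.cc)).data[0] for c in cases
        ])
        f_mlo = np.stack([
            net.branch_mlo(TwoViewFusionNet._view_tensor(c.mlo)).data[0] for c in cases
        ])
    opt = SGD(net.fusion_parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    n = len(cases)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward_from_features(Tensor(f_cc[idx]), Tensor(f_mlo[idx]))
            loss = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError("non-finite loss during fusion fine-tuning")
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(loss.item())
    return trace


# ---------------------------------------------------------------- evaluation
def make_folds(labels: np.ndarray | list, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified disjoint folds covering all cases, reproducible from seed."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    values, counts = np.unique(labels, return_counts=True)
    for v, c in zip(values, counts):
        if c < k:
            raise ValueError(f"class {v!r} has only {c} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.intp)
    for fold, (_tr, val) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[val] = fold
    return FoldPlan(k=k, assignments=assignments, labels=labels)


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> EvalReport:
    """Accuracy/sensitivity at the threshold, ROC over unique scores, and
    trapezoidal AUC. A single-class label vector yields AUC = None."""
    labels = np.asarray(labels, dtype=np.intp)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.all((scores >= 0) & (scores <= 1)):
        raise ValueError("scores must lie in [0, 1]")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    pred = scores >= threshold
    accuracy = float((pred == labels.astype(bool)).mean())
    pos = labels == 1
    sensitivity = float(pred[pos].mean()) if pos.any() else None
    if pos.all() or not pos.any():
        return EvalReport(accuracy, sensitivity, [], None)

    # threshold sweep from above-max downwards; ties fall together, which
    # makes the trapezoid equal to the tie-aware pairwise-ordering statistic
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / pos.sum()]
    fpr = np.r_[0.0, fps / (~pos).sum()]
    auc = float(np.trapezoid(tpr, fpr))
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return EvalReport(accuracy, sensitivity, roc_points, auc)


def per_lesion_breakdown(cases: list[CasePair], predictions: list[str],
                         task: str) -> dict[str, float]:
    """Accuracy over mass vs calcification subsets of the abnormal cases.

    ``predictions`` are task labels per case (screening: normal/abnormal;
    diagnosis: benign/malignant). Abnormal cases without a lesion type are
    excluded with a warning.
    """
    if len(cases) != len(predictions):
        raise ValueError("cases and predictions length mismatch")
    tally: dict[str, list[int]] = {"mass": [], "calcification": []}
    for case, pred in zip(cases, predictions):
        if case.label == "normal":
            continue
        if case.lesion_type not in tally:
            warnings.warn(f"abnormal case {case.case_id!r} lacks a lesion type; excluded")
            continue
        if task == "screening":
            correct = pred == "abnormal"
        elif task == "diagnosis":
            correct = pred == case.label
        else:
            raise ValueError(f"unknown task {task!r}")
        tally[case.lesion_type].append(int(correct))
    return {
        lesion: (float(np.mean(v)) if v else float("nan"))
        for lesion, v in tally.items()
    }


def evaluate_two_view(net: TwoViewFusionNet, cases: list[CasePair],
                      threshold: float = 0.5) -> tuple[EvalReport, np.ndarray]:
    """Score every case with the fusion model and compute the task metrics."""
    task = net.task
    scores = np.array([two_view_forward(c, net, threshold).score for c in cases])
    labels = np.array([task_label(c, task) for c in cases])
    report = compute_metrics(labels, scores, threshold)
    names = CLASS_NAMES[task]
    preds = [names[1] if s >= threshold else names[0] for s in scores]
    report.per_lesion_accuracy = per_lesion_breakdown(cases, preds, task)
    return report, scores
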