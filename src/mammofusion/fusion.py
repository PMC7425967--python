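"""Two-branch multi-view fusion model and the two-stage cascade.

Two architecturally identical (but independently parameterised) multi-scale
attention DenseNets extract feature vectors from the CC and MLO views. The
vectors are concatenated and passed through a fully connected fusion layer
with 1024 hidden nodes (ReLU) and a 2-way softmax head. Screening
(normal vs abnormal) and diagnosis (benign vs malignant) are separate
models chained into a cascade: cases called abnormal at stage 1 are sent to
stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneSpec, MultiScaleAttentionDenseNet
from .cases import CasePair
from .nn import Linear, Module, Tensor, concat, no_grad, softmax

__all__ = [
    "Prediction",
    "StagedResult",
    "TwoViewFusionNet",
    "two_view_forward",
    "classify_two_stage",
    "TASKS",
]

TASKS = ("screening", "diagnosis")

# positive class per task: abnormal for screening, malignant for diagnosis
POSITIVE_CLASS = {"screening": "abnormal", "diagnosis": "malignant"}
CLASS_NAMES = {
    "screening": ("normal", "abnormal"),
    "diagnosis": ("benign", "malignant"),
}


@dataclass
class Prediction:
    """Two-class softmax output: probs sums to 1; P is the positive-class score."""

    probs: np.ndarray
    score: float
    label: str

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (2,):
            raise ValueError("expected a 2-class probability vector")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-6):
            raise ValueError("probabilities must sum to 1")


@dataclass
class StagedResult:
    """Cascade output carrying both stage probabilities."""

    stage1_prob: float           # P(abnormal)
    stage1_label: str            # normal / abnormal
    stage2_prob: float | None    # P(malignant), None if stage 2 not invoked
    stage2_label: str | None
    final_label: str             # normal / benign / malignant


class TwoViewFusionNet(Module):
    """Independent CC and MLO backbones + 1024-node fusion layer + softmax head."""

    def __init__(self, spec: BackboneSpec | None = None, task: str = "screening",
                 fusion_width: int = 1024, seed: int = 0):
        super().__init__()
        if task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        self.spec = spec if spec is not None else BackboneSpec()
        self.task = task
        self.fusion_width = fusion_width
        # branches share architecture, never weights
        self.branch_cc = MultiScaleAttentionDenseNet(self.spec, seed=seed)
        self.branch_mlo = MultiScaleAttentionDenseNet(self.spec, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        feat = self.branch_cc.feature_dim
        self.fusion = Linear(2 * feat, fusion_width, rng=rng)
        self.head = Linear(fusion_width, 2, rng=rng)

    # ---------------------------------------------------------------- forward
    def forward(self, cc: Tensor, mlo: Tensor) -> Tensor:
        f_cc = self.branch_cc(cc)
        f_mlo = self.branch_mlo(mlo)
        fused = self.fusion(concat([f_cc, f_mlo], axis=1)).relu()
        return self.head(fused)

    def forward_from_features(self, f_cc: Tensor, f_mlo: Tensor) -> Tensor:
        """Fusion + head only, for phase-2 training on precomputed features."""
        fused = self.fusion(concat([f_cc, f_mlo], axis=1)).relu()
        return self.head(fused)

    # -------------------------------------------------------------- inference
    @staticmethod
    def _view_tensor(view: np.ndarray) -> Tensor:
        view = np.asarray(view, dtype=np.float64)
        if view.ndim == 2:
            view = view[None]
        if view.ndim != 3:
            raise ValueError("view must be (H, W) or (1, H, W)")
        return Tensor(view[None])

    def predict_proba_pair(self, cc: np.ndarray, mlo: np.ndarray) -> np.ndarray:
        if cc is None or mlo is None:
            raise ValueError("both CC and MLO views are required (no single-view fallback)")
        self.eval()
        with no_grad():
            logits = self.forward(self._view_tensor(cc), self._view_tensor(mlo))
        return softmax(logits.data)[0]

    def fusion_parameters(self):
        """Parameters of the fusion layer and head only (phase-2 trainables)."""
        return self.fusion.parameters() + self.head.parameters()

    def branch_parameters(self):
        return self.branch_cc.parameters() + self.branch_mlo.parameters()


def two_view_forward(case: CasePair, net: TwoViewFusionNet,
                     threshold: float = 0.5) -> Prediction:
    """Forward one case through the fusion model; P is the positive-class score."""
    probs = net.predict_proba_pair(case.cc, case.mlo)
    names = CLASS_NAMES[net.task]
    label = names[1] if probs[1] >= threshold else names[0]
    return Prediction(probs=probs, score=float(probs[1]), label=label)


def classify_two_stage(case: CasePair, screening: TwoViewFusionNet,
                       diagnosis: TwoViewFusionNet,
                       threshold: float = 0.5) -> StagedResult:
    """Stage 1 gates on P(abnormal) >= threshold; stage 2 resolves benign vs
    malignant only for cases called abnormal."""
    if screening.task != "screening" or diagnosis.task != "diagnosis":
        raise ValueError("pass a screening model and a diagnosis model, in that order")
    p1 = two_view_forward(case, screening, threshold)
    if p1.label == "normal":
        return StagedResult(p1.score, "normal", None, None, "normal")
    p2 = two_view_forward(case, diagnosis, threshold)
    return StagedResult(p1.score, "abnormal", p2.score, p2.label, p2.label)
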