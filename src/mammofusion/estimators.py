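"""scikit-learn-compatible estimator surface.

:class:`TwoViewMammogramClassifier` wraps the two-phase protocol (branch
training, then fusion fine-tuning with frozen convolutions) behind the
familiar ``fit`` / ``predict_proba`` / ``predict`` API, so the model composes
with sklearn model selection. ``X`` is a list of :class:`CasePair`; ``y`` is
optional and defaults to the task labels carried by the cases.

Defaults instantiate the canonical architecture (512x512 input, blocks
6/12/24/32/16, growth rate 32, 1024 fusion nodes, SGD lr 0.001 / momentum
0.9 / weight decay 1e-4 / batch 16); pass reduced settings for desk-scale
experiments.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .backbone import BackboneSpec, CANONICAL_BLOCK_SIZES
from .cases import CasePair
from .fusion import CLASS_NAMES, TwoViewFusionNet, classify_two_stage
from .preprocess import PreprocessConfig, preprocess
from .train_eval import TrainConfig, finetune_fusion, task_label, train_branch

__all__ = [
    "TwoViewMammogramClassifier",
    "TwoStageMammogramClassifier",
    "MammogramPreprocessor",
]


class TwoViewMammogramClassifier(BaseEstimator, ClassifierMixin):
    """Two-branch multi-view classifier for one binary task."""

    def __init__(self, task: str = "screening", image_size: int = 512,
                 block_sizes: tuple[int, ...] = CANONICAL_BLOCK_SIZES,
                 growth_rate: int = 32, stem_channels: int = 64,
                 reduction_ratio: int = 16, batch_norm: bool = True,
                 fusion_width: int = 1024, lr: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 batch_size: int = 16, branch_epochs: int = 300,
                 fusion_epochs: int = 300, threshold: float = 0.5,
                 seed: int = 0):
        self.task = task
        self.image_size = image_size
        self.block_sizes = block_sizes
        self.growth_rate = growth_rate
        self.stem_channels = stem_channels
        self.reduction_ratio = reduction_ratio
        self.batch_norm = batch_norm
        self.fusion_width = fusion_width
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.branch_epochs = branch_epochs
        self.fusion_epochs = fusion_epochs
        self.threshold = threshold
        self.seed = seed

    # ------------------------------------------------------------------ build
    def _spec(self) -> BackboneSpec:
        return BackboneSpec(
            input_size=self.image_size, stem_channels=self.stem_channels,
            block_sizes=tuple(self.block_sizes), growth_rate=self.growth_rate,
            reduction_ratio=self.reduction_ratio, batch_norm=self.batch_norm,
        )

    def _train_cfg(self, epochs: int) -> TrainConfig:
        return TrainConfig(lr=self.lr, momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           batch_size=self.batch_size, epochs=epochs,
                           seed=self.seed)

    @staticmethod
    def _check_cases(X) -> list[CasePair]:
        if not X or not all(isinstance(c, CasePair) for c in X):
            raise ValueError("X must be a non-empty list of CasePair")
        return list(X)

    def _binary_labels(self, cases: list[CasePair], y) -> np.ndarray:
        if y is None:
            return np.array([task_label(c, self.task) for c in cases])
        y = np.asarray(y)
        if y.dtype.kind in "US":
            names = CLASS_NAMES[self.task]
            if not set(y) <= set(names):
                raise ValueError(f"string labels must come from {names}")
            return (y == names[1]).astype(int)
        return y.astype(int)

    # -------------------------------------------------------------------- fit
    def fit(self, X, y=None):
        cases = self._check_cases(X)
        labels = self._binary_labels(cases, y)
        net = TwoViewFusionNet(self._spec(), task=self.task,
                               fusion_width=self.fusion_width, seed=self.seed)
        cfg1 = self._train_cfg(self.branch_epochs)
        _, self.loss_trace_cc_ = train_branch(
            [c.cc for c in cases], labels, net.branch_cc, cfg1)
        _, self.loss_trace_mlo_ = train_branch(
            [c.mlo for c in cases], labels, net.branch_mlo, cfg1)
        self.loss_trace_fusion_ = finetune_fusion(
            cases, labels, net, self._train_cfg(self.fusion_epochs))
        self.net_ = net
        self.classes_ = np.array(CLASS_NAMES[self.task])
        return self

    # -------------------------------------------------------------- inference
    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        cases = self._check_cases(X)
        return np.stack([self.net_.predict_proba_pair(c.cc, c.mlo) for c in cases])

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[(probs[:, 1] >= self.threshold).astype(int)]

    def score(self, X, y=None) -> float:
        cases = self._check_cases(X)
        labels = self._binary_labels(cases, y)
        probs = self.predict_proba(X)
        return float(((probs[:, 1] >= self.threshold).astype(int) == labels).mean())


class TwoStageMammogramClassifier(BaseEstimator, ClassifierMixin):
    """Cascade of a screening and a diagnosis model: normal vs abnormal
    first, benign vs malignant for cases called abnormal."""

    def __init__(self, screening: TwoViewMammogramClassifier | None = None,
                 diagnosis: TwoViewMammogramClassifier | None = None,
                 threshold: float = 0.5):
        self.screening = screening
        self.diagnosis = diagnosis
        self.threshold = threshold

    def fit(self, X, y=None):
        cases = TwoViewMammogramClassifier._check_cases(X)
        scr = self.screening if self.screening is not None \
            else TwoViewMammogramClassifier(task="screening")
        dia = self.diagnosis if self.diagnosis is not None \
            else TwoViewMammogramClassifier(task="diagnosis")
        if scr.task != "screening" or dia.task != "diagnosis":
            raise ValueError("stage estimators must have tasks screening/diagnosis")
        self.screening_ = scr.fit(cases)
        abnormal = [c for c in cases if c.is_abnormal]
        self.diagnosis_ = dia.fit(abnormal)
        self.classes_ = np.array(["normal", "benign", "malignant"])
        return self

    def predict(self, X) -> np.ndarray:
        cases = TwoViewMammogramClassifier._check_cases(X)
        out = [
            classify_two_stage(c, self.screening_.net_, self.diagnosis_.net_,
                               self.threshold).final_label
            for c in cases
        ]
        return np.array(out)

    def staged_results(self, X):
        cases = TwoViewMammogramClassifier._check_cases(X)
        return [classify_two_stage(c, self.screening_.net_, self.diagnosis_.net_,
                                   self.threshold) for c in cases]

    def score(self, X, y=None) -> float:
        cases = TwoViewMammogramClassifier._check_cases(X)
        truth = np.array([c.label for c in cases]) if y is None else np.asarray(y)
        return float((self.predict(cases) == truth).mean())


class MammogramPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the preprocessing chain per image."""

    def __init__(self, clahe_clip: float = 2.0, clahe_tiles: tuple[int, int] = (8, 8),
                 bilateral_diameter: int = 9, bilateral_sigma_color: float = 75.0,
                 bilateral_sigma_space: float = 75.0, target_size: int = 512):
        self.clahe_clip = clahe_clip
        self.clahe_tiles = clahe_tiles
        self.bilateral_diameter = bilateral_diameter
        self.bilateral_sigma_color = bilateral_sigma_color
        self.bilateral_sigma_space = bilateral_sigma_space
        self.target_size = target_size

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            clahe_clip=self.clahe_clip, clahe_tiles=tuple(self.clahe_tiles),
            bilateral_diameter=self.bilateral_diameter,
            bilateral_sigma_color=self.bilateral_sigma_color,
            bilateral_sigma_space=self.bilateral_sigma_space,
            target_size=self.target_size,
        )

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[np.ndarray]:
        cfg = self._config()
        return [preprocess(img, cfg) for img in X]
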