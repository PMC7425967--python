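"""The per-breast case container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CasePair", "LABELS", "LESION_TYPES"]

LABELS = ("normal", "benign", "malignant")
LESION_TYPES = ("mass", "calcification")


@dataclass
class CasePair:
    """One breast: paired craniocaudal (CC) and mediolateral-oblique (MLO)
    views with a per-breast label and, for synthetic data, lesion masks.

    Views are 2-D float arrays in [0, 1]; the channel axis the networks
    expect is added at model input.
    """

    cc: np.ndarray
    mlo: np.ndarray
    label: str
    lesion_type: str | None = None
    cc_mask: np.ndarray | None = None
    mlo_mask: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self):
        if self.cc is None or self.mlo is None:
            raise ValueError("both CC and MLO views are required")
        self.cc = np.asarray(self.cc, dtype=np.float64)
        self.mlo = np.asarray(self.mlo, dtype=np.float64)
        if self.cc.ndim != 2 or self.mlo.ndim != 2:
            raise ValueError("views must be 2-D (H, W) arrays")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.label == "normal":
            if self.lesion_type is not None:
                raise ValueError("normal cases cannot carry a lesion type")
        else:
            if self.lesion_type not in LESION_TYPES:
                raise ValueError(
                    f"abnormal cases need a lesion type from {LESION_TYPES}"
                )
        for mask, view, name in ((self.cc_mask, self.cc, "cc"),
                                 (self.mlo_mask, self.mlo, "mlo")):
            if mask is not None and mask.shape != view.shape:
                raise ValueError(f"{name} mask shape does not match the view")

    @property
    def is_abnormal(self) -> bool:
        return self.label != "normal"
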