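"""Checkpointing and on-disk dataset conventions.

A checkpoint is a single ``.npz`` archive holding every parameter and
batch-norm buffer of a two-view fusion model plus an embedded JSON manifest
describing the architecture, so a checkpoint is self-describing.

The dataset layout is ``<root>/<case_id>/{cc.png, mlo.png}`` with a
``labels.csv`` (case_id, label, lesion_type) at the root; phantom masks are
stored alongside the views when available.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from imageio.v3 import imread, imwrite

from .backbone import BackboneSpec
from .cases import CasePair
from .fusion import TwoViewFusionNet

__all__ = ["save_checkpoint", "load_checkpoint", "save_dataset", "load_dataset",
           "new_run_dir"]


# ------------------------------------------------------------- checkpointing
def save_checkpoint(path: str | Path, net: TwoViewFusionNet,
                    extra: dict | None = None) -> Path:
    path = Path(path)
    manifest = {
        "format": "mammofusion-checkpoint-v1",
        "task": net.task,
        "fusion_width": net.fusion_width,
        "spec": asdict(net.spec),
        "extra": extra or {},
    }
    state = {f"state::{k}": v for k, v in net.state_dict().items()}
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, __manifest__=json.dumps(manifest), **state)
    return path


def load_checkpoint(path: str | Path) -> TwoViewFusionNet:
    with np.load(Path(path), allow_pickle=False) as archive:
        manifest = json.loads(str(archive["__manifest__"]))
        if manifest.get("format") != "mammofusion-checkpoint-v1":
            raise ValueError("not a recognised checkpoint file")
        spec_d = dict(manifest["spec"])
        spec_d["block_sizes"] = tuple(spec_d["block_sizes"])
        net = TwoViewFusionNet(BackboneSpec(**spec_d), task=manifest["task"],
                               fusion_width=manifest["fusion_width"])
        state = {k[len("state::"):]: archive[k] for k in archive.files
                 if k.startswith("state::")}
    net.load_state_dict(state)
    return net


# ------------------------------------------------------------------ datasets
def _write_png(path: Path, img: np.ndarray) -> None:
    imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def save_dataset(cases: list[CasePair], root: str | Path) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        d = root / case.case_id
        d.mkdir(exist_ok=True)
        _write_png(d / "cc.png", case.cc)
        _write_png(d / "mlo.png", case.mlo)
        if case.cc_mask is not None:
            _write_png(d / "cc_mask.png", case.cc_mask.astype(float))
            _write_png(d / "mlo_mask.png", case.mlo_mask.astype(float))
        rows.append((case.case_id, case.label, case.lesion_type or ""))
    with open(root / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "lesion_type"])
        writer.writerows(rows)
    return root


def load_dataset(root: str | Path, with_masks: bool = True) -> list[CasePair]:
    root = Path(root)
    labels_file = root / "labels.csv"
    if not labels_file.exists():
        raise FileNotFoundError(f"no labels.csv under {root}")
    cases = []
    with open(labels_file, newline="") as fh:
        for row in csv.DictReader(fh):
            d = root / row["case_id"]
            cc = imread(d / "cc.png").astype(np.float64) / 255.0
            mlo = imread(d / "mlo.png").astype(np.float64) / 255.0
            cc_mask = mlo_mask = None
            if with_masks and (d / "cc_mask.png").exists():
                cc_mask = imread(d / "cc_mask.png") > 127
                mlo_mask = imread(d / "mlo_mask.png") > 127
            cases.append(CasePair(
                cc=cc, mlo=mlo, label=row["label"],
                lesion_type=row["lesion_type"] or None,
                cc_mask=cc_mask, mlo_mask=mlo_mask, case_id=row["case_id"],
            ))
    return cases


def new_run_dir(output_root: str | Path, prefix: str = "run") -> Path:
    """Next versioned run directory (run-0001, run-0002, ...); never overwrites."""
    output_root = Path(output_root)
    output_root.mkdir(parents=True, exist_ok=True)
    n = 1
    while (output_root / f"{prefix}-{n:04d}").exists():
        n += 1
    d = output_root / f"{prefix}-{n:04d}"
    d.mkdir()
    return d
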