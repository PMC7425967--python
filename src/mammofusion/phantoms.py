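"""Synthetic two-view mammogram phantoms.

Each phantom renders a breast-shaped half-elliptical bright region against a
dark background with smoothed-noise tissue texture; the MLO view adds a
pectoral-muscle wedge in the upper corner. Abnormal cases plant one lesion
at a shared normalized position (depth along the chest-wall/nipple axis and
a lateral offset) in both views, emulating the inter-view correlation that
the two-branch fusion model exploits — there is no physical projection
model, only the shared coordinate.

Lesions come in the two mammographic types: a mass (Gaussian-profile focal
density; malignant masses carry radial spiculation spikes) or a cluster of
``n_calcifications`` bright 1-3 px specks. Ground-truth binary masks are
returned for every planted lesion. Generation is fully deterministic from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

from .cases import CasePair, LABELS, LESION_TYPES

__all__ = ["PhantomSpec", "generate_case", "generate_dataset"]


@dataclass
class PhantomSpec:
    image_size: int = 512
    label: str = "normal"
    lesion_type: str | None = None
    n_calcifications: int = 6
    mass_radius_frac: tuple[float, float] = (0.03, 0.055)  # fraction of image size
    spiculation: int = 8                                   # spike count, malignant masses
    background_texture_scale: float = 0.05                 # texture amplitude
    lesion_contrast: float = 0.40                          # added intensity at lesion core
    seed: int = 0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.label == "normal":
            if self.lesion_type is not None:
                raise ValueError("normal phantoms cannot carry a lesion")
        else:
            if self.lesion_type not in LESION_TYPES:
                raise ValueError(f"abnormal phantoms need a lesion type from {LESION_TYPES}")
            if self.lesion_type == "calcification" and self.n_calcifications < 1:
                raise ValueError("need at least one calcification speck")
        if self.image_size < 32:
            raise ValueError("image size too small for a meaningful phantom")


# ----------------------------------------------------------------- rendering
def _breast_mask_cc(size: int, cy: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    a, b = 0.85 * size, 0.42 * size  # chest-wall depth, half-height
    return (xx / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _breast_mask_mlo(size: int, cy: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    # oblique: ellipse tilted downwards, attached to the left edge
    u = (xx + 0.25 * (yy - cy)) / (0.80 * size)
    v = (yy - cy - 0.10 * xx) / (0.46 * size)
    return u ** 2 + v ** 2 <= 1.0


def _pectoral_wedge(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return yy < 0.45 * size - 1.1 * xx


def _texture(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=(size, size))
    smooth = gaussian_filter(noise, sigma=max(1.0, size / 64.0))
    smooth /= max(smooth.std(), 1e-12)
    return amplitude * smooth


def _lesion_center(view: str, size: int, cy: float, depth: float,
                   lateral: float) -> tuple[int, int]:
    """Map the shared (depth, lateral) coordinate into view pixel space."""
    if view == "cc":
        row = cy + lateral * 0.30 * size
        col = depth * 0.70 * size
    else:  # MLO: oblique axis, same depth/lateral coordinate
        col = depth * 0.62 * size
        row = cy + 0.10 * col + lateral * 0.32 * size
    return int(round(row)), int(round(col))


def _paint_mass(img: np.ndarray, mask: np.ndarray, center: tuple[int, int],
                radius: float, contrast: float, spiculated: bool,
                n_spikes: int, rng: np.random.Generator) -> None:
    size = img.shape[0]
    r0, c0 = center
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy - r0) ** 2 + (xx - c0) ** 2
    sigma = radius / 1.8
    img += contrast * np.exp(-d2 / (2.0 * sigma ** 2))
    mask |= d2 <= radius ** 2
    if spiculated:
        for i in range(n_spikes):
            ang = 2.0 * np.pi * i / n_spikes + rng.uniform(-0.15, 0.15)
            length = radius * rng.uniform(1.6, 2.2)
            r1 = int(np.clip(round(r0 + length * np.sin(ang)), 0, size - 1))
            c1 = int(np.clip(round(c0 + length * np.cos(ang)), 0, size - 1))
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            img[rr[keep], cc[keep]] += contrast * 0.6
            mask[rr[keep], cc[keep]] = True


def _paint_calcifications(img: np.ndarray, mask: np.ndarray,
                          center: tuple[int, int], n: int, contrast: float,
                          malignant: bool, rng: np.random.Generator) -> None:
    """Plant exactly ``n`` separated bright specks. Benign clusters are
    compact and isotropic; malignant ones scatter along a line (a crude
    segmental distribution) — the cue the diagnosis task can learn."""
    size = img.shape[0]
    r0, c0 = center
    cluster_r = max(6.0, 0.035 * size)
    axis = rng.uniform(0, np.pi)
    stretch = 3.0 if malignant else 1.0
    min_sep = 5
    points: list[tuple[int, int]] = []
    attempts = 0
    while len(points) < n and attempts < 10000:
        attempts += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = cluster_r * np.sqrt(rng.uniform())
        dr = rad * np.sin(ang)
        dc = rad * np.cos(ang)
        along = dr * np.sin(axis) + dc * np.cos(axis)
        across = -dr * np.cos(axis) + dc * np.sin(axis)
        r = int(round(r0 + stretch * along * np.sin(axis) + across * -np.cos(axis)))
        c = int(round(c0 + stretch * along * np.cos(axis) + across * np.sin(axis)))
        if not (2 <= r < size - 2 and 2 <= c < size - 2):
            continue
        # Chebyshev separation: 3x3 specks stay disconnected (8-connectivity)
        if any(max(abs(r - pr), abs(c - pc)) < min_sep for pr, pc in points):
            cluster_r *= 1.01  # relax gradually if the cluster is crowded
            continue
        points.append((r, c))
    for r, c in points:
        half = int(rng.integers(0, 2))  # speck half-width: 1x1 or 3x3 support
        img[r - half:r + half + 1, c - half:c + half + 1] += contrast + 0.15
        mask[r - half:r + half + 1, c - half:c + half + 1] = True


def _render_view(view: str, spec: PhantomSpec, rng: np.random.Generator,
                 cy: float, depth: float, lateral: float,
                 lesion_radius: float) -> tuple[np.ndarray, np.ndarray]:
    size = spec.image_size
    breast = _breast_mask_cc(size, cy) if view == "cc" else _breast_mask_mlo(size, cy)
    img = np.full((size, size), 0.02)
    img += 0.01 * rng.normal(size=(size, size))
    tissue = 0.45 + _texture(rng, size, spec.background_texture_scale)
    img[breast] = tissue[breast]
    if view == "mlo":
        wedge = _pectoral_wedge(size)
        img[wedge] = 0.62 + 0.3 * _texture(rng, size, spec.background_texture_scale)[wedge]
    mask = np.zeros((size, size), dtype=bool)
    if spec.label != "normal":
        center = _lesion_center(view, size, cy, depth, lateral)
        if spec.lesion_type == "mass":
            _paint_mass(img, mask, center, lesion_radius, spec.lesion_contrast,
                        spiculated=(spec.label == "malignant"),
                        n_spikes=spec.spiculation, rng=rng)
        else:
            _paint_calcifications(img, mask, center, spec.n_calcifications,
                                  spec.lesion_contrast,
                                  malignant=(spec.label == "malignant"), rng=rng)
    return np.clip(img, 0.0, 1.0), mask


def generate_case(spec: PhantomSpec) -> CasePair:
    """Render one two-view phantom case (deterministic from ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    cy = 0.5 * size + rng.uniform(-0.04, 0.04) * size
    depth = rng.uniform(0.30, 0.65)
    lateral = rng.uniform(-0.45, 0.45)
    lesion_radius = rng.uniform(*spec.mass_radius_frac) * size
    cc, cc_mask = _render_view("cc", spec, rng, cy, depth, lateral, lesion_radius)
    mlo, mlo_mask = _render_view("mlo", spec, rng, cy, depth, lateral, lesion_radius)
    return CasePair(
        cc=cc, mlo=mlo, label=spec.label, lesion_type=spec.lesion_type,
        cc_mask=cc_mask if spec.label != "normal" else np.zeros_like(cc_mask),
        mlo_mask=mlo_mask if spec.label != "normal" else np.zeros_like(mlo_mask),
        case_id=f"phantom-{spec.seed}",
    )


def generate_dataset(n_cases: int, class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                     seed: int = 0, image_size: int = 512,
                     **spec_overrides) -> list[CasePair]:
    """Generate a labeled phantom dataset with per-case seeds derived from
    the master seed. Class counts follow ``class_mix`` (normal, benign,
    malignant) by largest remainder; abnormal cases alternate mass and
    calcification lesion types."""
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    n_classes_requested = sum(1 for p in class_mix if p > 0)
    if n_cases < n_classes_requested:
        raise ValueError("n_cases is smaller than the number of requested classes")
    raw = [p * n_cases for p in class_mix]
    counts = [int(np.floor(x)) for x in raw]
    remainders = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n_cases - sum(counts)):
        counts[remainders[i]] += 1

    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0]) % (2 ** 31) for s in ss.spawn(n_cases)]
    labels: list[str] = []
    for label, count in zip(LABELS, counts):
        labels.extend([label] * count)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cases)

    cases = []
    lesion_toggle = 0
    for idx, pos in enumerate(order):
        label = labels[pos]
        lesion_type = None
        if label != "normal":
            lesion_type = LESION_TYPES[lesion_toggle % 2]
            lesion_toggle += 1
        spec = PhantomSpec(
            image_size=image_size, label=label, lesion_type=lesion_type,
            seed=case_seeds[idx], **spec_overrides,
        )
        case = generate_case(spec)
        case.case_id = f"case-{idx:04d}"
        cases.append(case)
    return cases
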