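"""Seeded synthetic capsule-endoscopy-like imagery.

Produces small RGB frames of textured pink mucosa inside a circular
field-of-view vignette, with one class-specific lesion per non-normal image:

* ``blood``            large saturated dark-red blob
* ``ulcer``            pale crater with a red rim
* ``erosion``          small pale patch
* ``angiectasia``      small bright-red tortuous mark
* ``lymphangiectasia`` small white dot

The morphology is invented plumbing for tests and demos — visually plausible
and linearly separable at small resolution, with no claim of clinical
fidelity.  Everything is deterministic under (spec, seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation, gaussian_filter

CLASS_NAMES = ("normal", "ulcer", "erosion", "blood", "angiectasia",
               "lymphangiectasia")


@dataclass(frozen=True)
class LesionSpec:
    """Recipe for one lesion class."""

    class_name: str
    area_fraction: tuple[float, float]  # of total image area; (0, 0] => none
    color_mean: tuple[float, float, float]
    color_spread: float
    shape: str  # ellipse | blob | tortuous

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}; "
                             f"expected one of {CLASS_NAMES}")
        lo, hi = self.area_fraction
        if self.class_name != "normal" and not (0.0 < lo <= hi <= 0.4):
            raise ValueError("area_fraction must lie within (0, 0.4]")
        if any(not 0.0 <= c <= 1.0 for c in self.color_mean):
            raise ValueError("color values must lie in [0, 1]")
        if self.shape not in ("ellipse", "blob", "tortuous"):
            raise ValueError(f"unknown shape {self.shape!r}")


DEFAULT_SPECS: dict[str, LesionSpec] = {
    "normal": LesionSpec("normal", (0.0, 0.0), (0.0, 0.0, 0.0), 0.0, "ellipse"),
    "ulcer": LesionSpec("ulcer", (0.05, 0.15), (0.93, 0.88, 0.70), 0.03, "blob"),
    "erosion": LesionSpec("erosion", (0.01, 0.05), (0.88, 0.80, 0.66), 0.03,
                          "ellipse"),
    "blood": LesionSpec("blood", (0.10, 0.25), (0.55, 0.03, 0.03), 0.04, "blob"),
    "angiectasia": LesionSpec("angiectasia", (0.005, 0.03), (0.75, 0.05, 0.08),
                              0.03, "tortuous"),
    "lymphangiectasia": LesionSpec("lymphangiectasia", (0.003, 0.02),
                                   (0.97, 0.96, 0.90), 0.02, "ellipse"),
}

_MUCOSA_RGB = np.array([0.80, 0.47, 0.44])


def _background(hw: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = hw
    base = _MUCOSA_RGB * (1.0 + 0.06 * rng.standard_normal(3))
    img = np.empty((h, w, 3))
    sigma = max(2.0, min(h, w) / 10.0)
    for c in range(3):
        field = gaussian_filter(rng.standard_normal((h, w)), sigma)
        std = field.std()
        if std > 0:
            field /= std
        img[..., c] = base[c] * (1.0 + 0.10 * field)
    # folds: a couple of higher-frequency ridges
    ridge = gaussian_filter(rng.standard_normal((h, w)), sigma / 3.0)
    std = ridge.std()
    if std > 0:
        ridge /= std
    img *= (1.0 + 0.05 * ridge)[..., None]
    return img


def _vignette(hw: tuple[int, int]) -> np.ndarray:
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot((yy - cy) / (h / 2.0), (xx - cx) / (w / 2.0))
    return np.clip(1.15 - 0.9 * np.clip(r - 0.75, 0.0, None) / 0.25, 0.05, 1.0)


def _ellipse_mask(hw, center, a, b, angle, rng=None, wobble=0.0) -> np.ndarray:
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ca, sa = math.cos(angle), math.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    d2 = (u / a) ** 2 + (v / b) ** 2
    if wobble > 0 and rng is not None:
        noise = gaussian_filter(rng.standard_normal((h, w)), max(a, b) / 3.0)
        std = noise.std()
        if std > 0:
            noise /= std
        d2 = d2 * (1.0 + wobble * noise)
    # threshold by pixel count so the rasterized area hits pi*a*b exactly
    target = max(1, int(round(math.pi * a * b)))
    if target >= d2.size:
        return np.ones_like(d2, dtype=bool)
    thresh = np.partition(d2.reshape(-1), target)[target]
    return d2 < thresh


def _shape_mask(spec: LesionSpec, hw: tuple[int, int],
                rng: np.random.Generator) -> np.ndarray:
    h, w = hw
    frac = rng.uniform(*spec.area_fraction)
    target_area = frac * h * w
    # keep lesions well inside the vignette
    margin = 0.25
    cy = rng.uniform(margin * h, (1 - margin) * h)
    cx = rng.uniform(margin * w, (1 - margin) * w)
    if spec.shape == "tortuous":
        # random walk, then dilate until the target area is reached
        steps = max(8, int(min(h, w) * 0.6))
        pos = np.array([cy, cx], dtype=float)
        heading = rng.uniform(0, 2 * math.pi)
        mask = np.zeros(hw, dtype=bool)
        for _ in range(steps):
            heading += rng.normal(0.0, 0.7)
            pos += np.array([math.sin(heading), math.cos(heading)])
            pos[0] = np.clip(pos[0], h * 0.15, h * 0.85)
            pos[1] = np.clip(pos[1], w * 0.15, w * 0.85)
            mask[int(pos[0]), int(pos[1])] = True
        while mask.sum() < target_area:
            mask = binary_dilation(mask)
        return mask
    ratio = rng.uniform(0.6, 1.6)
    a = math.sqrt(target_area * ratio / math.pi)
    b = a / ratio
    angle = rng.uniform(0, math.pi)
    wobble = 0.35 if spec.shape == "blob" else 0.0
    return _ellipse_mask(hw, (cy, cx), a, b, angle, rng, wobble)


def generate_image(spec: LesionSpec | str, hw: tuple[int, int] = (64, 64),
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Returns (image in [0,1]^{HxWx3}, boolean lesion mask HxW)."""
    if isinstance(spec, str):
        try:
            spec = DEFAULT_SPECS[spec]
        except KeyError:
            raise ValueError(f"unknown class {spec!r}; expected one of "
                             f"{CLASS_NAMES}") from None
    h, w = hw
    if h < 8 or w < 8:
        raise ValueError(f"hw must be at least 8x8, got {hw}")
    rng = np.random.default_rng(seed)
    img = _background(hw, rng)
    mask = np.zeros(hw, dtype=bool)
    if spec.class_name != "normal":
        mask = _shape_mask(spec, hw, rng)
        color = np.clip(np.asarray(spec.color_mean)
                        + spec.color_spread * rng.standard_normal(3), 0, 1)
        soft = gaussian_filter(mask.astype(float), 1.0)
        soft = soft / soft.max() if soft.max() > 0 else soft
        img = img * (1 - soft[..., None]) + color[None, None, :] * soft[..., None]
        if spec.class_name == "ulcer":  # red rim around the pale crater
            rim = binary_dilation(mask, iterations=2) & ~mask
            rim_soft = gaussian_filter(rim.astype(float), 0.8)
            m = rim_soft.max()
            if m > 0:
                rim_soft /= m
            rim_color = np.array([0.62, 0.08, 0.08])
            img = (img * (1 - rim_soft[..., None])
                   + rim_color[None, None, :] * rim_soft[..., None])
    img *= _vignette(hw)[..., None]
    return np.clip(img, 0.0, 1.0), mask


def generate_dataset(class_counts: dict[str, int],
                     out_dir, hw: tuple[int, int] = (64, 64),
                     seed: int = 0,
                     specs: dict[str, LesionSpec] | None = None) -> Path:
    """Writes ``out_dir/<class>/<id>.png`` plus ``manifest.csv``; returns the
    manifest path.  Regenerating with the same arguments is bit-identical."""
    specs = specs or DEFAULT_SPECS
    out_dir = Path(out_dir)
    rows = []
    for ci, (cls, count) in enumerate(sorted(class_counts.items())):
        if count < 1:
            raise ValueError(f"count for class {cls!r} must be >= 1")
        if cls not in specs:
            raise ValueError(f"unknown class {cls!r}")
        cls_dir = out_dir / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            img_seed = int(np.random.SeedSequence([seed, ci, i])
                           .generate_state(1)[0])
            img, _ = generate_image(specs[cls], hw, img_seed)
            name = f"{cls}_{i:05d}.png"
            arr = np.round(img * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(cls_dir / name)
            rows.append((f"{cls}/{name}", cls, img_seed))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["identifier", "class", "seed"])
        writer.writerows(rows)
    return manifest
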