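"""Class-imbalance data protocol: smallest-class-referenced splitting and
augmentation-based upsampling.

Split rule: the smallest class is divided 80/20 (by ``ratio``); the size of
its 20% share becomes the validation count drawn from *every* class, so the
validation set is balanced by construction.  The remaining items of each
class form its training pool, which ``balance_upsample`` grows to a common
target count by attaching random augmentation recipes to resampled originals.

Augmentation operators (positional: rotate, flip, shear, warp; colour:
erase, additive_noise, blur) preserve image shape and the [0, 1] value range
and are deterministic under (params, seed).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import AffineTransform, rotate as _sk_rotate, warp as _sk_warp

from .config import AugmentationConfig

AUGMENTATION_OPS = ("rotate", "flip", "shear", "warp", "erase",
                    "additive_noise", "blur")


@dataclass(frozen=True)
class ClassIndex:
    """Ordered image identifiers belonging to one class."""

    class_name: str
    items: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"duplicate identifiers in class {self.class_name!r}")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class DatasetSplit:
    train: dict[str, tuple[str, ...]]
    val: dict[str, tuple[str, ...]]
    seed: int

    def __post_init__(self):
        sizes = {len(v) for v in self.val.values()}
        if len(sizes) > 1:
            raise ValueError(f"validation sets must have equal sizes, got {sizes}")
        for cls in self.train:
            overlap = set(self.train[cls]) & set(self.val.get(cls, ()))
            if overlap:
                raise ValueError(f"train/val overlap in class {cls!r}: "
                                 f"{sorted(overlap)[:3]}")


def split_by_smallest_class(classes: list[ClassIndex], ratio: float = 0.8,
                            seed: int = 0) -> DatasetSplit:
    """The smallest class's (1 - ratio) share sets the per-class validation
    count; that many items are drawn uniformly without replacement from every
    class and the rest of each class becomes its training pool."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    if not classes:
        raise ValueError("need at least one class")
    for c in classes:
        if len(c) == 0:
            raise ValueError(f"class {c.class_name!r} is empty")
    m = min(len(c) for c in classes)
    v = int(round((1.0 - ratio) * m))
    rng = np.random.default_rng(seed)
    train: dict[str, tuple[str, ...]] = {}
    val: dict[str, tuple[str, ...]] = {}
    for c in sorted(classes, key=lambda c: c.class_name):
        assert len(c) >= v, "smallest class defines v; cannot exceed any class"
        perm = rng.permutation(len(c))
        val_idx = set(perm[:v].tolist())
        val[c.class_name] = tuple(c.items[i] for i in sorted(val_idx))
        train[c.class_name] = tuple(it for i, it in enumerate(c.items)
                                    if i not in val_idx)
    return DatasetSplit(train=train, val=val, seed=seed)


# ---------------------------------------------------------------------------
# augmentation operators
# ---------------------------------------------------------------------------

def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] not in (1, 3):
        raise ValueError(f"expected an HxWxC image, got shape {image.shape}")
    return img


def _rotate(img, params, rng):
    angle = float(params.get("angle", 0.0))
    if angle == 0.0:
        return img
    return _sk_rotate(img, angle, mode="reflect", order=1, preserve_range=True)


def _flip(img, params, rng):
    axis = params.get("axis", "horizontal")
    if axis == "horizontal":
        return img[:, ::-1]
    if axis == "vertical":
        return img[::-1]
    raise ValueError(f"unknown flip axis {axis!r}")


def _shear(img, params, rng):
    degrees = float(params.get("degrees", 0.0))
    if degrees == 0.0:
        return img
    h, w = img.shape[:2]
    shear = np.deg2rad(degrees)
    center = AffineTransform(translation=(-w / 2.0, -h / 2.0))
    tf = center + AffineTransform(shear=shear) + AffineTransform(
        translation=(w / 2.0, h / 2.0))
    return _sk_warp(img, tf.inverse, mode="reflect", order=1,
                    preserve_range=True)


def _warp(img, params, rng):
    strength = float(params.get("strength", 2.0))
    if strength == 0.0:
        return img
    h, w = img.shape[:2]
    sigma = max(4.0, min(h, w) / 8.0)
    dy = gaussian_filter(rng.standard_normal((h, w)), sigma)
    dx = gaussian_filter(rng.standard_normal((h, w)), sigma)
    for d in (dy, dx):
        m = np.abs(d).max()
        if m > 0:
            d *= strength / m
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.array([yy + dy, xx + dx])
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = map_coordinates(img[..., c], coords, order=1,
                                      mode="reflect")
    return out


def _erase(img, params, rng):
    fraction = float(params.get("fraction", 0.05))
    if fraction <= 0.0:
        return img
    h, w = img.shape[:2]
    area = fraction * h * w
    aspect = rng.uniform(0.5, 2.0)
    eh = min(h, max(1, int(round(np.sqrt(area * aspect)))))
    ew = min(w, max(1, int(round(area / eh))))
    y0 = rng.integers(0, h - eh + 1)
    x0 = rng.integers(0, w - ew + 1)
    out = img.copy()
    out[y0:y0 + eh, x0:x0 + ew] = rng.uniform(
        0.0, 1.0, size=(eh, ew, img.shape[2]))
    return out


def _additive_noise(img, params, rng):
    sigma = float(params.get("sigma", 0.02))
    if sigma <= 0.0:
        return img
    return img + rng.normal(0.0, sigma, size=img.shape)


def _blur(img, params, rng):
    sigma = float(params.get("sigma", 1.0))
    if sigma <= 0.0:
        return img
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = gaussian_filter(img[..., c], sigma)
    return out


_OPS = {
    "rotate": _rotate,
    "flip": _flip,
    "shear": _shear,
    "warp": _warp,
    "erase": _erase,
    "additive_noise": _additive_noise,
    "blur": _blur,
}


def augment_once(image: np.ndarray, op_name: str, params: dict | None = None,
                 seed: int = 0) -> np.ndarray:
    """Applies one augmentation operator; output has the input's shape and
    stays within [0, 1]."""
    if op_name not in _OPS:
        raise ValueError(f"unknown augmentation op {op_name!r}; expected one "
                         f"of {AUGMENTATION_OPS}")
    img = _check_image(image)
    rng = np.random.default_rng(seed)
    out = _OPS[op_name](img, params or {}, rng)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# recipes and balancing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationRecipe:
    """A deterministic chain of augmentation steps."""

    steps: tuple[tuple[str, dict, int], ...] = field(default_factory=tuple)

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = image
        for op_name, params, seed in self.steps:
            out = augment_once(out, op_name, params, seed)
        return out

    def to_json(self) -> str:
        return json.dumps([[op, params, seed] for op, params, seed in self.steps])

    @classmethod
    def from_json(cls, text: str) -> "AugmentationRecipe":
        return cls(tuple((op, params, int(seed))
                         for op, params, seed in json.loads(text)))


def random_recipe(aug_config: AugmentationConfig,
                  rng: np.random.Generator) -> AugmentationRecipe:
    """Draws 1-2 random augmentation steps from the configured ranges."""
    ops = list(AUGMENTATION_OPS)
    if not aug_config.flip_axes:
        ops.remove("flip")
    n_steps = int(rng.integers(1, 3))
    chosen = rng.choice(ops, size=n_steps, replace=False)
    steps = []
    for op in chosen:
        if op == "rotate":
            params = {"angle": float(rng.uniform(*aug_config.rotation_degrees))}
        elif op == "flip":
            params = {"axis": str(rng.choice(aug_config.flip_axes))}
        elif op == "shear":
            params = {"degrees": float(rng.uniform(*aug_config.shear_degrees))}
        elif op == "warp":
            params = {"strength": float(rng.uniform(*aug_config.warp_strength))}
        elif op == "erase":
            params = {"fraction": float(rng.uniform(*aug_config.erase_fraction))}
        elif op == "additive_noise":
            params = {"sigma": float(rng.uniform(*aug_config.noise_sigma))}
        else:  # blur
            params = {"sigma": float(rng.uniform(*aug_config.blur_sigma))}
        steps.append((str(op), params, int(rng.integers(0, 2**31 - 1))))
    return AugmentationRecipe(tuple(steps))


def balance_upsample(pool: list[str], target_count: int,
                     aug_config: AugmentationConfig
                     ) -> list[tuple[str, AugmentationRecipe | None]]:
    """Grows ``pool`` to exactly ``target_count`` (identifier, recipe) pairs.
    Every original appears once with no recipe; the extras resample the pool
    uniformly and carry random recipes.  Deterministic under
    ``aug_config.seed``."""
    if not pool:
        raise ValueError("pool must be non-empty")
    if target_count < len(pool):
        raise ValueError(f"target_count {target_count} is below the pool size "
                         f"{len(pool)}")
    rng = np.random.default_rng(aug_config.seed)
    out: list[tuple[str, AugmentationRecipe | None]] = [
        (item, None) for item in pool]
    for _ in range(target_count - len(pool)):
        item = pool[int(rng.integers(0, len(pool)))]
        out.append((item, random_recipe(aug_config, rng)))
    return out


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def write_split_manifest(path, split: DatasetSplit,
                         balanced: dict[str, list[tuple[str, AugmentationRecipe | None]]]
                         | None = None) -> None:
    """CSV rows: identifier, class, partition, recipe (JSON or empty)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["identifier", "class", "partition", "recipe"])
        if balanced is not None:
            for cls in sorted(balanced):
                for ident, recipe in balanced[cls]:
                    writer.writerow([ident, cls, "train",
                                     recipe.to_json() if recipe else ""])
        else:
            for cls in sorted(split.train):
                for ident in split.train[cls]:
                    writer.writerow([ident, cls, "train", ""])
        for cls in sorted(split.val):
            for ident in split.val[cls]:
                writer.writerow([ident, cls, "val", ""])


def read_split_manifest(path) -> list[tuple[str, str, str, AugmentationRecipe | None]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            recipe = (AugmentationRecipe.from_json(row["recipe"])
                      if row["recipe"] else None)
            rows.append((row["identifier"], row["class"], row["partition"],
                         recipe))
    return rows


def scan_class_directories(root) -> list[ClassIndex]:
    """Reads the ``root/<class>/<image>`` layout into ClassIndex records."""
    root = Path(root)
    classes = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        items = sorted(f"{cls_dir.name}/{p.name}" for p in cls_dir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not items:
            raise ValueError(f"class directory {cls_dir} contains no images")
        classes.append(ClassIndex(cls_dir.name, tuple(items)))
    if not classes:
        raise ValueError(f"no class directories found under {root}")
    return classes
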