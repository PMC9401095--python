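"""Training and evaluation loops tying the data protocol, synthetic imagery,
network, and metrics together.

A run directory contains ``model.npz`` (best weights), ``config.yaml`` (the
full RunConfig, so checkpoints are self-describing), ``classes.json``,
``split_manifest.csv`` and ``history.csv``.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .config import RunConfig, load_config, save_config
from .data_protocol import (
    AugmentationRecipe,
    ClassIndex,
    balance_upsample,
    read_split_manifest,
    scan_class_directories,
    split_by_smallest_class,
    write_split_manifest,
)
from .evaluation import MetricsReport, multiclass_report
from .network import RatCapsNet, assemble_ratcapsnet
from .nn.losses import binary_cross_entropy_with_logits, softmax_cross_entropy
from .nn.optim import Adam

log = logging.getLogger("ratcapsnet")


class DataError(RuntimeError):
    pass


def load_image(path, hw: tuple[int, int]) -> np.ndarray:
    """Reads a PNG/JPEG as float HWC in [0, 1], bilinearly resized to hw."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if im.size != (hw[1], hw[0]):
            im = im.resize((hw[1], hw[0]), Image.BILINEAR)
        return np.asarray(im, dtype=np.float32) / 255.0


def _to_nchw_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([img.transpose(2, 0, 1) for img in images]).astype(np.float32)


@dataclass
class TrainResult:
    history: list[dict]
    checkpoint_dir: Path
    best_val_loss: float
    classes: list[str]


def _loss_fn(run: RunConfig):
    mode = run.loss
    if mode == "auto":
        mode = ("bce" if run.network.head_mode == "sigmoid_binary"
                else "cross_entropy")
    if mode == "bce":
        return binary_cross_entropy_with_logits
    return softmax_cross_entropy


def _predict_labels(model: RatCapsNet, logits: np.ndarray) -> np.ndarray:
    if model.config.head_mode == "sigmoid_binary":
        return (logits.reshape(-1) >= 0.0).astype(int)  # sigmoid(z) >= 0.5
    return logits.argmax(axis=1)


class _TrainSet:
    """Materialized identifiers + on-the-fly augmented image loading."""

    def __init__(self, root: Path, hw, entries: list[tuple[str, str,
                                                           AugmentationRecipe | None]],
                 class_to_idx: dict[str, int], cache_originals: bool = True):
        self.root = root
        self.hw = hw
        self.entries = entries
        self.class_to_idx = class_to_idx
        self._cache: dict[str, np.ndarray] = {} if cache_originals else None

    def __len__(self):
        return len(self.entries)

    def _original(self, ident: str) -> np.ndarray:
        if self._cache is not None and ident in self._cache:
            return self._cache[ident]
        img = load_image(self.root / ident, self.hw)
        if self._cache is not None:
            self._cache[ident] = img
        return img

    def get(self, i: int) -> tuple[np.ndarray, int]:
        ident, cls, recipe = self.entries[i]
        img = self._original(ident)
        if recipe is not None:
            img = recipe.apply(img.astype(np.float64)).astype(np.float32)
        return img, self.class_to_idx[cls]


def train(run: RunConfig) -> TrainResult:
    """split -> balance -> augment-on-the-fly -> optimize; saves the best
    checkpoint (validation loss) plus config and split manifest."""
    t0 = time.time()
    root = Path(run.data_root)
    classes = scan_class_directories(root)
    class_names = [c.class_name for c in classes]
    if run.network.num_classes != len(class_names):
        raise DataError(f"config expects {run.network.num_classes} classes "
                        f"but {root} holds {len(class_names)}: {class_names}")
    class_to_idx = {c: i for i, c in enumerate(class_names)}

    split = split_by_smallest_class(classes, run.split_ratio, run.seed)
    aug = run.augmentation
    if aug.seed != run.seed:
        aug = type(aug).from_dict({**aug.to_dict(), "seed": run.seed})
    # never shrink a pool: the effective target is the largest training pool
    # when that exceeds the configured one, keeping classes uniform either way
    target = max(run.balance_target,
                 max(len(v) for v in split.train.values()))
    balanced = {cls: balance_upsample(list(split.train[cls]), target, aug)
                for cls in sorted(split.train)}

    out_dir = Path(run.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(run, out_dir / "config.yaml")
    (out_dir / "classes.json").write_text(json.dumps(class_names))
    write_split_manifest(out_dir / "split_manifest.csv", split, balanced)

    hw = run.network.input_hw
    train_entries = [(ident, cls, recipe)
                     for cls in sorted(balanced)
                     for ident, recipe in balanced[cls]]
    train_set = _TrainSet(root, hw, train_entries, class_to_idx)
    val_images = [load_image(root / ident, hw)
                  for cls in sorted(split.val) for ident in split.val[cls]]
    val_labels = np.array([class_to_idx[cls]
                           for cls in sorted(split.val)
                           for _ in split.val[cls]])

    model = assemble_ratcapsnet(run.network)
    opt = Adam(model.modules(), lr=run.learning_rate)
    loss_fn = _loss_fn(run)
    rng = np.random.default_rng(run.seed)

    history: list[dict] = []
    best_val = np.inf
    best_state = None
    patience_left = run.patience
    for epoch in range(1, run.max_epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        correct = 0
        for start in range(0, len(order), run.batch_size):
            idx = order[start: start + run.batch_size]
            imgs, labels = zip(*(train_set.get(i) for i in idx))
            x = _to_nchw_batch(list(imgs))
            y = np.array(labels)
            opt.zero_grad()
            logits = model.forward(x)
            loss, dlogits = loss_fn(logits, y)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((_predict_labels(model, logits) == y).sum())
        train_loss = float(np.mean(losses))
        train_acc = correct / len(train_set)
        val_loss, val_acc = _evaluate_arrays(model, val_images, val_labels,
                                            loss_fn, run.batch_size)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "train_acc": train_acc, "val_loss": val_loss,
                        "val_acc": val_acc})
        log.info("epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                 epoch, train_loss, train_acc, val_loss, val_acc)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            patience_left = run.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                log.info("early stopping after epoch %d", epoch)
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    np.savez(out_dir / "model.npz", **model.state_dict())
    with open(out_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
    log.info("training finished in %.1fs; best val loss %.4f",
             time.time() - t0, best_val)
    return TrainResult(history=history, checkpoint_dir=out_dir,
                       best_val_loss=float(best_val), classes=class_names)


def _evaluate_arrays(model, images, labels, loss_fn, batch_size):
    losses = []
    preds = []
    for start in range(0, len(images), batch_size):
        x = _to_nchw_batch(images[start: start + batch_size])
        y = labels[start: start + batch_size]
        logits = model.forward(x)
        losses.append(loss_fn(logits, y)[0] * len(y))
        preds.append(_predict_labels(model, logits))
    preds = np.concatenate(preds)
    return (float(np.sum(losses) / len(labels)),
            float((preds == labels).mean()))


def load_checkpoint(checkpoint_dir) -> tuple[RatCapsNet, RunConfig, list[str]]:
    checkpoint_dir = Path(checkpoint_dir)
    run = load_config(checkpoint_dir / "config.yaml")
    classes = json.loads((checkpoint_dir / "classes.json").read_text())
    model = assemble_ratcapsnet(run.network)
    with np.load(checkpoint_dir / "model.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, run, classes


def evaluate(checkpoint_dir, data_root=None, partition: str = "val"
             ) -> MetricsReport:
    """Runs inference over a stored split partition and reports one-vs-rest
    metrics with macro averages."""
    if partition not in ("train", "val"):
        raise ValueError(f"partition must be 'train' or 'val', got {partition!r}")
    checkpoint_dir = Path(checkpoint_dir)
    model, run, classes = load_checkpoint(checkpoint_dir)
    root = Path(data_root) if data_root else Path(run.data_root)
    found = sorted(p.name for p in root.iterdir() if p.is_dir())
    if found != sorted(classes):
        raise DataError(f"checkpoint classes {sorted(classes)} do not match "
                        f"data root classes {found}")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    rows = read_split_manifest(checkpoint_dir / "split_manifest.csv")
    # evaluate each identifier once, un-augmented
    wanted = sorted({(ident, cls) for ident, cls, part, _ in rows
                     if part == partition})
    if not wanted:
        raise DataError(f"no rows for partition {partition!r} in the manifest")
    hw = run.network.input_hw
    images = [load_image(root / ident, hw) for ident, _ in wanted]
    labels = np.array([class_to_idx[cls] for _, cls in wanted])
    preds = []
    for start in range(0, len(images), run.batch_size):
        logits = model.forward(_to_nchw_batch(images[start: start + run.batch_size]))
        preds.append(_predict_labels(model, logits))
    preds = np.concatenate(preds)
    return multiclass_report([classes[i] for i in labels],
                             [classes[i] for i in preds], labels=classes)


def predict(checkpoint_dir, image_path) -> dict[str, float]:
    """Class-probability map for a single image."""
    model, run, classes = load_checkpoint(checkpoint_dir)
    img = load_image(image_path, run.network.input_hw)
    probs = model.predict_proba(_to_nchw_batch([img]))[0]
    if model.config.head_mode == "sigmoid_binary":
        p1 = float(probs[0])
        return {classes[0]: 1.0 - p1, classes[1]: p1}
    return {cls: float(p) for cls, p in zip(classes, probs)}
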