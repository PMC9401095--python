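"""Attention-mask and pyramid-map visualization.

For a checkpoint and an input image this writes, per encoder stage, the raw
sigmoid mask, the masked input (mask bilinearly resized to the input
resolution and multiplied in), and min-max contrast-stretched versions of
both, plus three channels of the stage-3 pyramid map.  Constant (zero dynamic
range) maps render mid-gray.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .network import RatCapsNet, extract_attention_maps
from .train import load_checkpoint, load_image

__all__ = ["contrast_stretch", "visualize_attention", "save_gray_png"]


def contrast_stretch(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant map becomes mid-gray (0.5)."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)


def save_gray_png(path, arr: np.ndarray) -> None:
    Image.fromarray(_to_uint8(arr), mode="L").save(path)


def _resize_to(arr: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(im.resize((hw[1], hw[0]), Image.BILINEAR), dtype=np.float64)


def visualize_attention(model_or_checkpoint, image_path, out_dir,
                        pfe_stage: int = 3, n_pfe_channels: int = 3
                        ) -> list[Path]:
    """Writes the visualization set and returns the created file paths."""
    if isinstance(model_or_checkpoint, RatCapsNet):
        model = model_or_checkpoint
    else:
        model, _, _ = load_checkpoint(model_or_checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = load_image(image_path, model.config.input_hw)
    masks, pfe_maps = extract_attention_maps(model, img)

    written: list[Path] = []

    def _write(name: str, arr: np.ndarray) -> None:
        path = out_dir / name
        save_gray_png(path, arr)
        written.append(path)

    gray = img.mean(axis=2)
    for stage, mask in masks:
        m = mask.values[..., 0]
        _write(f"mask_stage{stage}.png", m)
        _write(f"mask_stage{stage}_stretched.png", contrast_stretch(m))
        m_full = np.clip(_resize_to(m, model.config.input_hw), 0.0, 1.0)
        masked = gray * m_full
        _write(f"masked_input_stage{stage}.png", masked)
        _write(f"masked_input_stage{stage}_stretched.png",
               contrast_stretch(masked))

    available = {stage: fm for stage, fm in pfe_maps}
    if available:
        stage = pfe_stage if pfe_stage in available else min(available)
        fm = available[stage].values
        for c in range(min(n_pfe_channels, fm.shape[2])):
            _write(f"pfe_stage{stage}_channel{c}.png",
                   contrast_stretch(fm[..., c]))
    return written
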