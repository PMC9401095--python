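"""Validated array containers shared across the package.

All spatial containers use HWC axis order (height, width, channels); the
network internals convert to NCHW batches at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64) if not isinstance(values, np.ndarray) \
        else values
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    return arr


@dataclass(frozen=True)
class FeatureMap:
    """Rank-3 activation array, axes (height, width, channels)."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if arr.ndim != 3:
            raise ValueError(f"FeatureMap must be rank-3 HWC, got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"FeatureMap axes must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("FeatureMap entries must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AttentionMask:
    """Rank-3 H x W x 1 array with entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if arr.ndim != 3 or arr.shape[2] != 1:
            raise ValueError(f"AttentionMask must be HxWx1, got shape {arr.shape}")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("AttentionMask entries must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FeatureVector:
    """Rank-1 array of pooled features (singleton spatial axes squeezed)."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values).reshape(-1)
        if not np.all(np.isfinite(arr)):
            raise ValueError("FeatureVector entries must be finite")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax vector over classes, or a single sigmoid probability."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_array(self.values).reshape(-1)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if arr.size > 1 and abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"softmax probabilities must sum to 1, got {arr.sum()}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size
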