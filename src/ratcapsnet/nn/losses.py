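"""Classification losses; each returns (loss, dlogits)."""

from __future__ import annotations

import numpy as np

from .layers import softmax

_EPS = 1e-12


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch; labels are integer class ids."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.mean(np.log(probs[np.arange(n), labels] + _EPS))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def binary_cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray):
    """logits shape (N, 1); labels in {0, 1}."""
    z = logits.reshape(-1)
    y = labels.astype(z.dtype)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = -np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS))
    dlogits = ((p - y) / z.size).reshape(logits.shape)
    return float(loss), dlogits
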