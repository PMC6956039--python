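"""Softmax and cross-entropy loss."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``targets`` are integer class ids of shape (N,).
    """
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), targets] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n
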