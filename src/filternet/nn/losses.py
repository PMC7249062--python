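"""Softmax cross-entropy over dense per-sample class predictions."""

from __future__ import annotations

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = ["softmax_probs", "cross_entropy"]


def softmax_probs(logits: np.ndarray, axis: int = -2) -> np.ndarray:
    """Class probabilities from logits; class axis defaults to the channel axis."""
    return softmax(logits, axis=axis)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over every output sample.

    Parameters
    ----------
    logits : (N, K, L) array
    labels : (N, L) integer array

    Returns
    -------
    loss : float
    dlogits : (N, K, L) gradient of the mean loss w.r.t. the logits
    """
    n, k, length = logits.shape
    logp = log_softmax(logits, axis=1)
    idx_n = np.arange(n)[:, None]
    idx_l = np.arange(length)[None, :]
    loss = -logp[idx_n, labels, idx_l].mean()
    dlogits = softmax(logits, axis=1)
    np.subtract.at(dlogits, (idx_n, labels, idx_l), 1.0)
    dlogits /= n * length
    return float(loss), dlogits
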