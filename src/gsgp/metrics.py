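"""Fitness metrics."""

from __future__ import annotations

import numpy as np

__all__ = ["rmse"]


def rmse(predicted, target) -> float:
    """Root mean square error between predictions and targets."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - t) ** 2)))
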