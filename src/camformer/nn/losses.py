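"""Regression losses returning (value, gradient w.r.t. predictions)."""

from __future__ import annotations

import numpy as np

LOSSES = ("L1", "MSE", "Huber")


def loss_and_grad(name: str, pred: np.ndarray, target: np.ndarray,
                  huber_delta: float = 1.0) -> tuple[float, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    n = pred.size
    d = pred - target
    if name == "L1":
        return float(np.abs(d).mean()), np.sign(d) / n
    if name == "MSE":
        return float((d ** 2).mean()), 2.0 * d / n
    if name == "Huber":
        a = np.abs(d)
        quad = a <= huber_delta
        val = np.where(quad, 0.5 * d ** 2, huber_delta * (a - 0.5 * huber_delta))
        grad = np.where(quad, d, huber_delta * np.sign(d))
        return float(val.mean()), grad / n
    raise ValueError(f"unknown loss {name!r}; choose from {LOSSES}")
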