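"""Optimizers (AdamW, Lion) and learning-rate schedules.

Weight decay is decoupled (applied directly to the parameter, not through the
gradient) and, following common practice, only applied to weight matrices
(ndim > 1), never to biases or normalisation scales.
"""

from __future__ import annotations

import numpy as np

OPTIMIZERS = ("AdamW", "Lion")
SCHEDULERS = ("none", "step", "cosine")


class Optimizer:
    def __init__(self, param_refs: list[tuple[object, str]], lr: float,
                 weight_decay: float) -> None:
        # param_refs: (layer, param name) pairs; arrays updated in place
        self.param_refs = param_refs
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0

    def step(self) -> None:
        raise NotImplementedError


class AdamW(Optimizer):
    def __init__(self, param_refs, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        super().__init__(param_refs, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(layer.params[name], dtype=np.float64)
                  for layer, name in param_refs]
        self.v = [np.zeros_like(layer.params[name], dtype=np.float64)
                  for layer, name in param_refs]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.param_refs):
            p = layer.params[name]
            g = layer.grads[name].astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            upd = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay and p.ndim > 1:
                upd = upd + self.weight_decay * p
            layer.params[name] = (p - self.lr * upd).astype(p.dtype)


class Lion(Optimizer):
    """Sign-momentum optimizer (evoLved sign momentum)."""

    def __init__(self, param_refs, lr=1e-4, betas=(0.9, 0.99),
                 weight_decay=0.01):
        super().__init__(param_refs, lr, weight_decay)
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(layer.params[name], dtype=np.float64)
                  for layer, name in param_refs]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.param_refs):
            p = layer.params[name]
            g = layer.grads[name].astype(np.float64)
            upd = np.sign(self.b1 * self.m[i] + (1 - self.b1) * g)
            if self.weight_decay and p.ndim > 1:
                upd = upd + self.weight_decay * p
            layer.params[name] = (p - self.lr * upd).astype(p.dtype)
            self.m[i] = self.b2 * self.m[i] + (1 - self.b2) * g


def make_optimizer(name: str, param_refs, lr: float,
                   weight_decay: float) -> Optimizer:
    if name == "AdamW":
        return AdamW(param_refs, lr=lr, weight_decay=weight_decay)
    if name == "Lion":
        return Lion(param_refs, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; choose from {OPTIMIZERS}")


def lr_at_epoch(base_lr: float, epoch: int, scheduler: str, max_epochs: int,
                step_size: int = 10, gamma: float = 0.5) -> float:
    """Learning rate for a 0-based epoch index under the named schedule."""
    if scheduler == "none":
        return base_lr
    if scheduler == "step":
        return base_lr * gamma ** (epoch // step_size)
    if scheduler == "cosine":
        if max_epochs <= 1:
            return base_lr
        return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / (max_epochs - 1)))
    raise ValueError(f"unknown scheduler {scheduler!r}; choose from {SCHEDULERS}")
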