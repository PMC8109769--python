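"""Adam optimizer with L2 weight decay.

Weight decay is added to the raw gradient before the moment updates (the
classic coupled form used by the Keras-era optimizers).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer


def clip_grad_norm(layers: list[Layer], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.  A guard against the episodic gradient
    spikes of adversarial training on unnormalized networks.
    """
    total = 0.0
    for layer in layers:
        for g in layer.grads.values():
            total += float((g * g).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for layer in layers:
            for name in layer.grads:
                layer.grads[name] = layer.grads[name] * scale
    return norm


class Adam:
    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.8,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.slots = [(layer, name) for layer in layers if layer.params for name in layer.params]
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (layer, name) in enumerate(self.slots):
            p = layer.params[name]
            g = layer.grads[name]
            if self.weight_decay and name != "b":
                g = g + self.weight_decay * p
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * (g * g)
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
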