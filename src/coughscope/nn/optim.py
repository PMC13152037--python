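"""Adam optimizer, step learning-rate decay, and the classification loss."""

from __future__ import annotations

import numpy as np

from .layers import Param
from .resnet import softmax_scores


class Adam:
    """Adam with the library-standard constants beta=(0.9, 0.999), eps=1e-8."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)


def step_lr(base_lr: float, epoch: int, step_size: int = 7, gamma: float = 0.1) -> float:
    """Step decay: lr(e) = base_lr * gamma ** floor(e / step_size)."""
    return base_lr * gamma ** (epoch // step_size)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices. The gradient is
    (softmax(logits) - onehot) / N, the exact derivative of the mean loss.
    """
    n = logits.shape[0]
    probs = softmax_scores(logits)
    picked = probs[np.arange(n), labels]
    loss = float(-np.mean(np.log(np.maximum(picked, 1e-12))))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)
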