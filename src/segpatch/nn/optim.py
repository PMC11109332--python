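"""Adam optimizer and softmax cross-entropy, for the numpy CNN."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "softmax", "cross_entropy"]


class Adam:
    """Adam with bias correction; `lr` may be reassigned between steps
    (step decay)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray,
    target_idx: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy and its logit gradient."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    nll = lse - z[np.arange(n), target_idx]
    p = softmax(logits)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), target_idx] = 1.0
    if class_weights is None:
        loss = float(nll.mean())
        dlogits = (p - onehot) / n
    else:
        w = class_weights[target_idx]
        wsum = w.sum()
        loss = float((w * nll).sum() / wsum)
        dlogits = (p - onehot) * (w / wsum)[:, None]
    return loss, dlogits.astype(logits.dtype)
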