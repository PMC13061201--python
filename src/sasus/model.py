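"""Reference click-promptable segmentation model.

A deliberately small model used to exercise the augmentation, prompting and
evaluation machinery on a single CPU: each pixel is classified by a
one-hidden-layer network over a stack of per-pixel feature maps computed
from the image and the click prompts issued so far —

* raw and smoothed intensity, gradient magnitude, local texture energy;
* absolute intensity contrast against the tissue sampled at the positive
  clicks (scale-free evidence);
* normalized Euclidean distance to the nearest positive and nearest
  negative click (scale-dependent evidence).

Because the click-distance channels are in absolute pixels (normalized by
the input size), a model fitted only on large structures learns a large
effective radius around the click and over-segments small targets — the
failure mode that thumbnail-scale augmentation is designed to correct.

Training uses hand-written gradients and a hand-rolled AdamW, so the
harness has no deep-learning framework dependency.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .prompts import Click

__all__ = ["ClickNet"]

N_FEATURES = 7


def _click_features(image: np.ndarray, clicks: Sequence[Click]) -> np.ndarray:
    """Per-pixel feature stack, shape (H*W, N_FEATURES)."""
    h, w = image.shape
    scale = float(max(h, w))
    i_s = ndimage.gaussian_filter(image, sigma=2.0)
    grad = ndimage.gaussian_gradient_magnitude(image, sigma=2.0)
    local_sd = np.sqrt(np.maximum(
        ndimage.uniform_filter(image ** 2, size=7)
        - ndimage.uniform_filter(image, size=7) ** 2, 0.0))

    pos = [(c.y, c.x) for c in clicks if c.label == "positive"]
    neg = [(c.y, c.x) for c in clicks if c.label == "negative"]
    rows, cols = np.mgrid[0:h, 0:w]

    def min_dist(points: list[tuple[int, int]]) -> np.ndarray:
        if not points:
            return np.full((h, w), 1.5)
        d = np.full((h, w), np.inf)
        for r, c in points:
            d = np.minimum(d, np.hypot(rows - r, cols - c))
        return d / scale

    if pos:
        ref = float(np.mean([i_s[r, c] for r, c in pos]))
    else:
        ref = float(i_s.mean())
    sim = np.abs(i_s - ref)

    feats = np.stack([
        image, i_s, sim, min_dist(pos), min_dist(neg), grad, local_sd,
    ], axis=-1)
    return feats.reshape(-1, N_FEATURES)


class ClickNet:
    """One-hidden-layer per-pixel classifier with AdamW training steps."""

    def __init__(self, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(N_FEATURES)
        self.W1 = rng.normal(0.0, s, size=(N_FEATURES, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.b2 = 0.0
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._t = 0

    # -- parameter plumbing ------------------------------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.copy(), "b1": self.b1.copy(),
                "w2": self.w2.copy(), "b2": np.array(self.b2)}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.W1 = params["W1"].copy()
        self.b1 = params["b1"].copy()
        self.w2 = params["w2"].copy()
        self.b2 = float(params["b2"])

    # -- inference ---------------------------------------------------------
    def forward(self, image: np.ndarray, clicks: Sequence[Click]
                ) -> tuple[np.ndarray, dict]:
        """Foreground probabilities (same shape as image) + backprop cache."""
        F = _click_features(image, clicks)
        Z1 = F @ self.W1 + self.b1
        A = np.tanh(Z1)
        z2 = A @ self.w2 + self.b2
        p = 1.0 / (1.0 + np.exp(-z2))
        cache = {"F": F, "A": A, "p": p, "shape": image.shape}
        return p.reshape(image.shape), cache

    def predict(self, image: np.ndarray, clicks: Sequence[Click]) -> np.ndarray:
        probs, _ = self.forward(image, clicks)
        return (probs > 0.5).astype(np.uint8)

    # -- training ----------------------------------------------------------
    def gradients(self, cache: dict, grad_p: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop from dLoss/dp (flat, per-pixel) to parameter gradients."""
        F, A, p = cache["F"], cache["A"], cache["p"]
        g2 = grad_p * p * (1.0 - p)          # dL/dz2
        dw2 = A.T @ g2
        db2 = g2.sum()
        dA = np.outer(g2, self.w2)
        dZ1 = dA * (1.0 - A ** 2)
        dW1 = F.T @ dZ1
        db1 = dZ1.sum(axis=0)
        return {"W1": dW1, "b1": db1, "w2": dw2, "b2": np.array(db2)}

    def adamw_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999,
                   weight_decay: float = 0.01, eps: float = 1e-8) -> None:
        """One AdamW update (decoupled weight decay)."""
        params = {"W1": self.W1, "b1": self.b1, "w2": self.w2,
                  "b2": np.array(self.b2)}
        if self._adam is None:
            self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                          for k, v in params.items()}
        self._t += 1
        t = self._t
        for k, v in params.items():
            g = grads[k]
            m, s = self._adam[k]
            m = beta1 * m + (1 - beta1) * g
            s = beta2 * s + (1 - beta2) * g ** 2
            self._adam[k] = (m, s)
            mhat = m / (1 - beta1 ** t)
            shat = s / (1 - beta2 ** t)
            v = v - lr * mhat / (np.sqrt(shat) + eps) - lr * weight_decay * v
            params[k] = v
        self.W1, self.b1, self.w2 = params["W1"], params["b1"], params["w2"]
        self.b2 = float(params["b2"])
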