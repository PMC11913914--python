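"""A small fully-convolutional segmentation backbone in pure numpy.

The ensembling method this package implements (independently seeded members,
sigmoid-average fusion, foreground-entropy confidence) is agnostic to the
member architecture, so the default backbone is deliberately tiny: three
convolutional layers (3x3 -> ReLU -> 3x3 -> ReLU -> 1x1) mapping one
standardized intensity channel to a per-pixel tumor logit. Forward and
backward passes are written directly against numpy (im2col windows + einsum),
which keeps desk-scale training on 64x64 phantom slices to seconds per epoch
on one CPU and makes every training run bit-reproducible from its seed.

Optimization is plain stochastic gradient descent with momentum on a soft
Dice loss; both are implemented here so the gradient exactly matches the
loss the package reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyUNet", "SGDMomentum", "soft_dice_loss_grad", "standardize_slice"]


def standardize_slice(pixels: np.ndarray) -> np.ndarray:
    """Per-slice standardization to zero mean / unit variance.

    Applied inside the model pipeline (training and inference see the same
    transform); raw stored intensities are never modified at I/O time.
    """
    x = np.asarray(pixels, dtype=np.float64)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 1e-8 else 1.0)


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None):
    """Cross-correlation with 'same' zero padding.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout). Returns output and the
    im2col window view (needed for the weight gradient).
    """
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    else:
        xp = x
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,Cin,kh,kw)
    out = np.einsum("nhwcij,ijco->nhwo", win, w, optimize=True)
    if b is not None:
        out = out + b
    return out, win


def _conv2d_input_grad(dout: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Gradient w.r.t. the input is a correlation with the spatially flipped,
    # channel-transposed kernel.
    w_t = w[::-1, ::-1].transpose(0, 1, 3, 2)
    dx, _ = _conv2d_same(dout, np.ascontiguousarray(w_t))
    return dx


@dataclass
class SGDMomentum:
    """Classical momentum SGD: v <- mu v - lr g; w <- w + v."""

    learning_rate: float = 0.1
    momentum: float = 0.9

    def __post_init__(self) -> None:
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            v = self._velocity.get(name)
            if v is None:
                v = np.zeros_like(g)
            v = self.momentum * v - self.learning_rate * g
            self._velocity[name] = v
            params[name] += v


class TinyUNet:
    """Small fully-convolutional pixel classifier.

    Two 3x3 conv + ReLU stages feed a 1x1 logit layer that also sees the
    standardized input directly (an input skip connection). The skip makes
    near-threshold-separable foregrounds learnable within the few dozen SGD
    updates a desk-scale training run provides, while the conv stages add
    local-context smoothing of the decision.
    """

    def __init__(self, channels: int = 8, rng: np.random.Generator | None = None):
        self.channels = channels
        rng = rng or np.random.default_rng()
        c = channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "w1": he((3, 3, 1, c), 9),
            "b1": np.zeros(c),
            "w2": he((3, 3, c, c), 9 * c),
            "b2": np.zeros(c),
            # Final 1x1 over [conv features, raw input skip].
            "w3": he((1, 1, c + 1, 1), c + 1),
            "b3": np.zeros(1),
        }
        self._cache: dict[str, np.ndarray] = {}

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of standardized slices (N, H, W) -> per-pixel logits (N, H, W)."""
        x = np.asarray(x, dtype=np.float64)[..., None]  # (N,H,W,1)
        p = self.params
        z1, win1 = _conv2d_same(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, win2 = _conv2d_same(a1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        feat = np.concatenate([a2, x], axis=-1)
        logits = np.einsum("nhwc,co->nhwo", feat, p["w3"][0, 0], optimize=True) + p["b3"]
        if train:
            self._cache = {"win1": win1, "z1": z1, "win2": win2, "z2": z2, "feat": feat}
        return logits[..., 0]

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters; requires a cached
        ``forward(..., train=True)`` on the same batch."""
        c = self._cache
        if not c:
            raise RuntimeError("call forward(train=True) before backward()")
        p = self.params
        d3 = dlogits[..., None]  # (N,H,W,1)
        gw3 = np.einsum("nhwc,nhwo->co", c["feat"], d3, optimize=True)[None, None]
        gb3 = d3.sum(axis=(0, 1, 2))
        dfeat = np.einsum("nhwo,co->nhwc", d3, p["w3"][0, 0], optimize=True)
        dz2 = dfeat[..., : self.channels] * (c["z2"] > 0)
        gw2 = np.einsum("nhwcij,nhwo->ijco", c["win2"], dz2, optimize=True)
        gb2 = dz2.sum(axis=(0, 1, 2))
        da1 = _conv2d_input_grad(dz2, p["w2"])
        dz1 = da1 * (c["z1"] > 0)
        gw1 = np.einsum("nhwcij,nhwo->ijco", c["win1"], dz1, optimize=True)
        gb1 = dz1.sum(axis=(0, 1, 2))
        self._cache = {}
        return {"w1": gw1, "b1": gb1, "w2": gw2, "b2": gb2, "w3": gw3, "b3": gb3}

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid of the logits: per-pixel tumor probability."""
        return sigmoid(self.forward(x, train=False))

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_dice_loss_grad(
    logits: np.ndarray, targets: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Soft Dice loss (squared-denominator form) and its logit gradient.

    Per sample n with probabilities p = sigmoid(logits):

        loss_n = 1 - (2 sum(p t) + s) / (sum(p^2) + sum(t^2) + s)

    averaged over the batch. The squared denominator keeps the gradient
    well-behaved for near-binary probabilities and coincides with the
    cardinality form on binary inputs.
    """
    p = sigmoid(logits)
    t = np.asarray(targets, dtype=np.float64)
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (p * t).sum(axis=axes) + smooth
    den = (p * p).sum(axis=axes) + (t * t).sum(axis=axes) + smooth
    loss = float(np.mean(1.0 - num / den))
    n = p.shape[0]
    # d loss_n / d p = -(2 t den - 2 p num) / den^2 ; chain through sigmoid.
    shape = (n,) + (1,) * (p.ndim - 1)
    dp = -(2.0 * t * den.reshape(shape) - 2.0 * p * num.reshape(shape)) / (
        den.reshape(shape) ** 2
    )
    dlogits = dp * p * (1.0 - p) / n
    return loss, dlogits
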