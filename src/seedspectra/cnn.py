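"""A small 3D convolutional network for spatial-spectral patch classification.

Architecture: C1 (two 3-D kernels) -> ReLU -> C2 (four 3-D kernels) ->
ReLU -> flatten -> fully connected (128) -> ReLU -> linear -> softmax over
the two seed groups. Convolutions are "valid" with stride 1 and default
kernel size 3 x 3 x 7 (spatial x spatial x spectral), the smallest
standard receptive field compatible with 5 x 5 patches. Training is plain
minibatch SGD with momentum on the softmax cross-entropy loss, with
validation-accuracy early stopping; everything is seeded and fully
deterministic.

Implemented directly in NumPy: the network is four layers on tiny patches,
and the explicit forward/backward passes below (convolutions expressed as
sums over the 63 kernel offsets, each a batched einsum) train in seconds
at the scales this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CNN3DConfig", "CNN3DClassifier"]


@dataclass
class CNN3DConfig:
    kernel_size: tuple[int, int, int] = (3, 3, 7)  # (spatial, spatial, spectral)
    c1_channels: int = 2
    c2_channels: int = 4
    fc_width: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    rng_seed: int = 0


def _im2col(x: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    """(B, C, H, W, D) -> (B, Ho*Wo*Do, C*kh*kw*kd) patch-column matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, kshape, axis=(2, 3, 4))
    # win: (B, C, Ho, Wo, Do, kh, kw, kd) -> (B, Ho, Wo, Do, C, kh, kw, kd)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    b = x.shape[0]
    return win.reshape(b, -1, x.shape[1] * kshape[0] * kshape[1] * kshape[2])


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 3-D convolution. x: (B, Cin, H, W, D); w: (Cout, Cin, kh, kw, kd)."""
    kh, kw, kd = w.shape[2:]
    ho, wo, do = x.shape[2] - kh + 1, x.shape[3] - kw + 1, x.shape[4] - kd + 1
    cols = _im2col(x, (kh, kw, kd))  # (B, P, CK)
    out = cols @ w.reshape(w.shape[0], -1).T + b  # (B, P, Cout)
    return out.transpose(0, 2, 1).reshape(x.shape[0], w.shape[0], ho, wo, do)


def _conv3d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid conv: returns (dx, dw, db)."""
    kh, kw, kd = w.shape[2:]
    ho, wo, do = dout.shape[2:]
    cout = w.shape[0]
    cols = _im2col(x, (kh, kw, kd))  # (B, P, CK)
    dflat = dout.reshape(x.shape[0], cout, -1).transpose(0, 2, 1)  # (B, P, Cout)
    dw = np.tensordot(dflat, cols, axes=([0, 1], [0, 1])).reshape(w.shape)
    db = dout.sum(axis=(0, 2, 3, 4))
    # scatter column gradients back onto x: one slice-add per kernel offset
    dcols = (dflat @ w.reshape(cout, -1)).reshape(
        x.shape[0], ho, wo, do, x.shape[1], kh, kw, kd
    )
    dx = np.zeros_like(x)
    for i in range(kh):
        for j in range(kw):
            for k in range(kd):
                dx[:, :, i : i + ho, j : j + wo, k : k + do] += dcols[
                    :, :, :, :, :, i, j, k
                ].transpose(0, 4, 1, 2, 3)
    return dx, dw, db


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CNN3DClassifier:
    """Two-class 3-D CNN; ``fit`` then ``predict`` on (n, S, S, L) patches."""

    config: CNN3DConfig = field(default_factory=CNN3DConfig)

    def _init_params(self, s: int, n_bands: int) -> None:
        cfg = self.config
        kh, kw, kd = cfg.kernel_size
        if s < kh + (kh - 1) or n_bands < kd + (kd - 1):
            # two stacked valid convs must leave a positive output extent
            raise ValueError(
                f"patch ({s}x{s}x{n_bands}) smaller than the receptive field of two "
                f"{kh}x{kw}x{kd} convolutions"
            )
        rng = np.random.default_rng(cfg.rng_seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        c1, c2 = cfg.c1_channels, cfg.c2_channels
        self.w1 = he((c1, 1, kh, kw, kd), kh * kw * kd)
        self.b1 = np.zeros(c1)
        self.w2 = he((c2, c1, kh, kw, kd), c1 * kh * kw * kd)
        self.b2 = np.zeros(c2)
        s2 = s - 2 * (kh - 1)
        d2 = n_bands - 2 * (kd - 1)
        self._flat = c2 * s2 * s2 * d2
        self.w3 = he((self._flat, cfg.fc_width), self._flat)
        self.b3 = np.zeros(cfg.fc_width)
        self.w4 = he((cfg.fc_width, 2), cfg.fc_width)
        self.b4 = np.zeros(2)
        self._vel = {k: np.zeros_like(getattr(self, k)) for k in ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")}
        self._rng = rng

    def _forward(self, x: np.ndarray, cache: bool = False):
        a1 = _conv3d_forward(x, self.w1, self.b1)
        r1 = np.maximum(a1, 0)
        a2 = _conv3d_forward(r1, self.w2, self.b2)
        r2 = np.maximum(a2, 0)
        flat = r2.reshape(x.shape[0], -1)
        a3 = flat @ self.w3 + self.b3
        r3 = np.maximum(a3, 0)
        logits = r3 @ self.w4 + self.b4
        if cache:
            return logits, (x, a1, r1, a2, r2, flat, a3, r3)
        return logits

    def _backward(self, logits, y, cache) -> dict[str, np.ndarray]:
        x, a1, r1, a2, r2, flat, a3, r3 = cache
        n = x.shape[0]
        p = _softmax(logits)
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["w4"] = r3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dr3 = dlogits @ self.w4.T
        da3 = dr3 * (a3 > 0)
        grads["w3"] = flat.T @ da3
        grads["b3"] = da3.sum(axis=0)
        dflat = da3 @ self.w3.T
        dr2 = dflat.reshape(r2.shape)
        da2 = dr2 * (a2 > 0)
        dr1, grads["w2"], grads["b2"] = _conv3d_backward(r1, self.w2, da2)
        da1 = dr1 * (a1 > 0)
        _, grads["w1"], grads["b1"] = _conv3d_backward(x, self.w1, da1)
        return grads

    def _sgd_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        for k, g in grads.items():
            v = self._vel[k]
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            setattr(self, k, getattr(self, k) + v)
            self._vel[k] = v

    @staticmethod
    def _as_input(patches: np.ndarray) -> np.ndarray:
        """(n, S, S, L) patches -> (n, 1, S, S, L) network input."""
        p = np.asarray(patches, dtype=float)
        return p[:, None, :, :, :]

    def fit(
        self,
        train_patches: np.ndarray,
        train_labels: np.ndarray,
        val_patches: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
    ) -> "CNN3DClassifier":
        """Train with minibatch SGD; keep the best-validation-accuracy weights.

        Inputs are standardised with the training mean/sd (stored for
        prediction). Without a validation set the final weights are kept.
        """
        x = self._as_input(train_patches)
        y = np.asarray(train_labels, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        self._mu = float(x.mean())
        self._sd = float(x.std()) or 1.0
        x = (x - self._mu) / self._sd
        self._init_params(x.shape[2], x.shape[4])
        cfg = self.config

        best_acc, best_params, stale = -1.0, None, 0
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(x.shape[0])
            losses = []
            for start in range(0, order.size, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits, cache = self._forward(x[idx], cache=True)
                p = _softmax(logits)
                losses.append(-np.mean(np.log(p[np.arange(idx.size), y[idx]] + 1e-12)))
                self._sgd_step(self._backward(logits, y[idx], cache))
            if val_patches is not None and len(val_patches):
                acc = float(np.mean(self.predict(val_patches) == np.asarray(val_labels)))
                logger.debug("epoch %d: loss %.4f val acc %.4f", epoch, np.mean(losses), acc)
                if acc > best_acc + 1e-12:
                    best_acc, stale = acc, 0
                    best_params = {k: getattr(self, k).copy() for k in self._vel}
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        if best_params is not None:
            for k, v in best_params.items():
                setattr(self, k, v)
        return self

    def predict_proba(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = self._as_input(patches)
        if hasattr(self, "_mu"):
            x = (x - self._mu) / self._sd
        if not hasattr(self, "w1"):
            self._init_params(x.shape[2], x.shape[4])
        out = np.empty((x.shape[0], 2))
        for start in range(0, x.shape[0], batch_size):
            out[start : start + batch_size] = _softmax(self._forward(x[start : start + batch_size]))
        return out

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)
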