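"""Classifier backbones.

``small_cnn`` is the built-in desk-scale reference model: three 3x3
convolution blocks (8/16/32 channels, ReLU, 2x2 average pooling), global
average pooling and a single logistic output, trained with the AdaMax
optimizer on binary cross-entropy. It is written on plain numpy so the
whole pipeline runs on one CPU in minutes and is bit-reproducible under a
seed. Composite images are mean-intensity-normalized to [0, 1] and
bilinearly resized to the model's input size before entering the network.

The five large ImageNet architectures used in the original evaluation
(densenet121, inception_v3, vgg19, xception, resnet50) are pluggable: a
deep-learning framework of the user's choice supplies them through
:func:`register_backbone`. A densely connected network of L layers has
L(L+1)/2 direct connections, which is why densenet-style backbones suit
texture-like feature images; none of that changes the pipeline contract a
backbone must satisfy (``loss_and_grads`` / ``step`` / ``predict_proba``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ModelSpec",
    "Adamax",
    "SmallCNN",
    "build_model",
    "register_backbone",
    "MissingBackboneError",
    "resize_bilinear",
]

KNOWN_ARCHITECTURES = (
    "densenet121",
    "inception_v3",
    "vgg19",
    "xception",
    "resnet50",
    "small_cnn",
)


class MissingBackboneError(RuntimeError):
    """Raised when a named architecture has no registered factory."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice and input geometry.

    ``input_size`` is (height, width) after resizing; ``channels`` is 3 for
    the ImageNet backbones (grayscale replicated) and 1 for ``small_cnn``.
    """

    architecture: str = "small_cnn"
    input_size: tuple[int, int] = (40, 76)
    channels: int = 1

    def __post_init__(self) -> None:
        if self.architecture not in KNOWN_ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")


_BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, factory: Callable) -> None:
    """Register a model factory ``(spec, seed) -> model`` for a named
    architecture (used to plug in framework-backed networks)."""
    _BACKBONES[name] = factory


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the model named by ``spec``."""
    if spec.architecture == "small_cnn":
        return SmallCNN(spec.input_size, seed=seed)
    if spec.architecture in _BACKBONES:
        return _BACKBONES[spec.architecture](spec, seed)
    raise MissingBackboneError(
        f"{spec.architecture!r} needs a deep-learning framework; register a "
        "factory with voicescreen.models.register_backbone"
    )


def resize_bilinear(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D array to ``(out_h, out_w)``."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    out_h, out_w = out_hw
    ys = np.linspace(0, h - 1, out_h)
    xs = np.linspace(0, w - 1, out_w)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    a = img[np.ix_(y0, x0)]
    b = img[np.ix_(y0, x0 + 1)]
    c = img[np.ix_(y0 + 1, x0)]
    d = img[np.ix_(y0 + 1, x0 + 1)]
    return (1 - wy) * ((1 - wx) * a + wx * b) + wy * ((1 - wx) * c + wx * d)


class Adamax:
    """AdaMax: the infinity-norm variant of adaptive moment estimation."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._u: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(g))
            u = self._u.setdefault(k, np.zeros_like(g))
            m *= self.beta1
            m += (1 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            params[k] -= (self.lr / (1 - self.beta1**self.t)) * m / (u + self.eps)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution via im2col.

    x: (N, C, H, W); w: (F, C, 3, 3); returns (out, cols) with out
    (N, F, H, W).
    """
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(f, -1).T + b
    return out.reshape(n, h, wd, f).transpose(0, 3, 1, 2), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    n, c, h, wd = x_shape
    f = w.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ w.reshape(f, -1)
    # scatter columns back (col2im) over the padded input
    dxp = np.zeros((n, c, h + 2, wd + 2))
    dcols = dcols.reshape(n, h, wd, c, 3, 3)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout: np.ndarray, in_shape) -> np.ndarray:
    n, c, h, w = in_shape
    dx = np.zeros(in_shape)
    up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    dx[:, :, : up.shape[2], : up.shape[3]] = up
    return dx


class SmallCNN:
    """Three-conv-block binary classifier on single-channel images."""

    CHANNELS = (8, 16, 32)

    def __init__(self, input_size: tuple[int, int] = (40, 76), seed: int = 0) -> None:
        self.input_size = tuple(input_size)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(self.CHANNELS):
            fan_in = c_in * 9
            self.params[f"w{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["w_fc"] = rng.normal(0, np.sqrt(1.0 / c_in), (c_in,))
        self.params["b_fc"] = np.zeros(1)
        self.fitted = False

    def preprocess(self, images: list[np.ndarray] | np.ndarray) -> np.ndarray:
        """uint8 composites -> (N, 1, H, W) centered floats at input size.

        Intensities map to [-0.5, 0.5]; centering keeps the first conv
        layer well conditioned (composites are bright on average).
        """
        arr = [
            resize_bilinear(np.asarray(im, float) / 255.0 - 0.5, self.input_size)
            for im in images
        ]
        return np.stack(arr)[:, None, :, :]

    def _forward(self, x: np.ndarray):
        cache = []
        h = x
        for i in range(len(self.CHANNELS)):
            out, cols = _conv_forward(h, self.params[f"w{i}"], self.params[f"b{i}"])
            relu_mask = out > 0
            a = out * relu_mask
            p = _avgpool2(a) if i < len(self.CHANNELS) - 1 else a
            cache.append((h.shape, cols, relu_mask, a.shape, i < len(self.CHANNELS) - 1))
            h = p
        feats = h.mean(axis=(2, 3))  # global average pool
        logits = feats @ self.params["w_fc"] + self.params["b_fc"][0]
        return logits, feats, h.shape, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and parameter gradients for one batch."""
        n = x.shape[0]
        logits, feats, pooled_shape, cache = self._forward(x)
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        grads: dict[str, np.ndarray] = {}
        dlogits = (p - y) / n
        grads["w_fc"] = feats.T @ dlogits
        grads["b_fc"] = np.array([dlogits.sum()])
        dfeats = dlogits[:, None] * self.params["w_fc"][None, :]
        dh = np.broadcast_to(
            dfeats[:, :, None, None] / (pooled_shape[2] * pooled_shape[3]), pooled_shape
        ).copy()
        for i in reversed(range(len(self.CHANNELS))):
            x_shape, cols, relu_mask, a_shape, pooled = cache[i]
            da = _avgpool2_backward(dh, a_shape) if pooled else dh
            dout = da * relu_mask
            dh, dw, db = _conv_backward(dout, cols, self.params[f"w{i}"], x_shape)
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return loss, grads

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        logits, *_ = self._forward(x)
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def predict_proba(self, images) -> np.ndarray:
        """Per-image AD probability scores in [0, 1]."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        if len(images) == 0:
            return np.zeros(0)
        x = self.preprocess(images)
        logits, *_ = self._forward(x)
        return 1.0 / (1.0 + np.exp(-logits))

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in state.items()}
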