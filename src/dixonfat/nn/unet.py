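"""Encoder–decoder U-Net for per-pixel classification of Dixon slices.

The architecture follows the standard U-Net pattern: ``depth`` encoder
levels of two 3x3 convolution + ReLU blocks with channel doubling and 2x2
max-pooling, a bottleneck, then a mirrored decoder of 2x nearest-neighbor
upsampling + 3x3 convolution, skip concatenation, and two more 3x3
convolutions per level, finished by a 1x1 classification head. With
depth 4 and a 384-pixel input the bottleneck feature map is 24x24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Var

__all__ = ["UNetConfig", "UNet", "build_unet", "softmax"]


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``out_classes`` is 3 for both tasks: background / abdominal-wall ring /
    inner region for the region model, and background / SAT / VAT for the
    fat-pixel model. ``input_size`` must be divisible by ``2**depth``.
    """

    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    out_classes: int = 3
    input_size: int = 384

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if self.base_channels < 1 or self.out_classes < 2:
            raise ValueError("base_channels >= 1 and out_classes >= 2 required")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // (2**self.depth)


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> tuple[Var, Var]:
    std = np.sqrt(2.0 / (c_in * k * k))
    w = Var(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32))
    b = Var(np.zeros(c_out, dtype=np.float32))
    return w, b


class UNet:
    """A trainable U-Net; weights live in :class:`Var` leaves."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        d, base = config.depth, config.base_channels
        self.enc: list[list[tuple[Var, Var]]] = []
        c_in = config.in_channels
        for i in range(d):
            c_out = base * (2**i)
            self.enc.append([_he_conv(rng, c_out, c_in, 3), _he_conv(rng, c_out, c_out, 3)])
            c_in = c_out
        c_bn = base * (2**d)
        self.bottleneck = [_he_conv(rng, c_bn, c_in, 3), _he_conv(rng, c_bn, c_bn, 3)]
        self.dec: list[dict] = []
        c_prev = c_bn
        for i in reversed(range(d)):
            c_out = base * (2**i)
            self.dec.append(
                {
                    "up": _he_conv(rng, c_out, c_prev, 3),
                    "conv": [
                        _he_conv(rng, c_out, 2 * c_out, 3),
                        _he_conv(rng, c_out, c_out, 3),
                    ],
                }
            )
            c_prev = c_out
        self.head = _he_conv(rng, config.out_classes, c_prev, 1)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Var]:
        params: list[Var] = []
        for block in self.enc:
            for w, b in block:
                params += [w, b]
        for w, b in self.bottleneck:
            params += [w, b]
        for lvl in self.dec:
            params += list(lvl["up"])
            for w, b in lvl["conv"]:
                params += [w, b]
        params += list(self.head)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.astype(np.float32).copy()

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray | Var) -> Var:
        """Map (N, in_channels, H, W) input to per-pixel class logits.

        The returned Var holds NHWC data ``(N, H, W, out_classes)`` — the
        internal layout of the conv stack; :meth:`predict_proba` exposes
        the conventional channels-first probability maps.
        """
        if not isinstance(x, Var):
            x = Var(np.transpose(np.asarray(x, dtype=np.float32), (0, 2, 3, 1)))
        h, w = x.shape[1], x.shape[2]
        if h % (2**self.config.depth) or w % (2**self.config.depth):
            raise ValueError("spatial size must be divisible by 2^depth")
        skips: list[Var] = []
        t = x
        for block in self.enc:
            for wgt, bia in block:
                t = ad.relu(ad.conv2d(t, wgt, bia, pad=1))
            skips.append(t)
            t = ad.maxpool2(t)
        for wgt, bia in self.bottleneck:
            t = ad.relu(ad.conv2d(t, wgt, bia, pad=1))
        for lvl, skip in zip(self.dec, reversed(skips)):
            t = ad.upsample2(t)
            t = ad.relu(ad.conv2d(t, lvl["up"][0], lvl["up"][1], pad=1))
            t = ad.concat(skip, t)
            for wgt, bia in lvl["conv"]:
                t = ad.relu(ad.conv2d(t, wgt, bia, pad=1))
        wh, bh = self.head
        return ad.conv2d(t, wh, bh, pad=0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities ``(N, out_classes, H, W)``."""
        logits = self.forward(np.asarray(x, dtype=np.float32)).data
        return softmax(np.transpose(logits, (0, 3, 1, 2)))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a U-Net with deterministic He-initialized weights."""
    return UNet(config, seed=seed)
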