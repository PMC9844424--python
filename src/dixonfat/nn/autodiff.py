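"""Tape-based reverse-mode automatic differentiation on numpy arrays.

Only the handful of operations a 2D segmentation U-Net needs: stride-1 2D
convolution (correlation), ReLU, 2x2 max-pooling, 2x nearest-neighbor
upsampling, and channel concatenation. Activations use the channels-last
NHWC layout and float32; convolutions are decomposed into one BLAS sgemm
per kernel tap (shift-and-matmul), which on a single CPU core runs
several times faster than materializing an im2col matrix.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

__all__ = ["Var", "conv2d", "relu", "maxpool2", "upsample2", "concat"]


class Var:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents: tuple = (), backward: Optional[Callable] = None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad_output: np.ndarray) -> None:
        """Backpropagate ``d(loss)/d(self) = grad_output`` through the tape."""
        topo: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate(np.asarray(grad_output, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def conv2d(x: Var, w: Var, b: Var, pad: int = 1) -> Var:
    """Stride-1 2D convolution, zero padding; same-size for 3x3 with pad=1.

    ``x`` is NHWC ``(N, H, W, C)``; the kernel keeps the conventional
    ``(O, C, kh, kw)`` layout. One sgemm per kernel tap.
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    n, h, wd, c = x.data.shape
    o = w.data.shape[0]
    xp = x.data
    if pad:
        xp = np.pad(xp, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    ho = h + 2 * pad - kh + 1
    wo = wd + 2 * pad - kw + 1
    acc = np.empty((n, ho, wo, o), dtype=np.float32)
    acc[:] = b.data
    for i in range(kh):
        for j in range(kw):
            acc += xp[:, i:i + ho, j:j + wo, :] @ w.data[:, :, i, j].T
    out = Var(acc, parents=(x, w, b))

    def backward(g: np.ndarray) -> None:
        b.accumulate(g.sum(axis=(0, 1, 2)))
        g2 = g.reshape(-1, o)
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + ho, j:j + wo, :].reshape(-1, c)
                dw[:, :, i, j] = g2.T @ patch
                dxp[:, i:i + ho, j:j + wo, :] += g @ w.data[:, :, i, j]
        w.accumulate(dw)
        if pad:
            dxp = dxp[:, pad:-pad, pad:-pad, :]
        x.accumulate(dxp)

    out._backward = backward
    return out


def relu(x: Var) -> Var:
    y = np.maximum(x.data, 0.0)
    out = Var(y, parents=(x,))

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * (x.data > 0))

    out._backward = backward
    return out


def maxpool2(x: Var) -> Var:
    """2x2 max pooling, stride 2; H and W must be even. NHWC."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = (
        x.data.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Var(y, parents=(x,))

    def backward(g: np.ndarray) -> None:
        gr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        x.accumulate(gx)

    out._backward = backward
    return out


def upsample2(x: Var) -> Var:
    """2x nearest-neighbor upsampling. NHWC."""
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Var(y, parents=(x,))
    n, h, w, c = x.data.shape

    def backward(g: np.ndarray) -> None:
        x.accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    out._backward = backward
    return out


def concat(a: Var, b: Var) -> Var:
    """Concatenate along the channel (last) axis."""
    y = np.concatenate([a.data, b.data], axis=-1)
    out = Var(y, parents=(a, b))
    ca = a.data.shape[-1]

    def backward(g: np.ndarray) -> None:
        a.accumulate(g[..., :ca])
        b.accumulate(g[..., ca:])

    out._backward = backward
    return out
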