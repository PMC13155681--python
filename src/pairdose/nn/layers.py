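"""Layers and an Adam optimizer built on the autodiff core.

Initialization follows the usual He/Glorot fan-in scaling and is fully
determined by the ``numpy.random.Generator`` passed in, so every network in
the package is bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "Embedding", "Conv1d", "MLP", "Adam"]


class Linear:
    """Affine map ``x @ W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    """Token-index lookup table.

    Row ``pad_index`` (when given) is pinned to the zero vector and receives
    no updates, so padding positions contribute exactly nothing downstream.
    """

    def __init__(
        self,
        n_tokens: int,
        dim: int,
        rng: np.random.Generator,
        pad_index: int | None = None,
    ):
        w = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_tokens, dim))
        if pad_index is not None:
            w[pad_index] = 0.0
        self.W = Tensor(w, requires_grad=True)
        self.pad_index = pad_index

    def __call__(self, tokens: np.ndarray) -> Tensor:
        return self.W.take_rows(np.asarray(tokens))

    def pin_pad_row(self) -> None:
        if self.pad_index is not None:
            self.W.data[self.pad_index] = 0.0

    def params(self) -> list[Tensor]:
        return [self.W]


class Conv1d:
    """1-D convolution over a (batch, length, channels) sequence.

    'same' zero padding; implemented as window extraction followed by a
    single matrix product with the (kernel*channels, filters) weight.
    """

    def __init__(self, n_in: int, n_filters: int, kernel: int, rng: np.random.Generator):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel size must be a positive odd integer")
        scale = np.sqrt(2.0 / (n_in * kernel))
        self.W = Tensor(
            rng.normal(0.0, scale, size=(kernel * n_in, n_filters)), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)
        self.kernel = kernel
        self.n_in = n_in
        self.n_filters = n_filters

    def __call__(self, x: Tensor) -> Tensor:
        batch, length, _ = x.shape
        half = self.kernel // 2
        padded = x.pad_axis1(half, half)
        idx = np.arange(length)[:, None] + np.arange(self.kernel)[None, :]
        windows = padded.gather_windows(idx)  # (B, L, K, C)
        flat = windows.reshape(batch, length, self.kernel * self.n_in)
        return flat @ self.W + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with ReLU between them.

    ``final_activation`` is applied after the last affine layer ('linear'
    leaves it untouched).
    """

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        final_activation: str = "linear",
    ):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        if final_activation not in ("linear", "relu"):
            raise ValueError(f"unknown final activation {final_activation!r}")
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        x = self.layers[-1](x)
        if self.final_activation == "relu":
            x = x.relu()
        return x

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
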