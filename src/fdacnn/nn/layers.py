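"""Trainable layer modules and the Adam optimiser for the numpy backend.

Modules register their sub-modules in construction order, which the
network builders exploit to derive an auditable layer inventory: every
:class:`Conv2d` / :class:`ConvTranspose2d` carries its kernel geometry
and channel counts as plain attributes.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Adam"]

DTYPE = np.float32


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        """All modules in the subtree, depth-first in registration order."""
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self.modules():
            for value in vars(mod).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def train(self) -> "Module":
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self) -> "Module":
        for mod in self.modules():
            mod.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """Flat list of all learnable and running-statistic arrays."""
        arrays: list[np.ndarray] = []
        for mod in self.modules():
            for name in sorted(vars(mod)):
                value = vars(mod)[name]
                if isinstance(value, Tensor) and value.requires_grad:
                    arrays.append(value.data)
                elif isinstance(value, np.ndarray):
                    arrays.append(value)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for mod in self.modules():
            for name in sorted(vars(mod)):
                value = vars(mod)[name]
                if isinstance(value, Tensor) and value.requires_grad:
                    value.data = np.array(next(it), dtype=value.data.dtype)
                elif isinstance(value, np.ndarray):
                    src = next(it)
                    value[...] = src

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 2,
        stride: int = 2,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_channels, out_channels, kernel_size, kernel_size)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Adam:
    """Adam with bias correction; the learning rate may be reset per epoch."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
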