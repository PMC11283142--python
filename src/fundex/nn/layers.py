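"""Layer and module primitives built on :mod:`fundex.nn.tensor`.

Initialisation is seeded: every Module draws its parameters from the
``numpy.random.Generator`` passed to its constructor, so two modules built
with identically-seeded generators are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvTranspose2d", "Linear",
    "LayerNorm", "LeakyReLU", "Sigmoid",
]


class Module:
    """Base class: parameter traversal plus flat state-dict export/import."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


def _he_fan_in(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator, bias: bool = True):
        self.stride, self.padding = stride, padding
        self.weight = _he_fan_in(rng, (out_ch, in_ch, kernel, kernel),
                                 in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator, bias: bool = True):
        self.stride, self.padding = stride, padding
        self.weight = _he_fan_in(rng, (in_ch, out_ch, kernel, kernel),
                                 in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator):
        self.weight = _he_fan_in(rng, (in_dim, out_dim), in_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
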