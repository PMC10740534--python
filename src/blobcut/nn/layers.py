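"""Neural-network layers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d, zero_stuff3d

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "Linear",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Sequential",
]


class Module:
    """Base class: parameter discovery, state dicts, call syntax."""

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr


class Conv3d(Module):
    """3D convolution; weights ~ N(0, 0.02), replicate padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        pad_mode: str = "replicate",
        bias: bool = True,
        init_std: float = 0.02,
    ):
        self.stride = stride
        self.pad = (kernel_size - 1) // 2 if pad is None else pad
        self.pad_mode = pad_mode
        shape = (out_channels, in_channels, kernel_size, kernel_size, kernel_size)
        self.weight = Tensor(rng.normal(0.0, init_std, shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.pad, self.pad_mode)


class ConvTranspose3d(Module):
    """Fractional-strided convolution: zero-stuffing then a stride-1 conv."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        factor: int = 2,
        pad_mode: str = "replicate",
    ):
        self.factor = factor
        self.conv = Conv3d(
            in_channels, out_channels, kernel_size, rng, stride=1, pad_mode=pad_mode
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(zero_stuff3d(x, self.factor))


class InstanceNorm3d(Module):
    """Per-channel spatial standardization (no affine parameters)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(1, 2, 3), keepdims=True)
        return centered * (var + self.eps).pow(-0.5)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.weight = Tensor(rng.normal(0.0, init_std, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
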