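"""Layer building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "DepthwiseConv3x3",
    "PointwiseConv",
    "Conv3x3",
    "BatchNorm2d",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    # -- mode --------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data.copy()
                 for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy()
                      for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            target = params if kind == "param" else buffers
            if name not in target:
                raise KeyError(f"unexpected state entry {key!r}")
            if target[name].shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: "
                    f"{target[name].shape} vs {value.shape}"
                )
            if kind == "param":
                params[name].data = value.astype(np.float32).copy()
            else:
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, items: list[Module]):
        super().__init__()
        for i, item in enumerate(items):
            setattr(self, f"m{i}", item)
        self._n = len(items)

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i: int) -> Module:
        return getattr(self, f"m{i}")


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 correlation, reflect 'same' padding, no bias."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he(rng, (channels, 3, 3), 9))

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv3x3(ag.reflect_pad1(x), self.weight)


class PointwiseConv(Module):
    """1x1 convolution mixing channels."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = False):
        super().__init__()
        self.weight = Parameter(
            _he(rng, (out_channels, in_channels), in_channels))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.pointwise_conv(x, self.weight, self.bias)


class Conv3x3(Module):
    """Dense 3x3 correlation (plain-U-Net baseline), reflect padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(
            _he(rng, (out_channels, in_channels, 3, 3), 9 * in_channels))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3x3(ag.reflect_pad1(x), self.weight)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )
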