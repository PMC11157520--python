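"""Minimal neural-network layer abstractions over the autodiff engine.

Modules own named :class:`Parameter` tensors, support train/eval modes,
and serialize to flat ``{name: ndarray}`` state dicts.  Weights are
initialized with a truncated normal (resampled outside +/- 2 sd), the
convention used for all convolutional and fully connected layers here;
biases start at zero.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv3d",
    "Linear",
    "GroupNorm3d",
    "ReLU",
    "MaxPool3d",
    "truncated_normal",
]


def truncated_normal(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Normal(0, sd) samples resampled until they fall inside +/- 2 sd."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > 2.0 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * sd
    return out.astype(ad.DEFAULT_DTYPE)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=ad.DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class: attribute traversal gives parameters and submodules."""

    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- modes --------------------------------------------------------------
    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    # -- serialization ------------------------------------------------------
    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._walk_buffer_owners())
        missing = (set(params) | set(buffers)) - set(state)
        extra = set(state) - (set(params) | set(buffers))
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, (owner, attr) in buffers.items():
            setattr(owner, attr, state[name].copy())

    def _walk_buffer_owners(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, (self, name)
        for name, child in self._children():
            yield from child._walk_buffer_owners(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv3d(Module):
    """3D convolution layer; padding may be an int triple or ``"same"``."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride=1,
        padding=0,
        dilation=1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init_sd: float = 0.1,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        if padding == "same":
            eff = kernel_size + (kernel_size - 1) * (self._max_dilation() - 1)
            if eff % 2 == 0:
                raise ValueError("'same' padding requires an odd effective kernel")
            padding = self._same_padding()
        self.padding = padding
        rng = rng if rng is not None else np.random.default_rng(0)
        shape = (out_channels, in_channels) + (kernel_size,) * 3
        self.weight = Parameter(truncated_normal(rng, shape, init_sd))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def _max_dilation(self) -> int:
        d = self.dilation
        return max(d) if isinstance(d, (tuple, list)) else int(d)

    def _same_padding(self):
        k = self.kernel_size
        d = self.dilation
        ds = d if isinstance(d, (tuple, list)) else (d,) * 3
        return tuple((k + (k - 1) * (r - 1) - 1) // 2 for r in ds)

    def forward(self, x):
        return ad.conv3d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        init_sd: float = 0.1,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(truncated_normal(rng, (in_features, out_features), init_sd))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return x @ self.weight + self.bias


class GroupNorm3d(Module):
    """Group normalization over (channel-group, D, H, W) per sample.

    Statistics are computed per sample, so behaviour is identical in
    training and inference and independent of batch composition — a
    better fit than batch statistics for small-batch volumetric
    training.
    """

    def __init__(self, num_channels: int, num_groups: int = 8, eps: float = 1e-5):
        super().__init__()
        self.num_groups = math_gcd_groups(num_channels, num_groups)
        self.eps = eps
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))

    def forward(self, x):
        x = ad.as_tensor(x)
        B, C, D, H, W = x.shape
        G = self.num_groups
        xg = x.reshape(B, G, C // G * D * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xhat = (centered * (var + self.eps) ** -0.5).reshape(B, C, D, H, W)
        g = self.gamma.reshape(1, C, 1, 1, 1)
        b = self.beta.reshape(1, C, 1, 1, 1)
        return xhat * g + b


def math_gcd_groups(channels: int, groups: int) -> int:
    """Largest divisor of `channels` not exceeding `groups`."""
    g = min(groups, channels)
    while channels % g:
        g -= 1
    return g


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class MaxPool3d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return ad.max_pool3d(x, self.kernel)
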