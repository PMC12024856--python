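"""Layer abstractions on top of the autodiff core.

Mirrors the familiar module/parameter idiom: a :class:`Module` owns
:class:`Parameter` leaves and child modules, exposes ``named_parameters`` /
``state_dict`` and a train/eval switch (batch-norm layers use batch
statistics in training mode and running statistics in eval mode).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- child discovery --------------------------------------------------
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
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- buffers (non-trainable state, e.g. batch-norm running stats) -----
    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        if not hasattr(self, "_buffer_names"):
            self._buffer_names: list[str] = []
        self._buffer_names.append(name)
        setattr(self, name, value)

    # -- mode / grad bookkeeping ------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[f"buffer:{name}"] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {f"buffer:{n}" for n, _ in self.named_buffers()}
        missing = (set(params) | buffers) - set(state)
        if missing:
            raise KeyError(f"state dict is missing entries: {sorted(missing)}")
        for name, p in params.items():
            value = np.asarray(state[name], dtype=np.float32)
            if value.shape != p.shape:
                raise ValueError(
                    f"shape mismatch for '{name}': checkpoint {value.shape}, "
                    f"model {p.shape}"
                )
            p.data = value.copy()
        # buffers are stored flat; walk modules again to assign
        def assign(module: Module, prefix: str = ""):
            for bname in getattr(module, "_buffer_names", ()):
                key = f"buffer:{prefix}{bname}"
                setattr(module, bname, np.asarray(state[key], dtype=np.float32).copy())
            for cname, child in module._children():
                assign(child, f"{prefix}{cname}.")

        assign(self)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# initialisation helpers
# ---------------------------------------------------------------------------

def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Standard stride-1 same-padding convolution (optionally dilated)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, *, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.gelu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class LayerNormChannels(Module):
    """Layer norm over the channel axis, independently at each pixel.

    This is the "channels-first" convention of ConvNeXt-style trunks: for a
    (N, C, H, W) map each (n, h, w) column of C activations is standardised
    and then scaled/shifted by per-channel weights.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.bias = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        out, _, _ = ag.norm_affine(x, self.weight, self.bias, (1,), self.eps)
        return out


class _BatchNormBase(Module):
    _param_shape: tuple[int, ...] = ()
    _axes: tuple[int, ...] = ()

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        shape = tuple(channels if s == -1 else s for s in self._param_shape)
        self.weight = Parameter(np.ones(shape, dtype=np.float32))
        self.bias = Parameter(np.zeros(shape, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(shape, dtype=np.float32))
        self.register_buffer("running_var", np.ones(shape, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.norm_affine(x, self.weight, self.bias,
                                          self._axes, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(np.float32)
            return out
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
        xhat = (x - Tensor(self.running_mean)) * Tensor(inv)
        return xhat * self.weight + self.bias


class BatchNorm2d(_BatchNormBase):
    _param_shape = (1, -1, 1, 1)
    _axes = (0, 2, 3)


class BatchNorm1d(_BatchNormBase):
    """Batch norm over (N, C) feature vectors."""

    _param_shape = (1, -1)
    _axes = (0,)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): spatial mean per channel."""
    return x.mean(axis=(2, 3))
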