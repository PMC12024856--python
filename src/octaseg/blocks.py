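"""Full-resolution convolutional building blocks.

The trunk of the segmentation network is a stack of identical blocks that
never change spatial resolution (stride 1, same padding, no pooling).  Three
block families are provided:

* :class:`ResidualBlock` — two plain 3x3 convolutions with a skip, the
  classic full-resolution baseline stage;
* :class:`OriginalConvNeXtV2Block` — depthwise 7x7 -> channel layer norm ->
  1x1 expand -> GeLU -> GRN -> 1x1 project -> residual;
* :class:`ImprovedConvNeXtV2Block` — the lightweight variant used here:
  the 1x1 pointwise convolutions are replaced by full 3x3 convolutions and
  the 7x7/3x3 convolutions are applied *recursively* with shared weights
  (R iterations, re-injecting the block input each round), which enriches
  features at zero parameter cost.

Global response normalisation (GRN) rescales each channel by the ratio of
its global L2 response to the cross-channel mean response, with learned
per-channel gain/bias initialised to zero so the layer starts as identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
import json

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from . import nn


# ---------------------------------------------------------------------------
# depthwise-separable convolution
# ---------------------------------------------------------------------------

class DepthwiseSeparableConv(nn.Module):
    """Depthwise k x k filtering per channel followed by a 1x1 pointwise mix.

    Parameter cost is ``C_in*k^2 + C_in`` (depthwise, with bias) plus
    ``C_in*C_out + C_out`` (pointwise, with bias) — an order of magnitude
    below a standard convolution for the kernel sizes used here.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = nn.DepthwiseConv2d(
            in_channels, kernel_size, dilation=dilation, bias=bias, rng=rng)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


def effective_receptive_field(kernel_size: int, dilation: int) -> int:
    """Span of a dilated kernel: ``k + (k - 1)(d - 1)``."""
    return kernel_size + (kernel_size - 1) * (dilation - 1)


# ---------------------------------------------------------------------------
# recursion
# ---------------------------------------------------------------------------

def recursive_apply(conv, x: Tensor, R: int) -> Tensor:
    """Apply a weight-shared, shape-preserving operator recursively.

    ``y_1 = conv(x)``; ``y_t = conv(x + y_{t-1})`` for ``t = 2..R``.  The same
    weights are used at every iteration, so recursion depth never changes the
    trainable parameter count.  ``conv`` must map C -> C at unchanged H x W.
    """
    if R < 1:
        raise ValueError(f"recursion depth must be >= 1, got {R}")
    y = conv(x)
    if y.shape != x.shape:
        raise ValueError(
            f"recursive operator must preserve shape: got {y.shape} from {x.shape}"
        )
    for _ in range(R - 1):
        y = conv(x + y)
    return y


class RecursiveConv(nn.Module):
    """Recursion wrapper usable also around channel-changing convolutions.

    When the wrapped convolution maps C -> C this is exactly
    :func:`recursive_apply`.  When it changes the channel count the previous
    iterate is matched to the input's channel count before re-injection by
    truncating or zero-padding channels (a parameter-free projection), so the
    weight-sharing property — and hence the parameter count — is preserved.
    """

    def __init__(self, conv: nn.Module, R: int = 2):
        super().__init__()
        if R < 1:
            raise ValueError(f"recursion depth must be >= 1, got {R}")
        self.conv = conv
        self.R = R

    @staticmethod
    def _match_channels(y: Tensor, channels: int) -> Tensor:
        c = y.shape[1]
        if c == channels:
            return y
        if c > channels:
            return ag.getitem(y, (slice(None), slice(0, channels)))
        pad = Tensor(np.zeros((y.shape[0], channels - c) + y.shape[2:], dtype=np.float32))
        return ag.concat([y, pad], axis=1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        for _ in range(self.R - 1):
            y = self.conv(x + self._match_channels(y, x.shape[1]))
        return y


# ---------------------------------------------------------------------------
# global response normalisation
# ---------------------------------------------------------------------------

class GRN(nn.Module):
    """Global response normalisation with zero-initialised gain and bias.

    ``G_c = ||x_c||_2`` over space, ``N_c = G_c / (mean_c G + eps)``,
    ``out = gamma * (x * N) + beta + x``.  At initialisation
    (gamma = beta = 0) the layer is the identity.  Adds exactly ``2 C``
    trainable parameters and has no batch-size dependence (each sample is
    normalised on its own).
    """

    EPS = 1e-6

    def __init__(self, channels: int):
        super().__init__()
        self.weight = nn.Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.bias = nn.Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        # tiny floor inside the sqrt keeps the gradient finite on an
        # identically-zero channel
        g = ag.sqrt((x * x).sum(axis=(2, 3), keepdims=True), eps=1e-12)
        n = g / (g.mean(axis=1, keepdims=True) + self.EPS)
        return self.weight * (x * n) + self.bias + x


def grn(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Functional GRN for explicitly supplied per-channel gain/bias vectors."""
    c = x.shape[1]
    if gamma.size != c or beta.size != c:
        raise ValueError(
            f"gamma/beta must have length {c}, got {gamma.size}/{beta.size}"
        )
    layer = GRN(c)
    layer.weight.data = np.asarray(gamma.data if isinstance(gamma, Tensor) else gamma,
                                   dtype=np.float32).reshape(1, c, 1, 1)
    layer.bias.data = np.asarray(beta.data if isinstance(beta, Tensor) else beta,
                                 dtype=np.float32).reshape(1, c, 1, 1)
    return layer(x)


# ---------------------------------------------------------------------------
# trunk blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockConfig:
    """Architectural knobs of one trunk stage."""

    channels: int = 32
    recursion_R: int = 2
    expansion_width: int = 48   # hidden width of the middle convolutions
    pointwise_kind: str = "conv3x3"   # {"conv1x1", "conv3x3"}
    use_grn: bool = True

    def __post_init__(self):
        if self.recursion_R < 1:
            raise ValueError(f"recursion_R must be >= 1, got {self.recursion_R}")
        if self.pointwise_kind not in ("conv1x1", "conv3x3"):
            raise ValueError(f"unknown pointwise_kind: {self.pointwise_kind!r}")


class ImprovedConvNeXtV2Block(nn.Module):
    """Recursive ConvNeXt V2 stage with 3x3 middle convolutions.

    Pipeline: recursive depthwise 7x7 -> channel LN -> recursive 3x3 expand
    (C -> E, full channel mixing) -> GeLU -> GRN -> recursive 3x3 project
    (E -> C) -> residual add of the block input.  Spatial size is preserved
    throughout.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, e, r = cfg.channels, cfg.expansion_width, cfg.recursion_R
        self.cfg = cfg
        self.dwconv = RecursiveConv(nn.DepthwiseConv2d(c, 7, rng=rng), r)
        self.norm = nn.LayerNormChannels(c)
        self.expand = RecursiveConv(nn.Conv2d(c, e, 3, rng=rng), r)
        self.grn = GRN(e) if cfg.use_grn else None
        self.project = RecursiveConv(nn.Conv2d(e, c, 3, rng=rng), r)

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.expand(y)
        y = ag.gelu(y)
        if self.grn is not None:
            y = self.grn(y)
        y = self.project(y)
        out = x + y
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activations in ConvNeXt V2 stage")
        return out


class OriginalConvNeXtV2Block(nn.Module):
    """Non-recursive ConvNeXt V2 stage with 1x1 pointwise convolutions."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, e = cfg.channels, cfg.expansion_width
        self.cfg = cfg
        self.dwconv = nn.DepthwiseConv2d(c, 7, rng=rng)
        self.norm = nn.LayerNormChannels(c)
        self.expand = nn.Conv2d(c, e, 1, rng=rng)
        self.grn = GRN(e) if cfg.use_grn else None
        self.project = nn.Conv2d(e, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(self.dwconv(x))
        y = ag.gelu(self.expand(y))
        if self.grn is not None:
            y = self.grn(y)
        y = self.project(y)
        out = x + y
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activations in ConvNeXt V2 stage")
        return out


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with batch norm, ReLU and a skip connection."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c = cfg.channels
        self.cfg = cfg
        self.conv1 = nn.Conv2d(c, c, 3, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        y = ag.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return ag.relu(x + y)


# ---------------------------------------------------------------------------
# parameter reporting
# ---------------------------------------------------------------------------

def millions_2dp(total: int) -> float:
    """Integer parameter count -> millions, round-half-up to 2 decimals."""
    return float((Decimal(total) / Decimal(10 ** 6)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ParamReport:
    """Per-component trainable parameter tally."""

    per_component: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.per_component)

    @property
    def total_millions_2dp(self) -> float:
        return millions_2dp(self.total)

    def to_text(self) -> str:
        width = max((len(name) for name, _ in self.per_component), default=9)
        width = max(width, len("component"))
        lines = [f"{'component':<{width}}  {'params':>10}"]
        for name, n in self.per_component:
            lines.append(f"{name:<{width}}  {n:>10d}")
        lines.append(f"{'total':<{width}}  {self.total:>10d}  "
                     f"({self.total_millions_2dp:.2f} M)")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "per_component": {name: n for name, n in self.per_component},
            "total": self.total,
            "total_millions_2dp": self.total_millions_2dp,
        }, indent=2)


def count_parameters(model: nn.Module) -> ParamReport:
    """Exact trainable parameter count, broken down by top-level child."""
    report = ParamReport()
    own = sum(p.size for name, p in vars(model).items()
              if isinstance(p, nn.Parameter))
    if own:
        report.per_component.append(("(own)", own))
    for name, child in model._children():
        report.per_component.append((name, child.num_parameters()))
    if not report.per_component:
        report.per_component.append(("(own)", model.num_parameters()))
    return report
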