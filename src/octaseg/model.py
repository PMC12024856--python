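"""Assembly of the full-resolution vessel-segmentation network.

The network keeps the input resolution end to end: a 3x3 stem lifts the
grayscale angiogram to 32 channels, four identical trunk stages refine the
features, a hybrid attention stage (DWAM) plus fusion stage (EFF) reweights
them, and a pointwise head with a sigmoid emits a per-pixel vessel
probability map of the same H x W as the input.

A registry of named variants mirrors the ablation grid: trunk-only builds
with each block family, recursion toggled on/off, and 2..6-stage trunks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from . import nn
from .attention import AttentionStage, DwamConfig
from .blocks import (
    BlockConfig,
    ImprovedConvNeXtV2Block,
    OriginalConvNeXtV2Block,
    ParamReport,
    ResidualBlock,
    count_parameters,
)

_BLOCK_KINDS = ("residual", "convnextv2_original", "convnextv2_3x3",
                "convnextv2_3x3_recursive")


@dataclass
class ModelConfig:
    """Every architectural knob of the network."""

    in_channels: int = 1
    trunk_channels: int = 32
    num_stages: int = 4
    block_kind: str = "convnextv2_3x3_recursive"
    recursion_R: int = 2
    expansion_width: int = 48
    attention: str = "dwam_eff"           # {"none", "dwam_eff"}
    dwam: DwamConfig = field(default_factory=DwamConfig)
    eag_mid_channels: int = 32
    head_kernel: int = 1                  # 11 is supported as an alternative
    seed: int = 0

    def __post_init__(self):
        if self.num_stages < 1:
            raise ValueError(f"num_stages must be >= 1, got {self.num_stages}")
        if self.block_kind not in _BLOCK_KINDS:
            raise ValueError(
                f"unknown block_kind {self.block_kind!r}; one of {_BLOCK_KINDS}")
        if self.attention not in ("none", "dwam_eff"):
            raise ValueError(f"unknown attention mode: {self.attention!r}")

    def block_config(self) -> BlockConfig:
        if self.block_kind == "convnextv2_3x3_recursive":
            return BlockConfig(self.trunk_channels, self.recursion_R,
                               self.expansion_width, "conv3x3")
        if self.block_kind == "convnextv2_3x3":
            return BlockConfig(self.trunk_channels, 1,
                               self.expansion_width, "conv3x3")
        if self.block_kind == "convnextv2_original":
            return BlockConfig(self.trunk_channels, 1,
                               self.expansion_width, "conv1x1")
        return BlockConfig(self.trunk_channels, 1, self.expansion_width)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("dwam"), dict):
            d["dwam"] = DwamConfig(**d["dwam"])
        return cls(**d)


class SegmentationNet(nn.Module):
    """Stem -> N identical full-resolution stages -> attention -> head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.trunk_channels

        self.stem_conv = nn.Conv2d(cfg.in_channels, c, 3, rng=rng)
        self.stem_norm = nn.BatchNorm2d(c)

        bcfg = cfg.block_config()
        stages = []
        for _ in range(cfg.num_stages):
            if cfg.block_kind in ("convnextv2_3x3", "convnextv2_3x3_recursive"):
                stages.append(ImprovedConvNeXtV2Block(bcfg, rng=rng))
            elif cfg.block_kind == "convnextv2_original":
                stages.append(OriginalConvNeXtV2Block(bcfg, rng=rng))
            else:
                stages.append(ResidualBlock(bcfg, rng=rng))
        self.stages = nn.ModuleList(stages)

        if cfg.attention == "dwam_eff":
            dwam_cfg = cfg.dwam
            if dwam_cfg.channels != c:
                raise ValueError(
                    f"attention channels ({dwam_cfg.channels}) must match "
                    f"trunk channels ({c})")
            self.attention = AttentionStage(dwam_cfg, cfg.eag_mid_channels, rng=rng)
        else:
            self.attention = None

        self.head = nn.Conv2d(c, 1, cfg.head_kernel, rng=rng)

    def forward(self, x: Tensor, *, logits: bool = False) -> Tensor:
        """(N, 1, H, W) in [0, 1] (or standardised) -> (N, 1, H, W) map."""
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite values in network input")
        y = ag.relu(self.stem_norm(self.stem_conv(x)))
        for i, stage in enumerate(self.stages):
            y = stage(y)
            if not np.all(np.isfinite(y.data)):
                raise FloatingPointError(f"non-finite activations after stage {i}")
        if self.attention is not None:
            y = self.attention(y)
        y = self.head(y)
        return y if logits else ag.sigmoid(y)

    # -- reporting / persistence ------------------------------------------
    def param_report(self) -> ParamReport:
        return count_parameters(self)

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + buffers + config."""
        path = Path(path)
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"]).decode()))
            state = {k: data[k] for k in data.files if k != "__config__"}
        model = cls(cfg)
        model.load_state_dict(state)
        return model


def build_model(cfg: ModelConfig) -> SegmentationNet:
    return SegmentationNet(cfg)


def _variant_configs() -> dict[str, ModelConfig]:
    registry: dict[str, ModelConfig] = {
        "frnet_v2": ModelConfig(),
        "backbone_recursive": ModelConfig(
            attention="none", block_kind="convnextv2_3x3_recursive"),
        "backbone_3x3": ModelConfig(
            attention="none", block_kind="convnextv2_3x3", recursion_R=1),
        "backbone_original_block": ModelConfig(
            attention="none", block_kind="convnextv2_original", recursion_R=1),
        "backbone_residual": ModelConfig(
            attention="none", block_kind="residual", recursion_R=1),
    }
    for k in range(2, 7):
        registry[f"layers_{k}"] = ModelConfig(num_stages=k)
    return registry


VARIANT_NAMES: tuple[str, ...] = tuple(_variant_configs())


def variant_config(name: str) -> ModelConfig:
    registry = _variant_configs()
    if name not in registry:
        raise KeyError(
            f"unknown variant {name!r}; known variants: {sorted(registry)}")
    return registry[name]


def build_variant(name: str) -> SegmentationNet:
    return build_model(variant_config(name))
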