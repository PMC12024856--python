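"""Hybrid channel/spatial attention (DWAM) and the fusion stage (EFF).

DWAM consumes the trunk output through three parallel depthwise-separable
branches at different receptive fields (3x3, 5x5, dilated 3x3), then

* a **channel self-attention block** pools the two large-field branches to a
  per-channel descriptor, passes it through a fully connected layer with
  batch norm + ReLU, and emits two sigmoid channel maps ``a`` / ``a'`` that
  recalibrate the dilated and the 5x5 branch respectively;
* a **spatial self-attention block** lifts the 3x3 branch and the
  channel-weighted sum to a wider embedding, derives two single-channel
  sigmoid maps ``beta`` / ``beta'`` from their ReLU-fused sum and
  cross-calibrates the two embeddings before a final convolution projects
  back to the trunk width.

The EFF stage fuses the attention output with the trunk skip through an
additive attention gate (EAG), an efficient channel-attention gate (ECA,
a 3-tap 1-D convolution over the pooled channel descriptor) and a 7x7
spatial-attention gate (SA) over the channel mean/max maps.

The hidden widths (``fc_hidden``, ``spatial_mid_channels``,
``eag_mid_channels``) are the sizing knobs of the whole attention stage; the
defaults are calibrated so that DWAM + EFF add ~0.07 M parameters on top of
the 0.12 M backbone.  The budget sits in the channel-attention MLP on
purpose: widening layers that act on pooled C-vectors costs almost no
arithmetic, whereas widening the spatial embeddings would multiply the
activation volume of every forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from . import nn
from .blocks import DepthwiseSeparableConv, RecursiveConv


@dataclass
class DwamConfig:
    channels: int = 32
    dilation: int = 3
    recursion_R: int = 2
    fc_hidden: int | None = 576           # None -> channels
    spatial_mid_channels: int = 64
    final_kernel: int = 1
    combine: str = "add"                  # pooling combiner: {"add", "concat"}

    def __post_init__(self):
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        if self.combine not in ("add", "concat"):
            raise ValueError(f"unknown combine mode: {self.combine!r}")

    @property
    def hidden(self) -> int:
        return self.channels if self.fc_hidden is None else self.fc_hidden


@dataclass
class AttentionState:
    """Intermediates of one DWAM pass (numpy copies, for inspection)."""

    FG: np.ndarray | None = None          # pooled channel descriptor (N, C)
    F_fG: np.ndarray | None = None        # post-FC descriptor (N, hidden)
    a: np.ndarray | None = None           # channel gate for the dilated branch
    a_prime: np.ndarray | None = None     # channel gate for the 5x5 branch
    beta: np.ndarray | None = None        # spatial gate (N, 1, H, W)
    beta_prime: np.ndarray | None = None


class MultiScaleBranches(nn.Module):
    """Three parallel depthwise-separable branches: 3x3, 5x5, dilated 3x3.

    The 3x3 and 5x5 branches are recursive (weight shared across R
    iterations); each branch ends in batch norm + ReLU and preserves CxHxW.
    """

    def __init__(self, cfg: DwamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, r = cfg.channels, cfg.recursion_R
        self.cfg = cfg
        self.conv3 = RecursiveConv(DepthwiseSeparableConv(c, c, 3, rng=rng), r)
        self.bn3 = nn.BatchNorm2d(c)
        self.conv5 = RecursiveConv(DepthwiseSeparableConv(c, c, 5, rng=rng), r)
        self.bn5 = nn.BatchNorm2d(c)
        self.convd = DepthwiseSeparableConv(c, c, 3, dilation=cfg.dilation, rng=rng)
        self.bnd = nn.BatchNorm2d(c)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        f3 = ag.relu(self.bn3(self.conv3(x)))
        f5 = ag.relu(self.bn5(self.conv5(x)))
        fd = ag.relu(self.bnd(self.convd(x)))
        return f3, f5, fd


class ChannelSelfAttention(nn.Module):
    """Two sigmoid channel gates from the pooled 5x5/dilated descriptors."""

    def __init__(self, cfg: DwamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        in_features = cfg.channels * (2 if cfg.combine == "concat" else 1)
        self.fc = nn.Linear(in_features, cfg.hidden, rng=rng)
        self.bn = nn.BatchNorm1d(cfg.hidden)
        self.head_a = nn.Linear(cfg.hidden, cfg.channels, rng=rng)
        self.head_a_prime = nn.Linear(cfg.hidden, cfg.channels, rng=rng)

    def forward(self, f5: Tensor, fd: Tensor
                ) -> tuple[Tensor, Tensor, Tensor, AttentionState]:
        if f5.shape != fd.shape:
            raise ValueError(f"branch shape mismatch: {f5.shape} vs {fd.shape}")
        if self.cfg.combine == "add":
            pooled_src = f5 + fd
            fg = nn.global_avg_pool(pooled_src)
        else:
            fg = ag.concat([nn.global_avg_pool(f5), nn.global_avg_pool(fd)], axis=1)
        ffg = ag.relu(self.bn(self.fc(fg)))
        a = ag.sigmoid(self.head_a(ffg))
        a_prime = ag.sigmoid(self.head_a_prime(ffg))
        n, c = a.shape
        f_cd = a.reshape((n, c, 1, 1)) * fd
        f_c5 = a_prime.reshape((n, c, 1, 1)) * f5
        f_c = f_cd + f_c5
        state = AttentionState(FG=fg.data.copy(), F_fG=ffg.data.copy(),
                               a=a.data.copy(), a_prime=a_prime.data.copy())
        return f_cd, f_c5, f_c, state


class SpatialSelfAttention(nn.Module):
    """Cross-calibration of the 3x3 branch and the channel-weighted sum."""

    def __init__(self, cfg: DwamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, m = cfg.channels, cfg.spatial_mid_channels
        self.cfg = cfg
        self.embed_s = nn.Conv2d(c, m, 1, rng=rng)
        self.bn_s = nn.BatchNorm2d(m)
        self.embed_c = nn.Conv2d(c, m, 1, rng=rng)
        self.bn_c = nn.BatchNorm2d(m)
        self.beta_conv = nn.Conv2d(m, 1, 1, rng=rng)
        self.beta_bn = nn.BatchNorm2d(1)
        self.beta_prime_conv = nn.Conv2d(m, 1, 1, rng=rng)
        self.beta_prime_bn = nn.BatchNorm2d(1)
        self.final = nn.Conv2d(m, c, cfg.final_kernel, rng=rng)
        self.force_identity_gates = False   # diagnostic: replace gates by 1

    def forward(self, f3: Tensor, f_c: Tensor,
                state: AttentionState | None = None) -> Tensor:
        if f3.shape != f_c.shape:
            raise ValueError(f"shape mismatch: {f3.shape} vs {f_c.shape}")
        f_s1 = ag.relu(self.bn_s(self.embed_s(f3)))
        f_cs1 = ag.relu(self.bn_c(self.embed_c(f_c)))
        s = ag.relu(f_s1 + f_cs1)
        beta = ag.sigmoid(ag.relu(self.beta_bn(self.beta_conv(s))))
        beta_prime = ag.sigmoid(ag.relu(self.beta_prime_bn(self.beta_prime_conv(s))))
        if self.force_identity_gates:
            beta = Tensor(np.ones_like(beta.data))
            beta_prime = Tensor(np.ones_like(beta_prime.data))
        if state is not None:
            state.beta = beta.data.copy()
            state.beta_prime = beta_prime.data.copy()
        f_cs1_cal = beta * f_cs1          # single-channel gates broadcast over C
        f_s1_cal = beta_prime * f_s1
        return self.final(f_cs1_cal + f_s1_cal)


class DWAM(nn.Module):
    """Multi-scale branches -> channel self-attention -> spatial self-attention."""

    def __init__(self, cfg: DwamConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or DwamConfig()
        self.branches = MultiScaleBranches(self.cfg, rng=rng)
        self.channel_att = ChannelSelfAttention(self.cfg, rng=rng)
        self.spatial_att = SpatialSelfAttention(self.cfg, rng=rng)
        self.last_state: AttentionState | None = None

    def forward(self, x: Tensor) -> Tensor:
        f3, f5, fd = self.branches(x)
        _, _, f_c, state = self.channel_att(f5, fd)
        out = self.spatial_att(f3, f_c, state)
        self.last_state = state
        return out


class EffFusion(nn.Module):
    """Fuse the attention output with the trunk skip under three gates.

    ``fused = x_att + EAG(x_att, x_skip) * x_skip`` followed by the ECA
    channel gate and the SA spatial gate.  With every gate forced to one the
    stage degenerates to the plain sum ``x_att + x_skip``.
    """

    def __init__(self, channels: int = 32, eag_mid_channels: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c, g = channels, eag_mid_channels
        self.channels = c
        # EAG: additive attention gate
        self.gate_att = nn.Conv2d(c, g, 1, rng=rng)
        self.gate_att_bn = nn.BatchNorm2d(g)
        self.gate_skip = nn.Conv2d(c, g, 1, rng=rng)
        self.gate_skip_bn = nn.BatchNorm2d(g)
        self.psi = nn.Conv2d(g, 1, 1, rng=rng)
        self.psi_bn = nn.BatchNorm2d(1)
        # ECA: 3-tap 1-D conv over the pooled channel descriptor, no bias
        rng_ = rng if rng is not None else np.random.default_rng(0)
        self.eca_weight = nn.Parameter(nn.kaiming_uniform(rng_, (3,), 3))
        # SA: 7x7 conv over [channel-mean, channel-max]
        self.sa_conv = nn.Conv2d(2, 1, 7, rng=rng)
        self.force_identity_gates = False   # diagnostic: replace gates by 1

    def _eag_gate(self, x_att: Tensor, x_skip: Tensor) -> Tensor:
        s = ag.relu(self.gate_att_bn(self.gate_att(x_att))
                    + self.gate_skip_bn(self.gate_skip(x_skip)))
        return ag.sigmoid(self.psi_bn(self.psi(s)))

    def _eca_gate(self, x: Tensor) -> Tensor:
        g = nn.global_avg_pool(x)                       # (N, C)
        n, c = g.shape
        zeros = Tensor(np.zeros((n, 1), dtype=np.float32))
        left = ag.concat([zeros, ag.getitem(g, (slice(None), slice(0, c - 1)))], axis=1)
        right = ag.concat([ag.getitem(g, (slice(None), slice(1, None))), zeros], axis=1)
        w = self.eca_weight
        y = (ag.getitem(w, 0) * left + ag.getitem(w, 1) * g
             + ag.getitem(w, 2) * right)
        return ag.sigmoid(y).reshape((n, c, 1, 1))

    def _sa_gate(self, x: Tensor) -> Tensor:
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = ag.tmax(x, axis=1, keepdims=True)
        stacked = ag.concat([mean_map, max_map], axis=1)
        return ag.sigmoid(self.sa_conv(stacked))

    def forward(self, x_att: Tensor, x_skip: Tensor) -> Tensor:
        if x_att.shape != x_skip.shape:
            raise ValueError(f"shape mismatch: {x_att.shape} vs {x_skip.shape}")
        if self.force_identity_gates:
            return x_att + x_skip
        fused = x_att + self._eag_gate(x_att, x_skip) * x_skip
        fused = fused * self._eca_gate(fused)
        fused = fused * self._sa_gate(fused)
        return fused


class AttentionStage(nn.Module):
    """DWAM followed by EFF fusion with the trunk output as the skip path."""

    def __init__(self, cfg: DwamConfig | None = None, eag_mid_channels: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.dwam = DWAM(cfg, rng=rng)
        self.eff = EffFusion(self.dwam.cfg.channels, eag_mid_channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.eff(self.dwam(x), x)
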