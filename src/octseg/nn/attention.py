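"""Parameter-free energy attention (SimAM), pyramid squeeze attention (PSA),
and their tandem / parallel / nested combinations.

SimAM weighs every neuron by an inverse energy derived from its deviation
from the channel's spatial statistics:

    a = ((x - mu)^2 + 2*sigma^2 + 2*lambda) / (4 * (sigma^2 + lambda))
    out = x * sigmoid(a)

with mu, sigma^2 the per-channel spatial mean and population variance.  It
introduces no learnable parameters.

PSA splits the channels into S equal groups, runs each through a convolution
at its own kernel size, squeezes each branch into a channel descriptor via
global average pooling and a sigmoid-capped bottleneck, softmax-normalizes
the descriptors across branches, and rescales the branch features by them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np

from .autograd import Tensor, concat, softmax
from .layers import Conv2d, Linear, Module

_DEFAULT_KERNELS = (3, 5, 7, 9)
_DEFAULT_GROUPS = (1, 4, 8, 16)

__all__ = ["AttentionConfig", "SimAM", "PSA", "CombinedAttention",
           "build_attention", "psa_param_count"]


@dataclass
class AttentionConfig:
    """Configuration for the attention operators.

    mode: one of none / simam / psa / tandem / parallel / nested.
    simam_lambda: energy regularizer (>0) stabilising low-variance channels.
    psa_branches: number of multi-scale branches S.
    psa_kernel_sizes / psa_groups: per-branch conv kernel and group counts;
        default pyramid (3,5,7,9) with groups (1,4,8,16), truncated to S.
    se_reduction: bottleneck reduction of the squeeze descriptor.
    parallel_fusion: how the parallel topology merges branches (mean or sum).
    """

    mode: str = "none"
    simam_lambda: float = 1e-4
    psa_branches: int = 4
    psa_kernel_sizes: tuple = ()
    psa_groups: tuple = ()
    se_reduction: int = 4
    parallel_fusion: str = "mean"

    def __post_init__(self):
        if self.simam_lambda <= 0:
            raise ValueError("simam_lambda must be > 0")
        if self.mode not in ("none", "simam", "psa", "tandem", "parallel",
                             "nested"):
            raise ValueError(f"unknown attention mode {self.mode!r}")
        if self.parallel_fusion not in ("mean", "sum"):
            raise ValueError("parallel_fusion must be 'mean' or 'sum'")
        s = self.psa_branches
        if not self.psa_kernel_sizes:
            self.psa_kernel_sizes = _DEFAULT_KERNELS[:s]
        if not self.psa_groups:
            self.psa_groups = _DEFAULT_GROUPS[:s]
        self.psa_kernel_sizes = tuple(self.psa_kernel_sizes)
        self.psa_groups = tuple(self.psa_groups)
        if len(self.psa_kernel_sizes) != s or len(self.psa_groups) != s:
            raise ValueError("psa_kernel_sizes/psa_groups must have length S")
        if any(k % 2 == 0 for k in self.psa_kernel_sizes):
            raise ValueError("psa kernel sizes must be odd")


def simam_weights(x: np.ndarray, lam: float) -> np.ndarray:
    """Plain-NumPy SimAM weights for a (C,H,W) or (N,C,H,W) array."""
    arr = np.asarray(x, dtype=np.float64)
    mu = arr.mean(axis=(-2, -1), keepdims=True)
    var = ((arr - mu) ** 2).mean(axis=(-2, -1), keepdims=True)
    a = ((arr - mu) ** 2 + 2 * var + 2 * lam) / (4 * (var + lam))
    return 1.0 / (1.0 + np.exp(-a))


class SimAM(Module):
    """Energy-based per-neuron attention; zero learnable parameters."""

    def __init__(self, lam: float = 1e-4):
        super().__init__()
        if lam <= 0:
            raise ValueError("simam lambda must be > 0")
        self.lam = lam

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(-2, -1), keepdims=True)
        d = x - mu
        var = (d * d).mean(axis=(-2, -1), keepdims=True)
        a = (d * d + 2.0 * var + 2.0 * self.lam) / (4.0 * (var + self.lam))
        return x * a.sigmoid()


class _SqueezeExcite(Module):
    """GAP -> bottleneck -> sigmoid channel descriptor for one PSA branch."""

    def __init__(self, ch: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, ch // reduction)
        self.fc1 = Linear(ch, hidden, rng)
        self.fc2 = Linear(hidden, ch, rng)

    def forward(self, feat: Tensor) -> Tensor:
        z = feat.mean(axis=(-2, -1))          # (N, ch)
        return self.fc2(self.fc1(z).relu()).sigmoid()


def _effective_groups(requested: int, branch_ch: int) -> int:
    return gcd(requested, branch_ch)


class PSA(Module):
    """Pyramid squeeze attention over ``channels`` input channels."""

    def __init__(self, channels: int, cfg: AttentionConfig,
                 rng: np.random.Generator, nested_simam: bool = False):
        super().__init__()
        s = cfg.psa_branches
        if channels % s:
            raise ValueError(
                f"channel count C={channels} not divisible by S={s} branches"
            )
        self.branch_ch = channels // s
        self.cfg = cfg
        self.convs = [
            Conv2d(self.branch_ch, self.branch_ch, k, rng,
                   groups=_effective_groups(g, self.branch_ch))
            for k, g in zip(cfg.psa_kernel_sizes, cfg.psa_groups)
        ]
        self.se = [_SqueezeExcite(self.branch_ch, cfg.se_reduction, rng)
                   for _ in range(s)]
        self.inner = SimAM(cfg.simam_lambda) if nested_simam else None

    def forward(self, x: Tensor) -> Tensor:
        s = self.cfg.psa_branches
        bc = self.branch_ch
        feats = []
        for i in range(s):
            xi = x[:, i * bc:(i + 1) * bc]
            fi = self.convs[i](xi)
            if self.inner is not None:
                fi = self.inner(fi)
            feats.append(fi)
        descs = [se(f) for se, f in zip(self.se, feats)]   # each (N, bc)
        n = descs[0].shape[0]
        stackd = concat([d.reshape(n, 1, bc) for d in descs], axis=1)
        att = softmax(stackd, axis=1)                       # (N, S, bc)
        scaled = [feats[i] * att[:, i].reshape(n, bc, 1, 1) for i in range(s)]
        return concat(scaled, axis=1)

    def branch_softmax(self, x: Tensor) -> np.ndarray:
        """Softmax-normalized branch descriptors, shape (N, S, branch_ch)."""
        s, bc = self.cfg.psa_branches, self.branch_ch
        feats = []
        for i in range(s):
            fi = self.convs[i](x[:, i * bc:(i + 1) * bc])
            if self.inner is not None:
                fi = self.inner(fi)
            feats.append(fi)
        descs = [se(f) for se, f in zip(self.se, feats)]
        n = descs[0].shape[0]
        stackd = concat([d.reshape(n, 1, bc) for d in descs], axis=1)
        return softmax(stackd, axis=1).data


def psa_param_count(channels: int, cfg: AttentionConfig) -> int:
    """Closed-form learnable-parameter count of one PSA block."""
    s = cfg.psa_branches
    bc = channels // s
    total = 0
    for k, g in zip(cfg.psa_kernel_sizes, cfg.psa_groups):
        eg = _effective_groups(g, bc)
        total += k * k * (bc // eg) * bc + bc          # conv weight + bias
    hidden = max(1, bc // cfg.se_reduction)
    total += s * (bc * hidden + hidden + hidden * bc + bc)  # two FC layers
    return total


class CombinedAttention(Module):
    """tandem: psa(simam(x)); parallel: fuse(simam(x), psa(x));
    nested: psa with simam applied to each branch's conv features."""

    def __init__(self, channels: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        if cfg.mode not in ("tandem", "parallel", "nested"):
            raise ValueError(f"combine() needs a combined mode, got {cfg.mode!r}")
        self.cfg = cfg
        self.simam = SimAM(cfg.simam_lambda) if cfg.mode != "nested" else None
        self.psa = PSA(channels, cfg, rng, nested_simam=(cfg.mode == "nested"))

    def forward(self, x: Tensor) -> Tensor:
        mode = self.cfg.mode
        if mode == "tandem":
            return self.psa(self.simam(x))
        if mode == "parallel":
            a, b = self.simam(x), self.psa(x)
            out = a + b
            return out * 0.5 if self.cfg.parallel_fusion == "mean" else out
        return self.psa(x)  # nested


def build_attention(channels: int, cfg: AttentionConfig,
                    rng: np.random.Generator) -> Module | None:
    """Instantiate the attention block the config asks for (None = identity)."""
    if cfg.mode == "none":
        return None
    if cfg.mode == "simam":
        return SimAM(cfg.simam_lambda)
    if cfg.mode == "psa":
        return PSA(channels, cfg, rng)
    return CombinedAttention(channels, cfg, rng)
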