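"""UNet backbone with optional combined attention in the decoder.

The encoder applies a double 3x3 conv (each followed by batch norm and ReLU)
and a 2x2 max pool per level; the decoder upsamples with a 2x2 transposed
convolution, concatenates the skip connection, applies a double conv, and —
for the attention variants — passes the stage output through the configured
attention block.  A 1x1 convolution maps the top-level features to class
logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionConfig, build_attention, psa_param_count
from .autograd import Tensor, concat, maxpool2x2
from .layers import (BatchNorm2d, Conv2d, ConvTranspose2x2, Module, ReLU,
                     Sequential)

__all__ = ["ModelConfig", "UNet", "build_model", "unet_param_count",
           "VARIANTS"]

#: variant name -> attention mode
VARIANTS = {"unet": "none", "tandem": "tandem", "parallel": "parallel",
            "nested": "nested"}


@dataclass
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 2
    base_width: int = 64
    depth: int = 5
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    attention_levels: tuple | None = None  # decoder levels, None = all

    def widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(self.depth)]

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        cfg = self.attention
        if cfg.mode in ("psa", "tandem", "parallel", "nested"):
            for lvl in self._active_levels():
                w = self.widths()[lvl]
                s = cfg.psa_branches
                if w % s:
                    raise ValueError(
                        f"decoder level {lvl}: C={w} not divisible by "
                        f"S={s} PSA branches"
                    )

    def _active_levels(self) -> list[int]:
        # decoder levels indexed by their output width exponent (0 = top)
        levels = list(range(self.depth - 1))
        if self.attention_levels is not None:
            levels = [l for l in levels if l in set(self.attention_levels)]
        return levels


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.block = Sequential(
            Conv2d(cin, cout, 3, rng), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, rng), BatchNorm2d(cout), ReLU(),
        )

    def forward(self, x):
        return self.block(x)


class UNet(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.widths()
        self.enc = [_DoubleConv(cfg.in_channels if i == 0 else w[i - 1], w[i],
                                rng)
                    for i in range(cfg.depth)]
        self.ups = []
        self.dec = []
        self.att = []
        active = set(cfg._active_levels())
        for lvl in reversed(range(cfg.depth - 1)):  # deepest decoder first
            self.ups.append(ConvTranspose2x2(w[lvl + 1], w[lvl], rng))
            self.dec.append(_DoubleConv(2 * w[lvl], w[lvl], rng))
            blk = (build_attention(w[lvl], cfg.attention, rng)
                   if lvl in active else None)
            self.att.append(blk if blk is not None else _Identity())
        self.head = Conv2d(w[0], cfg.num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w_ = x.shape[-2:]
        f = 2 ** (self.cfg.depth - 1)
        if h % f or w_ % f:
            raise ValueError(
                f"input {h}x{w_} not divisible by 2^(depth-1)={f}; "
                "run preprocess_geometry first"
            )
        skips = []
        for i, enc in enumerate(self.enc):
            x = enc(x)
            if i < self.cfg.depth - 1:
                skips.append(x)
                x = maxpool2x2(x)
        for up, dec, att, skip in zip(self.ups, self.dec, self.att,
                                      reversed(skips)):
            x = up(x)
            x = dec(concat([skip, x], axis=1))
            x = att(x)
        return self.head(x)


class _Identity(Module):
    def forward(self, x):
        return x


def build_model(cfg: ModelConfig, seed: int = 0) -> UNet:
    """Construct a segmenter; identical seed + config -> identical weights."""
    return UNet(cfg, seed=seed)


def _double_conv_count(cin: int, cout: int) -> int:
    return (9 * cin * cout + cout + 2 * cout) + (9 * cout * cout + cout
                                                 + 2 * cout)


def unet_param_count(cfg: ModelConfig) -> int:
    """Closed-form learnable-parameter count of the configured model."""
    w = cfg.widths()
    total = _double_conv_count(cfg.in_channels, w[0])
    for i in range(1, cfg.depth):
        total += _double_conv_count(w[i - 1], w[i])
    for lvl in range(cfg.depth - 1):
        total += 4 * w[lvl + 1] * w[lvl] + w[lvl]        # 2x2 transposed conv
        total += _double_conv_count(2 * w[lvl], w[lvl])
    total += w[0] * cfg.num_classes + cfg.num_classes    # 1x1 head
    mode = cfg.attention.mode
    if mode in ("psa", "tandem", "parallel", "nested"):
        for lvl in cfg._active_levels():
            total += psa_param_count(w[lvl], cfg.attention)
    # simam-only variant adds zero parameters
    return total
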