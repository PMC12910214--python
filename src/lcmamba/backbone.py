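"""Hierarchical Mamba-style encoder.

A stem of stacked 3x3 strided convolutions embeds the input slice at 1/4
resolution; four stages of SS2D blocks follow, each later stage preceded by
a 2x2 stride-2 transition that halves the grid and doubles the channel
width, so the deepest feature map sits at 1/32 of the input.  Two sized
variants are provided (T = tiny, S = small, the latter with deeper stage 3
and one extra SS2D block appended to stage 4), plus a "nano" preset small
enough to train on a CPU in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .ssm_core import SSMBlock, InputError

logger = logging.getLogger("lcmamba")

STEM_STRIDE = 4
DIVISIBILITY = 32


@dataclass(frozen=True)
class StageSpec:
    depth: int
    channels: int
    stride: int  # cumulative downsampling vs the input


@dataclass(frozen=True)
class VariantConfig:
    name: str
    channels: tuple[int, ...]
    depths: tuple[int, ...]
    extra_ssm_blocks: int
    state_dim: int
    decoder_dim: int

    def __post_init__(self):
        if len(self.channels) != 4 or len(self.depths) != 4:
            raise ValueError("exactly four stages are required")
        if any(c2 <= c1 for c1, c2 in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must strictly increase per stage")
        if self.extra_ssm_blocks < 0:
            raise ValueError("extra_ssm_blocks must be >= 0")

    @property
    def stage_specs(self) -> list[StageSpec]:
        return [
            StageSpec(d, c, STEM_STRIDE * 2**i)
            for i, (d, c) in enumerate(zip(self.depths, self.channels))
        ]


VARIANTS: dict[str, VariantConfig] = {
    "T": VariantConfig("T", (96, 192, 384, 768), (2, 2, 4, 2), 0, 16, 64),
    "S": VariantConfig("S", (96, 192, 384, 768), (2, 2, 8, 2), 1, 16, 64),
    "nano": VariantConfig("nano", (8, 16, 32, 64), (1, 1, 2, 1), 0, 4, 16),
}


def get_variant(name: str) -> VariantConfig:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")


def complexity_estimate(H: int, W: int, C: int, N: int) -> int:
    """Dominant-term operation count H*W*C^2*N (linear in pixel count)."""
    if min(H, W, C, N) <= 0:
        raise InputError("all dimensions must be positive")
    return H * W * C * C * N


class Stem(nn.Module):
    """Two stacked 3x3 stride-2 convolutions: a stride-4 patch embedding."""

    def __init__(self, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(3, c_out // 2, 3, stride=2, rng=rng)
        self.conv2 = nn.Conv2d(c_out // 2, c_out, 3, stride=2, rng=rng)
        self.norm = nn.LayerNorm(c_out, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv2(nn.relu(self.conv1(x))))

    def profile(self, input_shape):
        s1, m1 = self.conv1.profile(input_shape)
        s2, m2 = self.conv2.profile(s1)
        return s2, m1 + m2


class Encoder(nn.Module):
    """Four-stage SS2D encoder producing feature maps f1..f4."""

    def __init__(self, cfg: VariantConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stem = Stem(cfg.channels[0], rng)
        self.stages: list[list[SSMBlock]] = []
        self.transitions: list[nn.Conv2d | None] = []
        for i, spec in enumerate(cfg.stage_specs):
            if i == 0:
                trans = None
            else:
                trans = nn.Conv2d(cfg.channels[i - 1], spec.channels, 2, stride=2,
                                  pad=0, rng=rng)
                setattr(self, f"transition{i}", trans)
            self.transitions.append(trans)
            depth = spec.depth + (cfg.extra_ssm_blocks if i == 3 else 0)
            blocks = []
            for j in range(depth):
                blk = SSMBlock(spec.channels, state_dim=cfg.state_dim, rng=rng)
                setattr(self, f"stage{i}_block{j}", blk)
                blocks.append(blk)
            self.stages.append(blocks)

    @staticmethod
    def _check_input(shape) -> None:
        B, C, H, W = shape
        if C != 3:
            raise InputError(f"expected a 3-channel input, got {C} channels")
        if H % DIVISIBILITY or W % DIVISIBILITY:
            raise InputError(
                f"input height and width must be multiples of {DIVISIBILITY}, got {H}x{W}"
            )

    def __call__(self, x: Tensor) -> list[Tensor]:
        self._check_input(x.shape)
        f = self.stem(x)
        features = []
        for blocks, trans in zip(self.stages, self.transitions):
            if trans is not None:
                f = trans(f)
            for blk in blocks:
                f = blk(f)
            features.append(f)
        return features

    def profile(self, input_shape):
        """Shape-propagated (feature_shapes, total_macs)."""
        self._check_input(input_shape)
        shape, macs = self.stem.profile(input_shape)
        feature_shapes = []
        for blocks, trans in zip(self.stages, self.transitions):
            if trans is not None:
                shape, m = trans.profile(shape)
                macs += m
            for blk in blocks:
                shape, m = blk.profile(shape)
                macs += m
            feature_shapes.append(shape)
        return feature_shapes, macs


def load_pretrained_encoder(encoder: Encoder, state: dict[str, np.ndarray]) -> list[str]:
    """Best-effort weight loading hook: copies arrays whose names and shapes
    match, logs and returns the names that were skipped."""
    skipped = encoder.load_state_dict(state, strict=False)
    if skipped:
        logger.info("pretrained load skipped %d parameter(s): %s",
                    len(skipped), ", ".join(skipped[:8]))
    return skipped
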