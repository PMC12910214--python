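"""Liver Cancer Attention Module (LCAM) and the coarse-to-fine decoder.

The decoder starts from a coarse probability map read off the deepest
encoder feature, then walks back up the pyramid.  At each level a
reverse-attention map

    Theta(P) = 1 - P + gamma * |grad P|

is built from the (upsampled) coarser prediction: regions the model is
already confident about (P near 1) are suppressed, while uncertain regions
and boundaries (where |grad P| is large) are emphasised.  The attention
modulates a transformed encoder feature, R_i = Theta(P) * delta(f_i), a
1x1 head reads a residual logit p_i from R_i, and the refined prediction is

    P_i = sigma(p_i + logit(P_{i+1} upsampled)),

i.e. the coarser prior passes through unchanged when the head is silent.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import DTYPE, Tensor
from .ssm_core import InputError, ConfigurationError

LOGIT_EPS = 1e-4


# ---------------------------------------------------------------------------
# Functional attention map (numpy, oracle-friendly)
# ---------------------------------------------------------------------------

def gradient_magnitude(P: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with edge replication.

    Accepts 1-D (|dP/dx|) or 2-D arrays (sqrt(dx^2 + dy^2))."""
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        Pp = np.pad(P, 1, mode="edge")
        return np.abs((Pp[2:] - Pp[:-2]) * 0.5)
    if P.ndim == 2:
        Pp = np.pad(P, 1, mode="edge")
        dx = (Pp[1:-1, 2:] - Pp[1:-1, :-2]) * 0.5
        dy = (Pp[2:, 1:-1] - Pp[:-2, 1:-1]) * 0.5
        return np.sqrt(dx * dx + dy * dy)
    raise InputError("gradient_magnitude expects a 1-D or 2-D array")


def attention_map(P: np.ndarray, gamma: float) -> np.ndarray:
    """Reverse attention Theta(P) = 1 - P + gamma * |grad P|."""
    P = np.asarray(P, dtype=float)
    if gamma < 0:
        raise InputError("gamma must be >= 0")
    if P.min() < 0 or P.max() > 1:
        raise InputError("P must be a probability map in [0, 1]")
    return 1.0 - P + gamma * gradient_magnitude(P)


# ---------------------------------------------------------------------------
# Autodiff building blocks
# ---------------------------------------------------------------------------

def pad_replicate1(x: Tensor) -> Tensor:
    """Replicate-pad an NCHW tensor by one pixel on each spatial side."""
    data = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")

    def bwd(out):
        def run():
            if not x.requires_grad:
                return
            g = out.grad
            gi = g[:, :, 1:-1, 1:-1].copy()
            gi[:, :, 0, :] += g[:, :, 0, 1:-1]
            gi[:, :, -1, :] += g[:, :, -1, 1:-1]
            gi[:, :, :, 0] += g[:, :, 1:-1, 0]
            gi[:, :, :, -1] += g[:, :, 1:-1, -1]
            gi[:, :, 0, 0] += g[:, :, 0, 0]
            gi[:, :, 0, -1] += g[:, :, 0, -1]
            gi[:, :, -1, 0] += g[:, :, -1, 0]
            gi[:, :, -1, -1] += g[:, :, -1, -1]
            x._accumulate(gi)
        return run

    return nn._make(data, (x,), bwd)


_KX = np.zeros((1, 1, 3, 3), dtype=DTYPE)
_KX[0, 0, 1, 0], _KX[0, 0, 1, 2] = -0.5, 0.5
_KY = np.zeros((1, 1, 3, 3), dtype=DTYPE)
_KY[0, 0, 0, 1], _KY[0, 0, 2, 1] = -0.5, 0.5


def grad_magnitude_t(P: Tensor) -> Tensor:
    """Differentiable gradient magnitude of a single-channel NCHW map."""
    Pp = pad_replicate1(P)
    kx = nn.Tensor(_KX)
    ky = nn.Tensor(_KY)
    dx = nn.conv2d(Pp, kx, None, stride=1, pad=0)
    dy = nn.conv2d(Pp, ky, None, stride=1, pad=0)
    return nn.power(nn.add(nn.add(nn.mul(dx, dx), nn.mul(dy, dy)), 1e-12), 0.5)


def attention_map_t(P: Tensor, gamma: float) -> Tensor:
    return nn.add(nn.add(1.0, nn.mul(P, -1.0)), nn.mul(grad_magnitude_t(P), gamma))


def logit_t(P: Tensor) -> Tensor:
    Pc = nn.clip(P, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return nn.add(nn.log(Pc), nn.mul(nn.log(nn.add(1.0, nn.mul(Pc, -1.0))), -1.0))


# ---------------------------------------------------------------------------
# LCAM refinement level
# ---------------------------------------------------------------------------

class LCAMBlock(nn.Module):
    """One refinement level: attention, feature modulation, residual head.

    ``up_factor`` is 2 for ordinary levels (the coarser prediction lives on a
    grid half the size of f_i); the deepest level uses 1 because the initial
    coarse prediction shares f4's grid.
    """

    def __init__(self, c_in: int, c_mid: int, gamma: float, up_factor: int,
                 rng: np.random.Generator, use_attention: bool = True):
        super().__init__()
        self.gamma = float(gamma)
        self.up_factor = up_factor
        self.use_attention = use_attention
        self.delta_conv = nn.Conv2d(c_in, c_mid, 3, rng=rng)
        self.delta_bn = nn.BatchNorm2d(c_mid)
        self.head = nn.Conv2d(c_mid, 1, 1, pad=0, rng=rng)

    def __call__(self, f: Tensor, P_next: Tensor) -> tuple[Tensor, Tensor]:
        B, C, H, W = f.shape
        ph, pw = P_next.shape[2], P_next.shape[3]
        if (ph * self.up_factor, pw * self.up_factor) != (H, W):
            raise ConfigurationError(
                f"prior grid {ph}x{pw} (x{self.up_factor}) does not match feature "
                f"grid {H}x{W}"
            )
        P_up = P_next if self.up_factor == 1 else nn.resize_bilinear(P_next, (H, W))
        feat = nn.relu(self.delta_bn(self.delta_conv(f)))
        if self.use_attention:
            A = attention_map_t(P_up, self.gamma)                # (B,1,H,W)
            R = nn.mul(A, feat)
        else:  # ablation: attention identically 1
            R = feat
        p = self.head(R)                                         # logit
        P = nn.sigmoid(nn.add(p, logit_t(P_up)))
        return R, P

    def profile(self, input_shape):
        s, m1 = self.delta_conv.profile(input_shape)
        _, m2 = self.head.profile(s)
        return s, m1 + m2


class Decoder(nn.Module):
    """Coarse-to-fine cascade over encoder features f1..f4.

    Produces the prediction pyramid [P5, P4, P3, P2, P1] (coarsest first;
    P5 and P4 share f4's grid) and the full-resolution probability map.
    """

    def __init__(self, channels: tuple[int, ...], decoder_dim: int,
                 gamma: float = 0.5, seed: int = 0, use_attention: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed + 101)
        self.gamma = gamma
        self.coarse_head = nn.Conv2d(channels[3], 1, 1, pad=0, rng=rng)
        self.levels: list[LCAMBlock] = []
        # levels processed 4 -> 1 (channels reversed)
        for idx, c in enumerate(reversed(channels)):
            blk = LCAMBlock(c, decoder_dim, gamma, up_factor=1 if idx == 0 else 2,
                            rng=rng, use_attention=use_attention)
            setattr(self, f"level{4 - idx}", blk)
            self.levels.append(blk)

    def __call__(self, features: list[Tensor], out_hw: tuple[int, int]):
        if len(features) != 4:
            raise ConfigurationError(f"expected 4 feature maps, got {len(features)}")
        f4 = features[3]
        P = nn.sigmoid(self.coarse_head(f4))
        pyramid = [P]
        for blk, f in zip(self.levels, reversed(features)):
            _, P = blk(f, P)
            pyramid.append(P)
        full = nn.resize_bilinear(P, out_hw)
        return full, pyramid

    def profile(self, feature_shapes):
        _, macs = self.coarse_head.profile(feature_shapes[3])
        for blk, s in zip(self.levels, reversed(feature_shapes)):
            _, m = blk.profile(s)
            macs += m
        return macs
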