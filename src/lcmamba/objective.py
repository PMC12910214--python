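"""Composite segmentation objective.

The training loss is a weighted sum of three terms,

    L = alpha * L_BCE + beta * L_Dice + lambda * L_Boundary,

where L_BCE is pixelwise binary cross-entropy, L_Dice = 1 - soft Dice with
an epsilon-smoothed ratio, and the boundary term evaluates the same
smoothed Dice complement restricted to a narrow band B around the
ground-truth lesion contour:

    L_Boundary = 1 - (2 sum_B y*yhat + eps) / (sum_B y + sum_B yhat + eps).

B is extracted from the ground-truth mask only: the mask XOR its one-pixel
morphological erosion (the inner rim), dilated by one pixel, giving a band
roughly three pixels wide straddling the contour.  The combination of
area-level (Dice) and contour-level (boundary) terms counteracts the
extreme foreground/background imbalance of lesion masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor

_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected structuring element
BCE_CLAMP = 1e-7


class ParameterError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0     # BCE weight
    beta: float = 1.0      # Dice weight
    lam: float = 0.5       # boundary weight
    epsilon: float = 1e-6  # smoothing constant

    def __post_init__(self):
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ParameterError("loss weights must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ParameterError("alpha + beta must be positive")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


def _check_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise InputError("mask must be binary (values 0/1)")
    return m.astype(bool)


def boundary_set(mask: np.ndarray) -> np.ndarray:
    """Boolean band around the ground-truth contour (empty mask -> empty set).

    A batch of masks (B, H, W) is processed slice by slice."""
    m = _check_binary(mask)
    if m.ndim > 2:
        return np.stack([boundary_set(s.astype(int)) for s in m])
    if not m.any():
        return np.zeros_like(m)
    rim = m ^ ndimage.binary_erosion(m, structure=_STRUCT)
    return ndimage.binary_dilation(rim, structure=_STRUCT)


def boundary_loss(y: np.ndarray, y_hat: np.ndarray, B: np.ndarray,
                  eps: float = 1e-6) -> float:
    """Smoothed Dice complement restricted to the boundary band B."""
    if eps <= 0:
        raise ParameterError("eps must be positive")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    B = np.asarray(B, dtype=bool)
    if y.shape != y_hat.shape or y.shape != B.shape:
        raise InputError("y, y_hat and B must share a shape")
    yb, pb = y[B], y_hat[B]
    num = 2.0 * float(np.sum(yb * pb)) + eps
    den = float(np.sum(yb)) + float(np.sum(pb)) + eps
    return 1.0 - num / den


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), BCE_CLAMP, 1.0 - BCE_CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def soft_dice(y: np.ndarray, y_hat: np.ndarray, eps: float = 1e-6) -> float:
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    return (2.0 * float(np.sum(y * p)) + eps) / (float(np.sum(y)) + float(np.sum(p)) + eps)


def total_loss(y: np.ndarray, y_hat: np.ndarray,
               w: LossWeights = LossWeights()) -> dict[str, float]:
    """Evaluate the composite loss on numpy arrays.

    Returns the components and their weighted total under keys
    ``bce``, ``dice``, ``boundary``, ``total``.
    """
    yb = _check_binary(y).astype(float)
    p = np.asarray(y_hat, dtype=float)
    if p.shape != yb.shape:
        raise InputError("prediction and target shapes differ")
    comps = {
        "bce": bce_loss(yb, p),
        "dice": 1.0 - soft_dice(yb, p, w.epsilon),
        "boundary": boundary_loss(yb, p, boundary_set(yb.astype(int)), w.epsilon),
    }
    comps["total"] = (w.alpha * comps["bce"] + w.beta * comps["dice"]
                      + w.lam * comps["boundary"])
    return comps


# ---------------------------------------------------------------------------
# Differentiable path used by training
# ---------------------------------------------------------------------------

def total_loss_t(y: np.ndarray, y_hat: Tensor, w: LossWeights,
                 B_mask: np.ndarray | None = None) -> Tensor:
    """Composite loss as a scalar Tensor; `y` and `B_mask` are constants.

    The boundary band is recomputed from the ground truth per call unless
    supplied (training precomputes it per sample)."""
    yf = np.asarray(y, dtype=np.float32)
    if B_mask is None:
        B_mask = boundary_set((yf > 0.5).astype(int))
    Bf = np.asarray(B_mask, dtype=np.float32)

    p = nn.clip(y_hat, BCE_CLAMP, 1.0 - BCE_CLAMP)
    one_m_p = nn.add(1.0, nn.mul(p, -1.0))
    bce = nn.mul(nn.tmean(nn.add(nn.mul(nn.log(p), yf),
                                 nn.mul(nn.log(one_m_p), 1.0 - yf))), -1.0)

    inter = nn.tsum(nn.mul(y_hat, yf))
    sums = nn.add(nn.tsum(y_hat), float(yf.sum()))
    dice = nn.add(1.0, nn.mul(nn.mul(nn.add(nn.mul(inter, 2.0), w.epsilon),
                                     nn.power(nn.add(sums, w.epsilon), -1.0)), -1.0))

    if Bf.any():
        inter_b = nn.tsum(nn.mul(nn.mul(y_hat, Bf), yf))
        sums_b = nn.add(nn.tsum(nn.mul(y_hat, Bf)), float((yf * Bf).sum()))
        bnd = nn.add(1.0, nn.mul(nn.mul(nn.add(nn.mul(inter_b, 2.0), w.epsilon),
                                        nn.power(nn.add(sums_b, w.epsilon), -1.0)), -1.0))
    else:
        bnd = Tensor(0.0)

    return nn.add(nn.add(nn.mul(bce, w.alpha), nn.mul(dice, w.beta)),
                  nn.mul(bnd, w.lam))
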