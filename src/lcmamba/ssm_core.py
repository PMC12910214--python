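"""Selective state-space primitives and the SS2D block.

A (diagonal) state-space layer turns an input sequence x_t into an output
y_t through the linear recurrence

    h_t = A_bar * h_{t-1} + B_bar * x_t,       y_t = C * h_t,

where the discrete-time parameters come from zero-order-hold discretisation
of a continuous system with diagonal state matrix A = diag(Lambda):

    A_bar = exp(Delta * Lambda),
    B_bar = (Delta*A)^-1 (exp(Delta*A) - I) * Delta * B
          = ((exp(Delta*Lambda) - 1) / Lambda) * B          (diagonal case).

"Selective" means Delta, B and C are functions of the input at each
position.  The 2-D variant (SS2D) serialises a feature map along four
directions (left-to-right, right-to-left, top-to-bottom, bottom-to-top),
scans each sequence independently, maps every result back onto the grid,
concatenates the four outputs along channels and projects back to the input
width.

This module has two layers of API:

* plain-numpy functional operations (:func:`discretize`,
  :func:`selective_scan`, :func:`serialize_directions`,
  :func:`ss2d_forward`) used for testing against brute-force oracles, and
* the trainable :class:`SS2DBlock` (pre-norm + residual + gate) built on
  :mod:`lcmamba.nn`, used by the encoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn import DTYPE, Tensor

DIRECTIONS = ("right", "left", "down", "up")

#: incremented once per recurrence step; used to verify linear-time scaling
SCAN_STEP_COUNTER = {"steps": 0}


class ParameterError(ValueError):
    """Invalid state-space parameters (non-positive step, non-finite rates)."""


class InputError(ValueError):
    """Invalid input data (empty sequence, bad shape)."""


class ConfigurationError(ValueError):
    """Mismatched dimensions between inputs and parameters."""


# ---------------------------------------------------------------------------
# Functional layer
# ---------------------------------------------------------------------------

@dataclass
class SSMParams:
    """Continuous-time parameters of a diagonal state-space system.

    lambda_diag : (N,) decay rates, the diagonal of A
    B_in        : (N, D) input map
    C_out       : (D_out, N) output map
    delta       : positive scalar step, or (L,) per-position steps
    """

    lambda_diag: np.ndarray
    B_in: np.ndarray
    C_out: np.ndarray
    delta: float | np.ndarray

    def __post_init__(self):
        self.lambda_diag = np.atleast_1d(np.asarray(self.lambda_diag, dtype=float))
        self.B_in = np.atleast_2d(np.asarray(self.B_in, dtype=float))
        self.C_out = np.atleast_2d(np.asarray(self.C_out, dtype=float))
        if not np.all(np.isfinite(self.lambda_diag)):
            raise ParameterError("lambda_diag must be finite")
        d = np.asarray(self.delta, dtype=float)
        if np.any(d <= 0):
            raise ParameterError("delta must be strictly positive")
        if self.B_in.shape[0] != self.lambda_diag.shape[0]:
            raise ConfigurationError("B_in rows must equal state dimension")
        if self.C_out.shape[1] != self.lambda_diag.shape[0]:
            raise ConfigurationError("C_out columns must equal state dimension")

    @property
    def state_dim(self) -> int:
        return self.lambda_diag.shape[0]

    @property
    def channel_dim(self) -> int:
        return self.B_in.shape[1]


@dataclass
class ScanSequence:
    """A serialised feature map: values[t] is the channel vector at step t."""

    values: np.ndarray  # (L, D)
    direction: str
    origin_shape: tuple[int, int]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        H, W = self.origin_shape
        if self.values.shape[0] != H * W:
            raise InputError(
                f"sequence length {self.values.shape[0]} != H*W = {H * W}"
            )
        if self.direction not in DIRECTIONS:
            raise InputError(f"direction must be one of {DIRECTIONS}")


def phi(z):
    """(exp(z) - 1)/z with a Taylor limit near zero (phi(0) = 1)."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-6
    safe = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z / 2.0 + z * z / 6.0, np.expm1(safe) / safe)


def discretize(params: SSMParams) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold discretisation of a diagonal system.

    Returns ``(A_bar, B_bar)`` where ``A_bar[k] = exp(delta * lambda_k)`` and
    ``B_bar[k, :] = phi(delta * lambda_k) * delta * B[k, :]`` — the diagonal
    specialisation of ``(dA)^-1 (exp(dA) - I) d B`` in which one factor of
    ``delta`` cancels, leaving ``((exp(d*l) - 1)/l) * B``.  When
    ``|delta*lambda| < 1e-6`` the series limit ``B_bar -> delta * B`` is used.

    With per-position steps (``delta`` of shape (L,)), A_bar is (L, N) and
    B_bar is (L, N, D).
    """
    lam = params.lambda_diag
    delta = np.asarray(params.delta, dtype=float)
    if delta.ndim == 0:
        z = delta * lam                           # (N,)
        A_bar = np.exp(z)
        B_bar = (phi(z) * delta)[:, None] * params.B_in
    else:
        z = delta[:, None] * lam[None, :]         # (L, N)
        A_bar = np.exp(z)
        B_bar = (phi(z) * delta[:, None])[:, :, None] * params.B_in[None, :, :]
    return A_bar, B_bar


def selective_scan(x_seq: ScanSequence, params: SSMParams) -> ScanSequence:
    """Run the linear recurrence along a serialised sequence.

    h_0 = 0;  h_t = A_bar h_{t-1} + B_bar x_t;  y_t = C h_t.  Runtime is
    linear in sequence length (one recurrence step per position).
    """
    x = x_seq.values
    if x.size == 0:
        raise InputError("empty sequence")
    if x.shape[1] != params.channel_dim:
        raise ConfigurationError(
            f"sequence channel dim {x.shape[1]} != params channel dim {params.channel_dim}"
        )
    A_bar, B_bar = discretize(params)
    L = x.shape[0]
    per_step = A_bar.ndim == 2
    h = np.zeros(params.state_dim, dtype=float)
    y = np.empty((L, params.C_out.shape[0]), dtype=float)
    for t in range(L):
        a = A_bar[t] if per_step else A_bar
        b = B_bar[t] if per_step else B_bar
        h = a * h + b @ x[t]
        y[t] = params.C_out @ h
        SCAN_STEP_COUNTER["steps"] += 1
    return ScanSequence(values=y, direction=x_seq.direction, origin_shape=x_seq.origin_shape)


def serialize_directions(fmap: np.ndarray) -> dict[str, ScanSequence]:
    """Serialise an (H, W, C) grid along the four scan directions.

    right = row-major order, left = its reversal, down = column-major order,
    up = its reversal.
    """
    fmap = np.asarray(fmap, dtype=float)
    if fmap.ndim == 2:
        fmap = fmap[:, :, None]
    H, W, C = fmap.shape
    if H < 1 or W < 1:
        raise InputError("empty grid")
    rm = fmap.reshape(H * W, C)                       # row-major
    cm = fmap.transpose(1, 0, 2).reshape(H * W, C)    # column-major
    return {
        "right": ScanSequence(rm, "right", (H, W)),
        "left": ScanSequence(rm[::-1].copy(), "left", (H, W)),
        "down": ScanSequence(cm, "down", (H, W)),
        "up": ScanSequence(cm[::-1].copy(), "up", (H, W)),
    }


def deserialize(seq: ScanSequence) -> np.ndarray:
    """Invert :func:`serialize_directions` for one sequence -> (H, W, C)."""
    H, W = seq.origin_shape
    v = seq.values
    if seq.direction == "right":
        return v.reshape(H, W, -1)
    if seq.direction == "left":
        return v[::-1].reshape(H, W, -1)
    if seq.direction == "down":
        return v.reshape(W, H, -1).transpose(1, 0, 2)
    return v[::-1].reshape(W, H, -1).transpose(1, 0, 2)


def ss2d_forward(
    fmap: np.ndarray,
    direction_params: dict[str, SSMParams],
    proj_weight: np.ndarray,
    proj_bias: np.ndarray | None = None,
) -> np.ndarray:
    """Four-direction selective scan with channel-concat merge.

    Each direction's sequence is scanned with its own parameters, mapped back
    onto the grid, the four results concatenated along channels and projected
    back to the input width: ``Y = Proj(Concat[Y_right, Y_left, Y_down, Y_up])``.
    """
    fmap = np.asarray(fmap, dtype=float)
    if not np.all(np.isfinite(fmap)):
        raise InputError("feature map must be finite")
    seqs = serialize_directions(fmap)
    outs = []
    for d in DIRECTIONS:
        if d not in direction_params:
            raise ConfigurationError(f"missing parameters for direction {d!r}")
        outs.append(deserialize(selective_scan(seqs[d], direction_params[d])))
    cat = np.concatenate(outs, axis=-1)
    if proj_weight.shape[0] != cat.shape[-1]:
        raise ConfigurationError(
            f"projection expects {proj_weight.shape[0]} channels, got {cat.shape[-1]}"
        )
    y = cat @ proj_weight
    if proj_bias is not None:
        y = y + proj_bias
    return y


# ---------------------------------------------------------------------------
# Trainable SS2D block
# ---------------------------------------------------------------------------

class SS2DLayer(nn.Module):
    """Selective four-direction 2-D scan with input-dependent Delta, B, C.

    Per direction d and channel e the layer holds a learned log-decay
    ``Lambda[d, e, :] < 0`` (initialised to -1..-N), and linear maps that read
    Delta (through a softplus, initialised so softplus(bias) lies in
    [1e-3, 1e-1]), B_t and C_t from the input vector at each position.  A
    learned direct (skip) term D*x and a channel-concat merge projection
    complete the block.
    """

    def __init__(self, dim: int, state_dim: int = 16, dt_rank: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim, self.state_dim = dim, state_dim
        self.dt_rank = dt_rank or max(1, dim // 16)
        R, N, E = self.dt_rank, state_dim, dim
        # Lambda = -(1..N), shared pattern per channel, per direction
        lam = -np.tile(np.arange(1, N + 1, dtype=DTYPE), (4, E, 1))
        self.add_param("log_neg_lambda", np.log(-lam))
        # x -> (dt_rank + 2N) per direction
        self.add_param("x_proj", nn._kaiming((4, E, R + 2 * N), E, rng))
        self.add_param("dt_proj", nn._kaiming((4, R, E), R, rng))
        # softplus(dt_bias) in [1e-3, 1e-1]
        dt0 = np.exp(rng.uniform(math.log(1e-3), math.log(1e-1), size=(4, E)))
        self.add_param("dt_bias", np.log(np.expm1(dt0)).astype(DTYPE))
        self.add_param("skip_D", np.ones((4, E), dtype=DTYPE))
        self.add_param("out_proj", nn._kaiming((4 * E, E), 4 * E, rng))
        self.add_param("out_bias", np.zeros(E, dtype=DTYPE))

    # serialisation of an NCHW batch into the 4 directional sequences,
    # stacked on a leading direction axis: (B, 4, L, E)
    @staticmethod
    def _serialize(x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        hw = nn.transpose(x, (0, 2, 3, 1))                       # B,H,W,C
        rm = nn.reshape(hw, (B, H * W, C))
        cm = nn.reshape(nn.transpose(hw, (0, 2, 1, 3)), (B, H * W, C))
        rm_r = _flip_axis(rm, 1)
        cm_r = _flip_axis(cm, 1)
        stacked = nn.concat(
            [nn.reshape(s, (B, 1, H * W, C)) for s in (rm, rm_r, cm, cm_r)], axis=1
        )
        return stacked

    @staticmethod
    def _deserialize(y: Tensor, H: int, W: int) -> list[Tensor]:
        """(B, 4, L, E) -> list of four (B, H, W, E) grids."""
        B = y.shape[0]
        C = y.shape[-1]
        grids = []
        for d in range(4):
            s = nn.reshape(y_slice(y, d), (B, H * W, C))
            if d in (1, 3):
                s = _flip_axis(s, 1)
            g = nn.reshape(s, (B, H, W, C)) if d < 2 else nn.transpose(
                nn.reshape(s, (B, W, H, C)), (0, 2, 1, 3)
            )
            grids.append(g)
        return grids

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        E, N, R = self.dim, self.state_dim, self.dt_rank
        L = H * W
        seqs = self._serialize(x)                                # (B,4,L,E)
        proj = nn.matmul(seqs, self.x_proj)                      # (B,4,L,R+2N)
        dt_in = t_slice_last(proj, 0, R)
        B_t = nn.reshape(t_slice_last(proj, R, R + N), (B, 4, L, 1, N))
        C_t = nn.reshape(t_slice_last(proj, R + N, R + 2 * N), (B, 4, L, 1, N))
        dt = nn.softplus(nn.add(nn.matmul(dt_in, self.dt_proj),
                                nn.reshape(self.dt_bias, (1, 4, 1, E))))  # (B,4,L,E)
        lam = nn.mul(nn.exp(self.log_neg_lambda), -1.0)          # (4,E,N)
        z = nn.mul(nn.reshape(dt, (B, 4, L, E, 1)), nn.reshape(lam, (1, 4, 1, E, N)))
        a_bar = nn.exp(z)                                        # (B,4,L,E,N)
        # B_bar x_t = phi(z) * dt * B_t * x_t   (per channel e, state n)
        dt_x = nn.mul(nn.reshape(dt, (B, 4, L, E, 1)),
                      nn.reshape(seqs, (B, 4, L, E, 1)))
        u = nn.mul(nn.mul(nn.expm1_over_x(z), dt_x), B_t)        # (B,4,L,E,N)
        hs = nn.linear_scan(a_bar, u)                            # (B,4,L,E,N)
        y = nn.tsum(nn.mul(hs, C_t), axis=-1)                    # (B,4,L,E)
        y = nn.add(y, nn.mul(seqs, nn.reshape(self.skip_D, (1, 4, 1, E))))
        grids = self._deserialize(y, H, W)                       # 4 x (B,H,W,E)
        cat = nn.concat(grids, axis=-1)                          # (B,H,W,4E)
        out = nn.add(nn.matmul(cat, self.out_proj), self.out_bias)
        return nn.transpose(out, (0, 3, 1, 2))                   # NCHW

    def macs(self, H: int, W: int, batch: int = 1) -> int:
        E, N, R = self.dim, self.state_dim, self.dt_rank
        L = H * W
        per_dir = L * (E * (R + 2 * N)      # x_proj
                       + R * E              # dt_proj
                       + 5 * E * N          # a_bar, u, recurrence, readout
                       + E)                 # skip
        return batch * (4 * per_dir + L * 4 * E * E)  # + merge projection


def _flip_axis(t: Tensor, axis: int) -> Tensor:
    idx = [slice(None)] * t.ndim
    idx[axis] = slice(None, None, -1)
    data = t.data[tuple(idx)].copy()

    def bwd(out):
        def run():
            if t.requires_grad:
                t._accumulate(out.grad[tuple(idx)])
        return run

    return nn._make(data, (t,), bwd)


def y_slice(t: Tensor, d: int) -> Tensor:
    """Select index d on axis 1 (keeping the axis removed)."""
    data = t.data[:, d]

    def bwd(out):
        def run():
            if t.requires_grad:
                g = np.zeros_like(t.data)
                g[:, d] = out.grad
                t._accumulate(g)
        return run

    return nn._make(data, (t,), bwd)


def t_slice_last(t: Tensor, lo: int, hi: int) -> Tensor:
    data = t.data[..., lo:hi]

    def bwd(out):
        def run():
            if t.requires_grad:
                g = np.zeros_like(t.data)
                g[..., lo:hi] = out.grad
                t._accumulate(g)
        return run

    return nn._make(data, (t,), bwd)


class SSMBlock(nn.Module):
    """Pre-norm residual SS2D block with a sigmoid gate.

    x -> LayerNorm -> in_proj (E -> 2E, giving value v and gate g)
      -> SS2D(v) * sigmoid(g) -> out is added back to x.
    """

    def __init__(self, dim: int, state_dim: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.norm = nn.LayerNorm(dim, axis=1)
        self.add_param("in_proj", nn._kaiming((dim, 2 * dim), dim, rng))
        self.add_param("in_bias", np.zeros(2 * dim, dtype=DTYPE))
        self.ss2d = SS2DLayer(dim, state_dim=state_dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.norm(x)
        hc = nn.transpose(h, (0, 2, 3, 1))                       # B,H,W,C
        p = nn.add(nn.matmul(hc, self.in_proj), self.in_bias)    # B,H,W,2C
        v = nn.transpose(t_slice_last(p, 0, C), (0, 3, 1, 2))
        g = nn.transpose(t_slice_last(p, C, 2 * C), (0, 3, 1, 2))
        y = nn.mul(self.ss2d(v), nn.sigmoid(g))
        return nn.add(x, y)

    def profile(self, input_shape):
        B, C, H, W = input_shape
        macs = B * H * W * C * 2 * C + self.ss2d.macs(H, W, batch=B)
        return input_shape, macs
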