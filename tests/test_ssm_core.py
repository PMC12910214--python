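"""Oracle tests for the selective-scan primitives.

Every structured operation is checked against an independent brute-force
implementation written here: dense matrix exponentials for the
discretisation, a naive position-by-position recurrence for the scan, and
explicit index enumeration for the four serialisation orders.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from lcmamba import ssm_core
from lcmamba.ssm_core import (SSMParams, ScanSequence, deserialize, discretize,
                              selective_scan, serialize_directions, ss2d_forward)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def dense_discretize(lam, delta, B):
    """(dA)^-1 (exp(dA) - I) d B with dense matrix algebra."""
    A = np.diag(np.atleast_1d(lam))
    dA = delta * A
    B = np.atleast_2d(B)
    A_bar = expm(dA)
    B_bar = np.linalg.inv(dA) @ (expm(dA) - np.eye(len(A))) @ (delta * B)
    return np.diag(A_bar), B_bar


def naive_scan(x, A_bar, B_bar, C):
    """Unrolled recurrence, one explicit step per position."""
    h = np.zeros(C.shape[1])
    ys = []
    for t in range(x.shape[0]):
        a = A_bar[t] if A_bar.ndim == 2 else A_bar
        b = B_bar[t] if B_bar.ndim == 3 else B_bar
        h = a * h + b @ x[t]
        ys.append(C @ h)
    return np.array(ys)


# ---------------------------------------------------------------------------
# discretize
# ---------------------------------------------------------------------------

def test_discretize_worked_example():
    """Delta=1, lambda=ln 2, B=1: a_bar = 2, b_bar = 1/ln 2 ~ 1.4427."""
    p = SSMParams(lambda_diag=[np.log(2.0)], B_in=[[1.0]], C_out=[[1.0]], delta=1.0)
    A_bar, B_bar = discretize(p)
    assert A_bar[0] == pytest.approx(2.0, abs=1e-12)
    assert B_bar[0, 0] == pytest.approx(1.0 / np.log(2.0), abs=1e-10)
    # against the dense matrix-exponential oracle
    a_o, b_o = dense_discretize([np.log(2.0)], 1.0, [[1.0]])
    assert A_bar[0] == pytest.approx(a_o[0], abs=1e-10)
    assert B_bar[0, 0] == pytest.approx(b_o[0, 0], abs=1e-10)


@pytest.mark.parametrize("n_state", [1, 2, 3, 4])
def test_discretize_matches_dense_expm(n_state):
    rng = np.random.default_rng(n_state)
    lam = -rng.uniform(0.1, 3.0, n_state)
    B = rng.standard_normal((n_state, 2))
    delta = rng.uniform(0.05, 1.5)
    p = SSMParams(lambda_diag=lam, B_in=B, C_out=np.eye(n_state), delta=delta)
    A_bar, B_bar = discretize(p)
    a_o, b_o = dense_discretize(lam, delta, B)
    np.testing.assert_allclose(A_bar, a_o, atol=1e-10)
    np.testing.assert_allclose(B_bar, b_o, atol=1e-10)


def test_discretize_taylor_limit():
    """lambda -> 0: a_bar -> 1 and b_bar -> delta * B (series limit)."""
    p = SSMParams(lambda_diag=[1e-9], B_in=[[2.0]], C_out=[[1.0]], delta=0.5)
    A_bar, B_bar = discretize(p)
    assert A_bar[0] == pytest.approx(1.0, abs=1e-6)
    assert B_bar[0, 0] == pytest.approx(0.5 * 2.0, rel=1e-5)


def test_discretize_small_delta_limit():
    """delta -> 0+: a_bar -> 1 and b_bar -> 0."""
    p = SSMParams(lambda_diag=[-1.3], B_in=[[1.0]], C_out=[[1.0]], delta=1e-8)
    A_bar, B_bar = discretize(p)
    assert A_bar[0] == pytest.approx(1.0, abs=1e-6)
    assert abs(B_bar[0, 0]) < 1e-7


def test_discretize_stability_for_decaying_modes():
    """Re(lambda) <= 0 implies |a_bar| <= 1."""
    rng = np.random.default_rng(0)
    lam = -rng.uniform(0, 5, 8)
    p = SSMParams(lambda_diag=lam, B_in=np.ones((8, 1)), C_out=np.ones((1, 8)),
                  delta=rng.uniform(0.01, 2.0))
    A_bar, _ = discretize(p)
    assert np.all(np.abs(A_bar) <= 1.0 + 1e-12)


@pytest.mark.parametrize("bad", [0.0, -0.1])
def test_discretize_rejects_nonpositive_delta(bad):
    with pytest.raises(ssm_core.ParameterError):
        SSMParams(lambda_diag=[-1.0], B_in=[[1.0]], C_out=[[1.0]], delta=bad)


def test_discretize_rejects_nonfinite_lambda():
    with pytest.raises(ssm_core.ParameterError):
        SSMParams(lambda_diag=[np.nan], B_in=[[1.0]], C_out=[[1.0]], delta=1.0)


# ---------------------------------------------------------------------------
# selective_scan
# ---------------------------------------------------------------------------

def _random_params(rng, n_state, d_in, d_out, per_step_delta=None):
    return SSMParams(
        lambda_diag=-rng.uniform(0.1, 2.0, n_state),
        B_in=rng.standard_normal((n_state, d_in)),
        C_out=rng.standard_normal((d_out, n_state)),
        delta=per_step_delta if per_step_delta is not None else rng.uniform(0.1, 1.0),
    )


def test_scan_single_step_is_CB_x():
    """Length-1 sequence: y_1 = C B_bar x_1 because h_0 = 0."""
    rng = np.random.default_rng(3)
    p = _random_params(rng, 3, 2, 2)
    x = rng.standard_normal((1, 2))
    y = selective_scan(ScanSequence(x, "right", (1, 1)), p)
    _, B_bar = discretize(p)
    np.testing.assert_allclose(y.values[0], p.C_out @ (B_bar @ x[0]), atol=1e-12)


def test_scan_memoryless_when_abar_zero():
    """lambda*delta -> -inf: the state never carries over."""
    rng = np.random.default_rng(4)
    p = SSMParams(lambda_diag=[-1e4], B_in=rng.standard_normal((1, 2)),
                  C_out=rng.standard_normal((2, 1)), delta=1.0)
    x = rng.standard_normal((6, 2))
    y = selective_scan(ScanSequence(x, "right", (2, 3)), p)
    _, B_bar = discretize(p)
    expected = np.array([p.C_out @ (B_bar @ xt) for xt in x])
    np.testing.assert_allclose(y.values, expected, atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_scan_matches_naive_unroll(seed):
    rng = np.random.default_rng(100 + seed)
    L, d, n = 8, 3, 2
    p = _random_params(rng, n, d, d)
    x = rng.standard_normal((L, d))
    y = selective_scan(ScanSequence(x, "right", (2, 4)), p)
    A_bar, B_bar = discretize(p)
    np.testing.assert_allclose(y.values, naive_scan(x, A_bar, B_bar, p.C_out),
                               atol=1e-5)


def test_scan_per_position_delta_matches_naive():
    rng = np.random.default_rng(11)
    L = 6
    p = _random_params(rng, 2, 2, 1, per_step_delta=rng.uniform(0.05, 1.0, L))
    x = rng.standard_normal((L, 2))
    y = selective_scan(ScanSequence(x, "right", (1, 6)), p)
    A_bar, B_bar = discretize(p)
    np.testing.assert_allclose(y.values, naive_scan(x, A_bar, B_bar, p.C_out),
                               atol=1e-8)


def test_scan_rejects_empty_sequence():
    p = _random_params(np.random.default_rng(0), 2, 2, 2)
    with pytest.raises(ssm_core.InputError):
        ScanSequence(np.empty((0, 2)), "right", (0, 0))
        selective_scan(ScanSequence(np.empty((0, 2)), "right", (0, 0)), p)


def test_scan_step_count_linear_in_length():
    """Doubling the sequence length doubles the recurrence-step count."""
    rng = np.random.default_rng(5)
    p = _random_params(rng, 2, 1, 1)

    def steps(L):
        ssm_core.SCAN_STEP_COUNTER["steps"] = 0
        selective_scan(ScanSequence(rng.standard_normal((L, 1)), "right", (1, L)), p)
        return ssm_core.SCAN_STEP_COUNTER["steps"]

    assert steps(32) == 32
    assert steps(64) == 2 * steps(32)


def test_scan_hidden_state_bound():
    """Decaying modes keep the state bounded by |B_bar| max|x| / (1 - a_max)."""
    rng = np.random.default_rng(6)
    p = _random_params(rng, 3, 2, 3)
    x = rng.uniform(-1, 1, (200, 2))
    A_bar, B_bar = discretize(p)
    h = np.zeros(3)
    bound = np.abs(B_bar).sum(axis=1).max() * np.abs(x).max() / (1 - np.abs(A_bar).max())
    for t in range(200):
        h = A_bar * h + B_bar @ x[t]
        assert np.abs(h).max() <= bound + 1e-9


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_serialize_2x2_orders():
    """Explicit enumeration of the row-/column-major conventions."""
    grid = np.arange(4).reshape(2, 2, 1)  # labels: (0,0)=0 (0,1)=1 (1,0)=2 (1,1)=3
    seqs = serialize_directions(grid)
    assert seqs["right"].values[:, 0].tolist() == [0, 1, 2, 3]
    assert seqs["left"].values[:, 0].tolist() == [3, 2, 1, 0]
    assert seqs["down"].values[:, 0].tolist() == [0, 2, 1, 3]
    assert seqs["up"].values[:, 0].tolist() == [3, 1, 2, 0]


def test_serialize_1x1_degenerate():
    seqs = serialize_directions(np.array([[[7.0]]]))
    for s in seqs.values():
        assert s.values.shape == (1, 1)
        assert s.values[0, 0] == 7.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(h=st.integers(1, 7), w=st.integers(1, 7), c=st.integers(1, 3),
       seed=st.integers(0, 1000))
def test_serialize_roundtrip_identity(h, w, c, seed):
    grid = np.random.default_rng(seed).standard_normal((h, w, c))
    for s in serialize_directions(grid).values():
        assert s.values.shape == (h * w, c)
        np.testing.assert_array_equal(deserialize(s), grid)


# ---------------------------------------------------------------------------
# ss2d_forward
# ---------------------------------------------------------------------------

def _block_params(rng, C, n_state, d_out):
    return {d: _random_params(rng, n_state, C, d_out) for d in ssm_core.DIRECTIONS}


def test_ss2d_zero_projection_annihilates():
    rng = np.random.default_rng(7)
    fmap = rng.standard_normal((3, 4, 2))
    params = _block_params(rng, 2, 2, 3)
    y = ss2d_forward(fmap, params, np.zeros((4 * 3, 2)))
    assert y.shape == (3, 4, 2)
    assert np.all(y == 0)


def test_ss2d_1x1_input_directions_agree():
    """On a 1x1 grid all four directional scans coincide: Proj of 4 copies."""
    rng = np.random.default_rng(8)
    fmap = rng.standard_normal((1, 1, 3))
    p = _random_params(rng, 2, 3, 2)
    params = {d: p for d in ssm_core.DIRECTIONS}
    W = rng.standard_normal((8, 3))
    y = ss2d_forward(fmap, params, W)
    _, B_bar = discretize(p)
    y_dir = p.C_out @ (B_bar @ fmap[0, 0])
    np.testing.assert_allclose(y[0, 0], np.tile(y_dir, 4) @ W, atol=1e-10)


@pytest.mark.parametrize("seed", range(3))
def test_ss2d_equals_pipeline_of_steps(seed):
    """ss2d_forward == serialize -> scan -> deserialize -> concat -> project."""
    rng = np.random.default_rng(200 + seed)
    H, W_, C = 4, 4, 3
    fmap = rng.standard_normal((H, W_, C))
    params = _block_params(rng, C, 2, C)
    proj = rng.standard_normal((4 * C, C))
    bias = rng.standard_normal(C)
    y = ss2d_forward(fmap, params, proj, bias)

    outs = []
    for d in ssm_core.DIRECTIONS:
        seq = serialize_directions(fmap)[d]
        A_bar, B_bar = discretize(params[d])
        yv = naive_scan(seq.values, A_bar, B_bar, params[d].C_out)
        outs.append(deserialize(ScanSequence(yv, d, (H, W_))))
    expected = np.concatenate(outs, axis=-1) @ proj + bias
    np.testing.assert_allclose(y, expected, atol=1e-5)


def test_ss2d_shape_preserved_and_channel_mismatch_rejected():
    rng = np.random.default_rng(9)
    fmap = rng.standard_normal((5, 6, 2))
    params = _block_params(rng, 2, 2, 2)
    y = ss2d_forward(fmap, params, rng.standard_normal((8, 2)))
    assert y.shape == fmap.shape
    with pytest.raises(ssm_core.ConfigurationError):
        ss2d_forward(fmap, params, rng.standard_normal((5, 2)))
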