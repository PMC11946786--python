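"""Attention primitives against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echomasa import attention as A

# ---------------------------------------------------------------------------
# brute-force reference implementations (straight loops, no vectorization)
# ---------------------------------------------------------------------------


def brute_decay_1d(n, gamma):
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = gamma ** (i - j) if i >= j else 0.0
    return D


def brute_decay_2d(H, W, gamma):
    coords = [(x, y) for x in range(H) for y in range(W)]  # row-major
    N = len(coords)
    D = np.zeros((N, N))
    for n, (xn, yn) in enumerate(coords):
        for m, (xm, ym) in enumerate(coords):
            D[n, m] = gamma ** (abs(xn - xm) + abs(yn - ym))
    return D


def brute_retention_1d(Q, K, V, gamma):
    N, d = Q.shape
    out = np.zeros((N, d))
    for n in range(N):
        for m in range(n + 1):
            out[n] += gamma ** (n - m) * float(Q[n] @ K[m]) * V[m]
    return out


def brute_softmax_row(row):
    e = np.exp(row - row.max())
    return e / e.sum()


def brute_masa_full(Q, K, V, gamma):
    """Entry-wise evaluation: out_n = sum_m softmax(q_n.K)_m * D2d_nm * v_m."""
    H, W, d = Q.shape
    coords = [(x, y) for x in range(H) for y in range(W)]
    q = Q.reshape(-1, d)
    k = K.reshape(-1, d)
    v = V.reshape(-1, d)
    out = np.zeros_like(q, dtype=np.float64)
    for n, (xn, yn) in enumerate(coords):
        scores = np.array([float(q[n] @ k[m]) for m in range(len(coords))])
        attn = brute_softmax_row(scores)
        for m, (xm, ym) in enumerate(coords):
            out[n] += attn[m] * gamma ** (abs(xn - xm) + abs(yn - ym)) * v[m]
    return out.reshape(H, W, d)


def brute_masa_decomposed(Q, K, V, gamma):
    """Nested-loop evaluation: height-axis attention per column, then
    width-axis attention per row, sharing Q and K."""
    H, W, d = Q.shape
    U = np.zeros((H, W, d))
    for y in range(W):
        for x in range(H):
            scores = np.array([float(Q[x, y] @ K[m, y]) for m in range(H)])
            attn = brute_softmax_row(scores)
            for m in range(H):
                U[x, y] += attn[m] * gamma ** abs(x - m) * V[m, y]
    out = np.zeros((H, W, d))
    for x in range(H):
        for y in range(W):
            scores = np.array([float(Q[x, y] @ K[x, m]) for m in range(W)])
            attn = brute_softmax_row(scores)
            for m in range(W):
                out[x, y] += attn[m] * gamma ** abs(y - m) * U[x, m]
    return out


# ---------------------------------------------------------------------------
# softmax_rows
# ---------------------------------------------------------------------------


def test_softmax_uniform_and_closed_form():
    assert np.allclose(A.softmax_rows(np.zeros((2, 2))), np.full((2, 2), 0.5))
    out = A.softmax_rows(np.array([[0.0, np.log(3.0)]]))
    assert np.allclose(out, [[0.25, 0.75]], atol=1e-7)


def test_softmax_rows_normalized(rng):
    M = rng.normal(size=(4, 4)) * 5
    out = A.softmax_rows(M)
    assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-12)
    assert (out > 0).all()


def test_softmax_rejects_non_finite():
    with pytest.raises(ValueError):
        A.softmax_rows(np.array([[np.inf, 0.0]]))


# ---------------------------------------------------------------------------
# decay matrices
# ---------------------------------------------------------------------------


def test_decay_1d_closed_form():
    expected = [[1, 0, 0], [0.5, 1, 0], [0.25, 0.5, 1]]
    assert np.allclose(A.decay_1d(3, 0.5), expected)
    assert np.allclose(A.decay_1d(1, 0.3), [[1.0]])


def test_decay_1d_matches_brute_force():
    assert np.allclose(A.decay_1d(5, 0.9), brute_decay_1d(5, 0.9), atol=1e-7)


@pytest.mark.parametrize("gamma", [0.0, 1.0, -0.2, 1.5])
def test_invalid_gamma_rejected(gamma):
    with pytest.raises(ValueError):
        A.decay_1d(3, gamma)
    with pytest.raises(ValueError):
        A.decay_2d(2, 2, gamma)


def test_decay_2d_2x2_closed_form():
    D = A.decay_2d(2, 2, 0.5)
    assert np.allclose(D, brute_decay_2d(2, 2, 0.5), atol=1e-7)
    # each row's off-diagonal entries are {0.5, 0.5, 0.25}
    for row in D:
        off = sorted(row[row < 1.0])
        assert np.allclose(off, [0.25, 0.5, 0.5])
    # token (0,0) vs (1,1): Manhattan distance 2
    assert np.isclose(D[0, 3], 0.25)


@given(H=st.integers(1, 5), W=st.integers(1, 5),
       gamma=st.floats(0.05, 0.95), data=st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_decay_2d_properties(H, W, gamma, data):
    D = A.decay_2d(H, W, gamma)
    N = H * W
    assert np.allclose(np.diag(D), 1.0)
    assert (D >= 0).all() and (D <= 1).all()
    assert np.allclose(D, D.T)
    # monotone: decay never increases with Manhattan distance
    n = data.draw(st.integers(0, N - 1))
    m = data.draw(st.integers(0, N - 1))
    dist = abs(n // W - m // W) + abs(n % W - m % W)
    closer = [k for k in range(N)
              if abs(n // W - k // W) + abs(n % W - k % W) <= dist]
    assert all(D[n, k] >= D[n, m] - 1e-12 for k in closer)


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------


def test_retention_single_token(rng):
    q, k, v = rng.normal(size=(3, 1, 4)).astype(np.float32)
    out = A.retention_1d(q, k, v, 0.5)
    assert np.allclose(out, float(q[0] @ k[0]) * v[0], atol=1e-6)


def test_retention_matches_brute_force(rng):
    Q, K, V = (rng.normal(size=(3, 4)).astype(np.float32) for _ in range(3))
    assert np.allclose(A.retention_1d(Q, K, V, 0.7), brute_retention_1d(Q, K, V, 0.7),
                       atol=1e-5)


def test_retention_shape_mismatch(rng):
    Q = rng.normal(size=(3, 4))
    with pytest.raises(ValueError):
        A.retention_1d(Q, Q[:2], Q, 0.5)


# ---------------------------------------------------------------------------
# full and decomposed MaSA
# ---------------------------------------------------------------------------


def test_masa_full_single_token(rng):
    Q, K, V = (rng.normal(size=(1, 1, 5)).astype(np.float32) for _ in range(3))
    assert np.allclose(A.masa_full(Q, K, V, 0.5), V, atol=1e-6)
    assert np.allclose(A.masa_decomposed(Q, K, V, 0.5), V, atol=1e-6)


def test_masa_full_uniform_attention_near_gamma_one(rng):
    # Q = K = 0 gives uniform softmax; gamma -> 1 makes D all ones,
    # so every output token approaches the mean of the V rows
    V = rng.normal(size=(2, 3, 4)).astype(np.float32)
    Z = np.zeros_like(V)
    out = A.masa_full(Z, Z, V, 1 - 1e-7)
    assert np.allclose(out, V.reshape(-1, 4).mean(axis=0), atol=1e-4)


@pytest.mark.parametrize("H,W,d", [(3, 3, 4), (2, 5, 3), (6, 6, 16), (1, 4, 2)])
def test_masa_full_matches_brute_force(H, W, d):
    rng = np.random.default_rng(H * 100 + W * 10 + d)
    Q, K, V = (rng.normal(size=(H, W, d)).astype(np.float32) for _ in range(3))
    assert np.abs(A.masa_full(Q, K, V, 0.8) - brute_masa_full(Q, K, V, 0.8)).max() < 1e-6


@pytest.mark.parametrize("H,W,d", [(4, 4, 8), (2, 3, 4), (5, 2, 6)])
def test_masa_decomposed_matches_brute_force(H, W, d):
    rng = np.random.default_rng(H * 100 + W * 10 + d)
    Q, K, V = (rng.normal(size=(H, W, d)).astype(np.float32) for _ in range(3))
    got = A.masa_decomposed(Q, K, V, 0.7)
    assert np.abs(got - brute_masa_decomposed(Q, K, V, 0.7)).max() < 1e-6


@pytest.mark.parametrize("shape", [(1, 6, 4), (6, 1, 4)])
def test_masa_decomposed_equals_full_on_degenerate_grids(shape):
    rng = np.random.default_rng(7)
    Q, K, V = (rng.normal(size=shape).astype(np.float32) for _ in range(3))
    full = A.masa_full(Q, K, V, 0.85)
    dec = A.masa_decomposed(Q, K, V, 0.85)
    assert np.abs(full - dec).max() < 1e-6


def test_masa_shape_mismatch(rng):
    Q = rng.normal(size=(2, 2, 4)).astype(np.float32)
    with pytest.raises(ValueError):
        A.masa_full(Q, Q, Q[:, :1], 0.5)


def test_masa_config_validation():
    cfg = A.MaSAConfig(num_heads=4)
    assert np.allclose(cfg.gammas, [1 - 2.0 ** (-5 - h) for h in range(4)])
    with pytest.raises(ValueError):
        A.MaSAConfig(num_heads=2, gammas=np.array([0.5, 1.2]))


# ---------------------------------------------------------------------------
# cost model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [2, 3, 4, 8, 16, 32])
@pytest.mark.parametrize("d", [1, 8, 64])
def test_decomposed_strictly_cheaper_on_square_grids(n, d):
    assert A.op_counts_masa_decomposed(n, n, d) < A.op_counts_masa_full(n, n, d)
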