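"""Retention and Manhattan self-attention (MaSA) primitives.

The retention mechanism replaces the purely learned weighting of softmax
attention with an *explicit* relative-position prior: token pairs are
down-weighted by ``gamma ** distance`` with ``0 < gamma < 1``.  In 1D the
distance is the (causal) index difference; in 2D it is the Manhattan
distance between the tokens' grid coordinates, which makes the prior
usable on images.

Conventions used throughout the package
---------------------------------------
* A token field is an ``(H, W, d)`` array; token ``(x, y)`` sits at row
  ``x``, column ``y``.  Flattening is always row-major, so token ``(x, y)``
  has flat index ``x * W + y``.
* 2D MaSA: ``out = (softmax_rows(Q K^T) ⊙ D2d) V`` — the Hadamard mask is
  **not** renormalized afterwards.
* Decomposed MaSA applies two 1D attentions in sequence: first along the
  height axis (one attention per column, decay ``gamma**|x_n - x_m|``),
  then along the width axis (one attention per row, decay
  ``gamma**|y_n - y_m|``).  Both reuse the same Q and K.  On single-row or
  single-column grids the unused factor degenerates to the identity and the
  decomposed form equals the full form exactly.

Everything here is plain numpy in double precision (these functions double
as numerical references); the differentiable float32 layers in
:mod:`echomasa.encoder` re-express the same math with autodiff tensors and
are tested for agreement with these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaSAConfig",
    "decay_1d",
    "decay_2d",
    "decay_axis",
    "default_head_gammas",
    "masa_decomposed",
    "masa_full",
    "op_counts_masa_decomposed",
    "op_counts_masa_full",
    "retention_1d",
    "softmax_rows",
]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must lie strictly inside (0, 1), got {gamma}")
    return gamma


def default_head_gammas(num_heads: int) -> np.ndarray:
    """Per-head decay rates ``1 - 2**(-5 - h)``, h = 0..num_heads-1.

    Deeper heads decay more slowly, mixing short- and long-range context.
    """
    h = np.arange(num_heads)
    return (1.0 - 2.0 ** (-5.0 - h)).astype(np.float64)


@dataclass
class MaSAConfig:
    """Configuration of one MaSA block (per-head decay, head count, form)."""

    num_heads: int = 1
    gammas: np.ndarray | None = None
    decomposed: bool = False

    def __post_init__(self):
        if self.num_heads < 1:
            raise ValueError("num_heads must be positive")
        if self.gammas is None:
            self.gammas = default_head_gammas(self.num_heads)
        self.gammas = np.asarray(self.gammas, dtype=np.float64)
        if self.gammas.shape != (self.num_heads,):
            raise ValueError("need one gamma per head")
        for g in self.gammas:
            _check_gamma(g)


def softmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a matrix (stable under row-max subtraction).

    Computed in float64: these reference functions serve as numerical
    oracles, so they carry full double precision; the network layers in
    :mod:`echomasa.nn` work in float32.
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("softmax_rows: input contains non-finite entries")
    e = np.exp(M - M.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def decay_1d(n: int, gamma: float) -> np.ndarray:
    """Causal 1D decay matrix: entry (i, j) = gamma**(i-j) for i >= j, else 0."""
    gamma = _check_gamma(gamma)
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    return np.where(diff >= 0, np.power(gamma, np.clip(diff, 0, None)), 0.0)


def decay_axis(n: int, gamma: float) -> np.ndarray:
    """Symmetric 1D decay matrix: entry (i, j) = gamma**|i-j|."""
    gamma = _check_gamma(gamma)
    i = np.arange(n)
    return np.power(gamma, np.abs(i[:, None] - i[None, :]))


def decay_2d(H: int, W: int, gamma: float) -> np.ndarray:
    """Manhattan decay matrix over a row-major H×W token grid.

    Entry (n, m) = gamma**(|x_n - x_m| + |y_n - y_m|).  Equals the Kronecker
    product of the two axis decays, which is how it is built here.
    """
    if H < 1 or W < 1:
        raise ValueError("grid dimensions must be >= 1")
    return np.kron(decay_axis(H, gamma), decay_axis(W, gamma))


def retention_1d(Q: np.ndarray, K: np.ndarray, V: np.ndarray, gamma: float) -> np.ndarray:
    """1D retention: (Q K^T ⊙ D1d) V — note, no softmax."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape != K.shape or Q.shape[0] != V.shape[0]:
        raise ValueError(f"shape mismatch: Q{Q.shape} K{K.shape} V{V.shape}")
    D = decay_1d(Q.shape[0], gamma)
    return ((Q @ K.T) * D) @ V


def _check_field(Q, K, V):
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if not (Q.shape == K.shape == V.shape) or Q.ndim != 3:
        raise ValueError(f"token fields must share an (H, W, d) shape: {Q.shape} {K.shape} {V.shape}")
    return Q, K, V


def masa_full(Q: np.ndarray, K: np.ndarray, V: np.ndarray, gamma: float) -> np.ndarray:
    """Full 2D Manhattan self-attention on an (H, W, d) token field."""
    Q, K, V = _check_field(Q, K, V)
    H, W, d = Q.shape
    D = decay_2d(H, W, gamma)
    q = Q.reshape(H * W, d)
    k = K.reshape(H * W, d)
    v = V.reshape(H * W, d)
    A = softmax_rows(q @ k.T) * D
    return (A @ v).reshape(H, W, d)


def masa_decomposed(Q: np.ndarray, K: np.ndarray, V: np.ndarray, gamma: float) -> np.ndarray:
    """Decomposed MaSA: height-axis attention, then width-axis attention.

    ``U[:, y, :] = (softmax(Q[:, y] Q-col scores) ⊙ gamma**|Δx|) V[:, y, :]``
    followed by ``out[x, :, :] = (softmax(Q[x] row scores) ⊙ gamma**|Δy|) U[x, :, :]``.
    Q, K, V stay in (H, W, d) layout — they are never flattened to N tokens.
    """
    Q, K, V = _check_field(Q, K, V)
    H, W, d = Q.shape
    Dh = decay_axis(H, gamma)  # vertical distances |x_n - x_m|
    Dw = decay_axis(W, gamma)  # horizontal distances |y_n - y_m|

    # height axis: batch over columns (contiguous copies keep matmul on BLAS)
    Qc = np.ascontiguousarray(Q.transpose(1, 0, 2))  # (W, H, d)
    Kc = np.ascontiguousarray(K.transpose(1, 0, 2))
    Vc = np.ascontiguousarray(V.transpose(1, 0, 2))
    Av = softmax_rows(np.matmul(Qc, Kc.transpose(0, 2, 1))) * Dh[None]
    U = np.ascontiguousarray(np.matmul(Av, Vc).transpose(1, 0, 2))  # back to (H, W, d)

    # width axis: batch over rows
    Ah = softmax_rows(np.matmul(Q, K.transpose(0, 2, 1))) * Dw[None]
    return np.matmul(Ah, U)


# -- analytic cost model ------------------------------------------------------
#
# Scalar-operation counts for one single-head attention application.  The
# convention counts every scalar operation the algorithm performs: one
# multiply-add per scalar product term in the matrix products, and for each
# softmax row of length L: L max-subtractions, L exponentials, L-1 additions
# and L divisions; the decay Hadamard mask adds one multiply per entry.
# Counting the softmax interior matters: on matmul MACs alone the full and
# decomposed forms tie at 2×2, while the complete budget is strictly smaller
# for the decomposed form on every square grid with side >= 2.

def _softmax_ops(rows: int, length: int) -> int:
    return rows * (3 * length + (length - 1))


def op_counts_masa_full(H: int, W: int, d: int) -> int:
    """Total scalar ops of full MaSA on an H×W grid with embed dim d."""
    N = H * W
    scores = N * N * d
    apply_v = N * N * d
    hadamard = N * N
    return scores + apply_v + hadamard + _softmax_ops(N, N)


def op_counts_masa_decomposed(H: int, W: int, d: int) -> int:
    """Total scalar ops of decomposed MaSA on an H×W grid with embed dim d."""
    vertical = W * H * H * d * 2 + W * H * H + _softmax_ops(W * H, H)
    horizontal = H * W * W * d * 2 + H * W * W + _softmax_ops(H * W, W)
    return vertical + horizontal


# default N-doubling path for empirical scaling checks: N = 256 ... 4096
DOUBLING_PATH: tuple[tuple[int, int], ...] = ((16, 16), (32, 16), (32, 32), (64, 32), (64, 64))


def doubling_time_ratio(kind: str, d: int = 32,
                        path: tuple[tuple[int, int], ...] = DOUBLING_PATH,
                        repeats: int = 5, seed: int = 0) -> float:
    """Geometric-mean wall-time growth per token-count doubling.

    Times the float32 network implementation of the attention form (the
    single-head layers in :mod:`echomasa.encoder`; the float64 functions in
    this module are precision oracles, not the production path) along a grid
    path in which N doubles at each step, taking the best of ``repeats``
    runs per size.  Quadratic scaling gives ~4 per doubling; the decomposed
    form's N·(H+W)·d cost gives ~2.8 asymptotically and less at these
    partially overhead-bound sizes.  Decay matrices are cached per size, as
    in a real model, so their construction is excluded.
    """
    import time as _time

    from .encoder import masa_decomposed_t, masa_full_t
    from .nn import Tensor

    fn = {"full": masa_full_t, "decomposed": masa_decomposed_t}[kind]
    gammas = np.array([0.9])
    rng = np.random.default_rng(seed)
    times = []
    for H, W in path:
        Q, K, V = (Tensor(rng.normal(size=(1, d, H, W)).astype(np.float32))
                   for _ in range(3))
        fn(Q, K, V, 1, gammas)  # warm-up; builds and caches the decay matrix
        best = np.inf
        for _ in range(repeats):
            t0 = _time.perf_counter()
            fn(Q, K, V, 1, gammas)
            best = min(best, _time.perf_counter() - t0)
        times.append(best)
    ratios = [t2 / t1 for t1, t2 in zip(times, times[1:])]
    return float(np.prod(ratios) ** (1.0 / len(ratios)))
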