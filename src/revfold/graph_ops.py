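"""Pairwise geometry and multiscale chain operators.

Distances between feature columns define a weighted, fully connected graph
whose Laplacian acts as the spatial coupling operator of every network layer;
the graph is rebuilt from the current features each time it is used, so
connectivity evolves smoothly as the latent dynamics evolve.  Chain pooling
and unpooling provide the coarse scales of the graph U-net.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


def pairwise_distances(Y: np.ndarray) -> np.ndarray:
    """Euclidean distances between the columns of a d×n matrix.

    Computed via the Gram identity (outer sums of squared column norms minus
    twice the Gram matrix); round-off negatives are clamped to zero before
    the square root, and the diagonal is exactly zero.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("pairwise_distances: non-finite input")
    sq = np.sum(Y * Y, axis=0)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Y.T @ Y)
    np.maximum(D2, 0.0, out=D2)
    D = np.sqrt(D2)
    np.fill_diagonal(D, 0.0)
    return D


def edge_weights(D: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential affinities W_ij = exp(-D_ij / alpha), in (0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return np.exp(-np.asarray(D, dtype=float) / alpha)


def graph_laplacian(W: np.ndarray) -> np.ndarray:
    """L = diag(W·1) − W for a symmetric nonnegative weight matrix.

    The result has zero row sums and is positive semi-definite; the unit
    self-weight on W's diagonal cancels in the construction.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if np.max(np.abs(W - W.T)) > 1e-6:
        raise ValueError("W must be symmetric (tolerance 1e-6)")
    return np.diag(W.sum(axis=1)) - W


def _pool_matrix(n: int) -> np.ndarray:
    """n×⌈n/2⌉ column-averaging operator; odd trailing column carried."""
    m = (n + 1) // 2
    A = np.zeros((n, m))
    for j in range(n // 2):
        A[2 * j, j] = 0.5
        A[2 * j + 1, j] = 0.5
    if n % 2 == 1:
        A[n - 1, m - 1] = 1.0
    return A


def _coarse_centers(m: int, target_n: int) -> np.ndarray:
    """Fine-chain positions represented by coarse nodes after factor-2 pooling.

    Pair-averaged node j sits at fine position 2j + 0.5; a carried odd tail
    column sits at its own position target_n − 1.
    """
    c = 2.0 * np.arange(m) + 0.5
    return np.minimum(c, target_n - 1.0)


def _unpool_matrix(m: int, target_n: int) -> np.ndarray:
    """m×target_n linear-interpolation operator along the chain.

    Coarse nodes are placed at the fine positions factor-2 pooling drew them
    from, values are linearly interpolated between neighbouring nodes, and
    the chain ends are extended with the nearest node's value.  This makes
    unpool∘pool the identity on features linear in the chain index (away
    from the flat-extended endpoints).
    """
    if m == 1:
        return np.ones((1, target_n))
    centers = _coarse_centers(m, target_n)
    P = np.zeros((m, target_n))
    pos = np.arange(target_n, dtype=float)
    idx = np.clip(np.searchsorted(centers, pos) - 1, 0, m - 2)
    left = centers[idx]
    right = centers[idx + 1]
    t = np.clip((pos - left) / (right - left), 0.0, 1.0)
    P[idx, np.arange(target_n)] = 1.0 - t
    P[idx + 1, np.arange(target_n)] += t
    return P


def pool_chain(Y):
    """Average non-overlapping pairs of consecutive columns (d×n → d×⌈n/2⌉).

    Odd-length chains carry the final column through unchanged.  Accepts an
    ndarray or an autodiff Tensor.
    """
    n = Y.shape[1]
    if n < 2:
        raise ValueError("pool_chain requires at least 2 columns")
    A = _pool_matrix(n)
    if isinstance(Y, ad.Tensor):
        return ad.matmul(Y, A)
    return np.asarray(Y, dtype=float) @ A


def unpool_chain(Y, target_n: int):
    """Linearly interpolate coarse columns back to ``target_n`` positions."""
    m = Y.shape[1]
    if target_n < m:
        raise ValueError(f"target_n ({target_n}) must be >= m ({m})")
    P = _unpool_matrix(m, target_n)
    if isinstance(Y, ad.Tensor):
        return ad.matmul(Y, P)
    return np.asarray(Y, dtype=float) @ P


# ---------------------------------------------------------------------------
# tape (autodiff) versions of the graph construction, used inside the network

def pairwise_distances_t(Y: ad.Tensor) -> ad.Tensor:
    """Tensor version of :func:`pairwise_distances` (Gram identity + safe sqrt)."""
    sq = ad.tsum(ad.square(Y), axis=0, keepdims=True)  # (1, n)
    D2 = ad.sub(ad.add(ad.transpose(sq), sq), ad.scale(ad.matmul(ad.transpose(Y), Y), 2.0))
    return ad.safe_sqrt(D2)


def graph_laplacian_t(Y: ad.Tensor, alpha: float) -> ad.Tensor:
    """Weighted Laplacian rebuilt from current features, on the tape."""
    D = pairwise_distances_t(Y)
    W = ad.exp(ad.scale(D, -1.0 / alpha))
    deg = ad.tsum(W, axis=1)
    return ad.sub(ad.diag_embed(deg), W)
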