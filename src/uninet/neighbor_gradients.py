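"""κ-nearest-neighbor constructions and co-activity gradients.

A correlation network C is thresholded column-wise to its κ strongest
off-diagonal neighbors (C̃), symmetrized into a binary union graph (ℭ),
or squared into the integer co-neighbor matrix 𝒞 = [C̃>0]ᵀ[C̃>0] that
counts shared retained neighbors.  Co-activity gradients are computed
either through the diffusion-map pipeline popular in imaging
neuroscience (cosine kernel, α-Laplacian normalization, row-stochastic
transition matrix, trailing eigenvectors) or, equivalently up to the
constant first eigenvector, as eigenvectors 2..k+1 of the co-neighbor
matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .core import Network, Partition, UninetError, eigensystem, _fix_signs
from .loyvain import ClusterResult, LoyvainConfig, loyvain


def default_kappa(n: int) -> int:
    """Standard imaging-neuroscience choice κ = round(0.1 n)."""
    return max(1, round(0.1 * n))


def knn_threshold(C: Network, kappa: int) -> sparse.csc_matrix:
    """Column-wise κ-strongest-neighbor thresholding C̃ of C.

    Per column, the κ largest off-diagonal entries are retained (ties at
    the threshold break toward the lowest node index, so exactly κ
    entries survive); everything else, including the diagonal, is zeroed.
    The result may be asymmetric.
    """
    n = C.n
    if not 1 <= kappa < n:
        raise UninetError(f"need 1 <= kappa < n, got kappa={kappa}, n={n}")
    W = C.weights.copy()
    np.fill_diagonal(W, -np.inf)
    # stable sort => among ties the lowest row index is retained
    order = np.argsort(-W, axis=0, kind="stable")[:kappa]
    rows = order.ravel(order="F")
    cols = np.repeat(np.arange(n), kappa)
    data = C.weights[rows, cols]
    return sparse.csc_matrix((data, (rows, cols)), shape=(n, n))


def symmetric_knn(C: Network, kappa: int) -> Network:
    """Symmetric binary κ-NN graph ℭ: an edge when either node retains the other."""
    B = (knn_threshold(C, kappa) > 0).astype(float)
    U = ((B + B.T) > 0).astype(float).toarray()
    np.fill_diagonal(U, 0.0)
    return Network(U, flavor="knn_binary")


def co_neighbor(C: Network, kappa: int, keep_diagonal: bool = False) -> Network:
    """Integer co-neighbor matrix 𝒞 = [C̃>0]ᵀ[C̃>0].

    Entry (i, j) counts the retained neighbors shared by columns i and j
    (at most κ).  The diagonal, which equals κ by construction, is zeroed
    by default: a constant diagonal shifts all eigenvalues uniformly
    without changing eigenvectors.
    """
    B = (knn_threshold(C, kappa) > 0).astype(float)
    S = (B.T @ B).toarray()
    if not keep_diagonal:
        np.fill_diagonal(S, 0.0)
        return Network(S, flavor="co_neighbor")
    net = Network(S, flavor="co_neighbor")
    return net


def _check_connected(adj: np.ndarray, what: str) -> None:
    ncomp, _ = connected_components(sparse.csr_matrix(adj > 0), directed=False)
    if ncomp > 1:
        raise UninetError(
            f"{what} graph has {ncomp} components; increase kappa to connect it"
        )


def diffusion_gradients(
    C: Network, kappa: int, k: int, alpha: float = 0.5
) -> np.ndarray:
    """Diffusion-map co-activity gradients (imaging-neuroscience variant).

    Steps: cosine-similarity kernel A = η̃ C̃ᵀ C̃ η̃ with η̃_ii =
    (c̃_iᵀc̃_i)^(−1/2); α-normalization R = A ⊙ vvᵀ with v = (A1)^(−α)
    (default α = 1/2); row-stochastic 𝓡; gradients are the right
    eigenvectors 2..k+1 of 𝓡 divided elementwise by the (constant) first
    right eigenvector.  Eigenvalue rescaling of the gradients is omitted,
    as it amounts to normalization by constants.
    """
    Ct = knn_threshold(C, kappa).toarray()
    norms = np.linalg.norm(Ct, axis=0)
    if np.any(norms <= 0):
        raise UninetError("a node has no retained neighbors")
    A = (Ct / norms).T @ (Ct / norms)
    _check_connected(A, "kernel")
    v = A.sum(axis=1) ** -alpha
    R = A * np.outer(v, v)
    rowsum = R.sum(axis=1)
    # row-stochastic Rcal = diag(rowsum)^-1 R is similar to the symmetric
    # matrix D^-1/2 R D^-1/2; right eigenvectors are D^-1/2 w
    half = rowsum**-0.5
    sym = R * np.outer(half, half)
    es = eigensystem(sym, k=k + 1)
    Q = _fix_signs(half[:, None] * es.vectors)
    q1 = Q[:, 0]
    return _fix_signs(Q[:, 1 : k + 1] / q1[:, None])


def coneighbor_gradients(C: Network, kappa: int, k: int) -> np.ndarray:
    """Gradients as eigenvectors 2..k+1 of the co-neighbor matrix."""
    S = co_neighbor(C, kappa)
    if k == 0:
        return np.empty((C.n, 0))
    _check_connected(S.weights, "co-neighbor")
    es = eigensystem(S, k=k + 1)
    return es.vectors[:, 1 : k + 1]


def binary_gradients(
    C: Network, kappa: int, k: int, config: LoyvainConfig | None = None
) -> ClusterResult:
    """Binary co-activity gradients: k-modularity modules of the co-neighbor
    network."""
    S = co_neighbor(C, kappa)
    config = config or LoyvainConfig(k=k, objective="kmodularity")
    if config.k != k or config.objective != "kmodularity":
        from dataclasses import replace

        config = replace(config, k=k, objective="kmodularity")
    return loyvain(S, config)


def partition_from_gradients(result: ClusterResult) -> Partition:
    return result.partition
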