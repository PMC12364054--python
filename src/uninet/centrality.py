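"""Degree-family centrality measures and their theoretical partners.

The degree s = W1 and the second degree S = (W∘²)1 are the first and
second raw moments of nodal connectivity.  This module implements the
measures they approximate (eigenvector centrality, diffusion efficiency,
communicability, average controllability) or exactly complement (modal
controllability = 1 − S on unit-spectral-radius networks), plus the
participation-coefficient family and the squared coefficient of
variation.  Communicability and controllability assume the network is
rescaled to unit spectral radius (``rescale_spectral``).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from scipy import sparse

from .core import Network, Partition, UninetError, eigensystem


def degree(W: Network) -> np.ndarray:
    """Degree s = W 1."""
    return W.weights.sum(axis=1)


def second_degree(W: Network) -> np.ndarray:
    """Second degree S_i = Σ_j w_ij², the sum of squared connection weights."""
    return (W.weights**2).sum(axis=1)


def rescale_spectral(W: Network) -> Network:
    """Rescale weights so the leading eigenvalue is 1."""
    lam1 = eigensystem(W, k=1).values[0]
    if lam1 <= 0:
        raise UninetError("spectral rescaling requires a positive leading eigenvalue")
    return Network(W.weights / lam1, flavor=W.flavor)


def _require_connected(W: Network, what: str) -> None:
    ncomp, _ = connected_components(sparse.csr_matrix(W.weights > 0), directed=False)
    if ncomp > 1:
        raise UninetError(f"{what} requires a connected network")


def eigenvector_centrality(W: Network) -> np.ndarray:
    """Leading eigenvector of W (all-positive by Perron–Frobenius), unit norm."""
    _require_connected(W, "eigenvector centrality")
    v1 = eigensystem(W, k=1).vectors[:, 0]
    if v1.min() < -1e-8:
        raise UninetError("leading eigenvector is not positive; network invalid")
    return np.abs(v1)


def mean_first_passage_time(W: Network) -> np.ndarray:
    """MFPT matrix of the random walk with transitions Y = diag(s)^(-1) W.

    Entry (i, j) is the expected number of steps for a walker starting at
    i to first reach j; the diagonal is 0 (self-passage convention).
    Computed through the fundamental matrix Z = (I − Y + 1πᵀ)^(−1) with
    stationary distribution π = s / Σw:  MFPT_ij = (z_jj − z_ij) / π_j.
    """
    _require_connected(W, "mean first passage time")
    s = degree(W)
    if np.any(s <= 0) or W.total_weight <= 0:
        raise UninetError("MFPT requires positive degrees")
    Y = W.weights / s[:, None]
    pi = s / W.total_weight
    n = W.n
    Z = linalg.solve(np.eye(n) - Y + np.outer(np.ones(n), pi), np.eye(n))
    mfpt = (np.diagonal(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    return mfpt


def diffusion_efficiency(W: Network, axis: str = "into") -> np.ndarray:
    """Mean inverse MFPT per node (higher = easier to reach).

    The default reads efficiency of node j as the mean over sources i ≠ j
    of 1/MFPT_ij — how easily j is reached from the rest of the network,
    the reading under which the measure tracks the degree.  ``axis='from'``
    averages over targets instead.  Invariant to uniform weight rescaling.
    """
    mfpt = mean_first_passage_time(W)
    n = W.n
    inv = np.zeros_like(mfpt)
    off = ~np.eye(n, dtype=bool)
    inv[off] = 1.0 / mfpt[off]
    if axis == "into":
        return inv.sum(axis=0) / (n - 1)
    if axis == "from":
        return inv.sum(axis=1) / (n - 1)
    raise UninetError("axis must be 'into' or 'from'")


def communicability_centrality(
    W_rescaled: Network, truncated: bool = False
) -> np.ndarray:
    """Diagonal of the communicability matrix exp(W) (unit spectral radius).

    ``truncated`` returns the second-order series 1 + S_i/2, the
    approximation that ties communicability to the second degree.
    """
    if truncated:
        return 1.0 + 0.5 * second_degree(W_rescaled)
    return np.diagonal(linalg.expm(W_rescaled.weights)).copy()


def average_controllability(W_rescaled: Network, gamma: float = 2.0) -> np.ndarray:
    """Diagonal of the controllability Gramian Σ_τ (W/γ)^(2τ) with B = I.

    Closed form diag((I − W²/γ²)^(−1)); requires γ > λ₁ = 1.  The default
    γ = 1 + λ₁ = 2 is the standard normalization.
    """
    lam1 = eigensystem(W_rescaled, k=1).values[0]
    if gamma <= lam1:
        raise UninetError(f"need gamma > leading eigenvalue {lam1:.6g}")
    n = W_rescaled.n
    G = linalg.solve(
        np.eye(n) - W_rescaled.weights @ W_rescaled.weights / gamma**2, np.eye(n)
    )
    return np.diagonal(G).copy()


def modal_controllability(W_rescaled: Network) -> np.ndarray:
    """Modal controllability φ_i = Σ_j v_ij² (1 − λ_j²).

    On unit-spectral-radius networks this equals 1 − S_i exactly, the
    complement of the second degree.
    """
    es = eigensystem(W_rescaled)
    return ((es.vectors**2) * (1.0 - es.values**2)).sum(axis=1)


def participation(
    W: Network, P: Partition, normalized: bool = False
) -> np.ndarray:
    """Participation coefficient 1 − Σ_h (s_ih/s_i)².

    ``normalized`` gives the k-participation coefficient, which divides
    each module's term by its size N_h (the analogue of the size
    normalization in k-modularity).
    """
    s = degree(W)
    if np.any(s <= 0):
        raise UninetError("participation requires positive degrees")
    frac = (W.weights @ P.indicator()) / s[:, None]
    if normalized:
        return 1.0 - (frac**2 / P.sizes).sum(axis=1)
    return 1.0 - (frac**2).sum(axis=1)


def coefficient_of_variation_sq(W: Network) -> np.ndarray:
    """Squared coefficient of variation var(w_i)/mean(w_i)² of each node's
    weight vector (all n entries, including the zero diagonal)."""
    mean = W.weights.mean(axis=1)
    if np.any(mean <= 0):
        raise UninetError("cv² requires positive mean weights")
    var = W.weights.var(axis=1)
    return var / mean**2
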