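"""Canonical covariance and correlation analysis, weighted and binary.

Weighted canonical covariance analysis (partial least squares
correlation) finds coefficient pairs (a_h, b_h) maximizing
Σ_h a_hᵀ X Yᵀ b_h under unit-norm constraints — the top singular pairs of
the cross-covariance Z = XYᵀ.  The binary variant constrains the
coefficients to 0/1 module indicators and reduces to k-means
co-clustering of Z with co-Loyvain.  Canonical correlation analysis is
recovered by whitening both sides before the decomposition and
back-transforming the coefficients (which generally destroys binarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import UninetError
from .loyvain import LoyvainConfig, co_loyvain


@dataclass
class CanonicalResult:
    coeffs_a: np.ndarray  # pa x k
    coeffs_b: np.ndarray  # pb x k
    components_a: np.ndarray | None  # k x n projected series
    components_b: np.ndarray | None
    pair_values: np.ndarray
    binary: bool = False


def _center_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=1, keepdims=True)


def _sign_fix_pairs(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argmax(np.abs(A), axis=0)
    signs = np.sign(A[idx, np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    return A * signs, B * signs


def canonical_covariance(X: np.ndarray, Y: np.ndarray, k: int) -> CanonicalResult:
    """Top-k singular pairs of the cross-covariance Z = XYᵀ.

    X is pa x n and Y is pb x n (rows = features, columns = data points);
    both are row-centered before forming Z.  Pair values are the singular
    values, in descending order.
    """
    X, Y = _center_rows(X), _center_rows(Y)
    if X.shape[1] != Y.shape[1]:
        raise UninetError("X and Y must share the number of data points")
    if k > min(X.shape[0], Y.shape[0]):
        raise UninetError("k exceeds the smaller feature count")
    Z = X @ Y.T
    U, s, Vt = linalg.svd(Z, full_matrices=False)
    A, B = _sign_fix_pairs(U[:, :k], Vt[:k].T)
    return CanonicalResult(
        coeffs_a=A,
        coeffs_b=B,
        components_a=A.T @ X,
        components_b=B.T @ Y,
        pair_values=s[:k],
        binary=False,
    )


def binary_canonical_covariance(
    Z: np.ndarray,
    k: int,
    config: LoyvainConfig | None = None,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> CanonicalResult:
    """Canonical covariance analysis with binary (module-indicator) coefficients.

    Co-Loyvain co-clusters the rows and columns of Z; the indicator
    columns are the coefficients and each pair value is that pair's
    normalized co-clustering term m_ahᵀ Z m_bh / (N_ah N_bh)^(1/2).  When
    the underlying data matrices are given, the components are sums of
    data rows over each module's nonzero features.
    """
    Z = np.asarray(Z, dtype=float)
    if k > min(Z.shape):
        raise UninetError("k exceeds the smaller dimension of Z")
    config = config or LoyvainConfig(k=k, replicates=20)
    Pa, Pb, _ = co_loyvain(Z, k, k, config)
    Ma, Mb = Pa.indicator(), Pb.indicator()
    pair = np.einsum("ih,ij,jh->h", Ma, Z, Mb, optimize=True)
    values = pair / np.sqrt(Pa.sizes.astype(float) * Pb.sizes)
    order = np.argsort(values)[::-1]
    Ma, Mb, values = Ma[:, order], Mb[:, order], values[order]
    comps_a = Ma.T @ _center_rows(X) if X is not None else None
    comps_b = Mb.T @ _center_rows(Y) if Y is not None else None
    return CanonicalResult(Ma, Mb, comps_a, comps_b, values, binary=True)


def _inv_sqrt(S: np.ndarray, ridge: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric square root and inverse square root of S + ridge·I."""
    vals, vecs = linalg.eigh(S)
    vals = vals + ridge
    if vals.min() <= 0:
        raise UninetError(
            "whitening matrix is singular; pass a positive ridge value"
        )
    root = (vecs * np.sqrt(vals)) @ vecs.T
    inv_root = (vecs / np.sqrt(vals)) @ vecs.T
    return root, inv_root


def canonical_correlation(
    X: np.ndarray, Y: np.ndarray, k: int, ridge: float | None = None
) -> CanonicalResult:
    """Canonical correlation via whitening of both sides.

    Decomposes Z̃ = (XXᵀ)^(−1/2) XYᵀ (YYᵀ)^(−1/2) and back-transforms the
    singular pairs through the inverse whitening.  The default ridge is
    1e-6·trace/p per side, which stabilizes the whitening when features
    outnumber samples.  Pair values are canonical correlations in [0, 1].
    """
    X, Y = _center_rows(X), _center_rows(Y)
    if X.shape[1] != Y.shape[1]:
        raise UninetError("X and Y must share the number of data points")
    if k > min(X.shape[0], Y.shape[0]):
        raise UninetError("k exceeds the smaller feature count")
    Sx, Sy = X @ X.T, Y @ Y.T
    ridge_x = 1e-6 * np.trace(Sx) / Sx.shape[0] if ridge is None else ridge
    ridge_y = 1e-6 * np.trace(Sy) / Sy.shape[0] if ridge is None else ridge
    _, Wx = _inv_sqrt(Sx, ridge_x)
    _, Wy = _inv_sqrt(Sy, ridge_y)
    Zt = Wx @ (X @ Y.T) @ Wy
    U, s, Vt = linalg.svd(Zt, full_matrices=False)
    A, B = _sign_fix_pairs(Wx @ U[:, :k], Wy @ Vt[:k].T)
    return CanonicalResult(
        coeffs_a=A,
        coeffs_b=B,
        components_a=A.T @ X,
        components_b=B.T @ Y,
        pair_values=np.clip(s[:k], 0.0, 1.0),
        binary=False,
    )
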