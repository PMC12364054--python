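"""Partition-quality objectives for networks, data matrices and bipartite matrices.

The family is built from within-module weight sums m_hᵀ C m_h with
different normalizations and residualizations:

==============================  =============================================
k-means coherence               Σ_h (1/N_h) m_hᵀ C m_h
k-means distance                n − coherence      (unit-diagonal C)
modularity                      (1/Σc) Σ_h m_hᵀ C⋄ m_h
k-modularity (degree-corr.)     (1/Σc) Σ_h (1/N_h) m_hᵀ C⋄ m_h
k-modularity (density-corr.)    (1/Σc) Σ_h (1/N_h) m_hᵀ C m_h − 1/n
normalized cut (association)    Σ_h (1/D_h) m_hᵀ C m_h
s-modularity                    (1/Σc) Σ_h (1/D_h) m_hᵀ C⋄ m_h
==============================  =============================================

Density-corrected k-modularity is an affine function of k-means coherence;
s-modularity equals (normalized cut − 1)/Σc; degree-corrected k-modularity
is (1/Σc) times coherence computed on the degree-corrected network.  The
diagonal entries of C are counted in every within-module sum, exactly as
in the local update rules of the Loyvain optimizer.
"""

from __future__ import annotations

import numpy as np

from .core import DataMatrix, Network, Partition, UninetError
from .residual import degree_correct


def _within_sums(
    N: Network | DataMatrix | np.ndarray, P: Partition
) -> np.ndarray:
    """Within-module weight sums m_hᵀ C m_h for every module h.

    Accepts a network, a raw symmetric matrix, or a rescaled data matrix;
    the data-matrix path computes ‖X m_h‖² without materializing C.
    """
    M = P.indicator()
    if isinstance(N, DataMatrix):
        if not N.rescaled:
            raise UninetError("data-matrix objectives require rescaled data")
        XM = N.values @ M
        return np.einsum("ij,ij->j", XM, XM)
    W = N.weights if isinstance(N, Network) else np.asarray(N, dtype=float)
    return np.einsum("ih,ij,jh->h", M, W, M, optimize=True)


def kmeans_objective(
    N: Network | DataMatrix, P: Partition, form: str = "coherence"
) -> float:
    """k-means objective: coherence Σ_h m_hᵀCm_h/N_h, or distance n − coherence."""
    coherence = float((_within_sums(N, P) / P.sizes).sum())
    if form == "coherence":
        return coherence
    if form == "distance":
        return P.n - coherence
    raise UninetError(f"unknown k-means form: {form!r}")


def modularity(N: Network, P: Partition) -> float:
    """Degree-corrected modularity (1/Σc) Σ_h m_hᵀ C⋄ m_h."""
    if N.total_weight <= 0:
        raise UninetError("modularity requires positive total weight")
    resid = degree_correct(N).weights
    return float(_within_sums(resid, P).sum() / N.total_weight)


def k_modularity(
    N: Network, P: Partition, density_corrected: bool = False
) -> float:
    """Size-normalized modularity.

    Degree-corrected form uses C⋄; the density-corrected form subtracts
    the constant-density expectation, which reduces to an affine function
    of the k-means coherence: (1/Σc)·coherence − 1/n.
    """
    if N.total_weight <= 0:
        raise UninetError("k-modularity requires positive total weight")
    if density_corrected:
        coherence = (_within_sums(N, P) / P.sizes).sum()
        return float(coherence / N.total_weight - 1.0 / N.n)
    resid = degree_correct(N).weights
    return float((_within_sums(resid, P) / P.sizes).sum() / N.total_weight)


def normalized_cut(N: Network, P: Partition) -> float:
    """Normalized-association objective Σ_h (1/D_h) m_hᵀ C m_h."""
    D = P.module_degrees(N)
    if np.any(D <= 0):
        raise UninetError("normalized cut requires positive module degrees")
    return float((_within_sums(N, P) / D).sum())


def s_modularity(N: Network, P: Partition) -> float:
    """Degree-normalized modularity (1/Σc) Σ_h (1/D_h) m_hᵀ C⋄ m_h.

    Affinely equivalent to the normalized cut: equals (ncut − 1)/Σc.
    """
    D = P.module_degrees(N)
    if np.any(D <= 0):
        raise UninetError("s-modularity requires positive module degrees")
    resid = degree_correct(N).weights
    return float((_within_sums(resid, P) / D).sum() / N.total_weight)


def co_objectives(
    Z: np.ndarray, Pa: Partition, Pb: Partition, variant: str = "kmeans"
) -> float:
    """Bipartite co-clustering objectives.

    kmeans variant:   Σ_h m_ahᵀ Z m_bh / (N_ah N_bh)^(1/2)
    spectral variant: Σ_h m_ahᵀ Z m_bh / (D_ah D_bh)^(1/2)
    """
    Z = np.asarray(Z, dtype=float)
    if Pa.n != Z.shape[0] or Pb.n != Z.shape[1]:
        raise UninetError("partition sizes must match the bipartite matrix")
    if Pa.k != Pb.k:
        raise UninetError("row and column partitions must share k")
    Ma, Mb = Pa.indicator(), Pb.indicator()
    pair_sums = np.einsum("ih,ij,jh->h", Ma, Z, Mb, optimize=True)
    if variant == "kmeans":
        denom = np.sqrt(Pa.sizes.astype(float) * Pb.sizes)
    elif variant == "spectral":
        Da = Ma.T @ Z.sum(axis=1)
        Db = Mb.T @ Z.sum(axis=0)
        if np.any(Da <= 0) or np.any(Db <= 0):
            raise UninetError("spectral co-objective requires positive module degrees")
        denom = np.sqrt(Da * Db)
    else:
        raise UninetError(f"unknown co-objective variant: {variant!r}")
    return float((pair_sums / denom).sum())


def node_module_correlation(X: DataMatrix, P: Partition) -> np.ndarray:
    """Pearson correlation of each node series with each module-mean series.

    Returns an n x k matrix; entry (i, h) is corr(x_i, x̄_h).
    """
    if not X.rescaled:
        raise UninetError("node_module_correlation requires rescaled data")
    M = P.indicator()
    centroids = X.values @ M / P.sizes  # p x k module-mean series
    Xc = X.values - X.values.mean(axis=0)
    Fc = centroids - centroids.mean(axis=0)
    fn = np.linalg.norm(Fc, axis=0)
    if np.any(fn < 1e-12):
        raise UninetError("a module-mean series is constant")
    xn = np.linalg.norm(Xc, axis=0)
    return (Xc / xn).T @ (Fc / fn)


def percent_improvement(new: float, old: float) -> float:
    """Signed percentage improvement 100·(new − old)/old."""
    if old == 0:
        raise UninetError("percent improvement undefined for old = 0")
    return 100.0 * (new - old) / old
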