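"""Domain containers and canonical constructions shared by all analyses.

The central objects are

``DataMatrix``
    A p x n matrix of p features (e.g. time points) by n nodes.  After
    canonical rescaling every column has unit Euclidean norm and mean
    (2p)^(-1/2), which maps inner products onto rescaled Pearson
    correlations in [0, 1].

``Network``
    A symmetric non-negative n x n weighted matrix.  Correlation-flavored
    networks have a unit diagonal; structural-flavored networks have a
    zero diagonal.

``EigenSystem``
    An eigendecomposition with descending eigenvalues and a deterministic
    sign convention (largest-magnitude entry of each eigenvector positive).

``Partition``
    A hard assignment of n nodes into k non-empty modules, stored as
    0-based labels internally with 1-based labels at the file boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

SYMMETRY_RTOL = 1e-10


class UninetError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class DataMatrix:
    """p features x n nodes data matrix.

    Parameters
    ----------
    values
        The (p, n) array.  Rows are features (e.g. time points), columns
        are nodes.
    rescaled
        Whether the columns have been canonically rescaled (unit norm,
        mean (2p)^(-1/2)).
    """

    values: np.ndarray
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise UninetError("data matrix must be two-dimensional")
        p, n = self.values.shape
        if p < 2 or n < 2:
            raise UninetError(f"need p >= 2 and n >= 2, got shape {(p, n)}")
        if not np.all(np.isfinite(self.values)):
            raise UninetError("data matrix contains non-finite entries")
        if self.rescaled:
            norms = np.linalg.norm(self.values, axis=0)
            means = self.values.mean(axis=0)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise UninetError("rescaled flag set but column norms differ from 1")
            if not np.allclose(means, (2 * p) ** -0.5, atol=1e-8):
                raise UninetError(
                    "rescaled flag set but column means differ from (2p)^(-1/2)"
                )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def global_signal(self) -> np.ndarray:
        """Mean-activity signal x̄ = (1/n) X 1."""
        return self.values.mean(axis=1)


@dataclass
class Network:
    """Symmetric non-negative weighted network.

    ``flavor`` is one of ``correlation`` (unit diagonal), ``structural``
    (zero diagonal), ``co_neighbor`` (integer weights, zero diagonal) or
    ``knn_binary`` (0/1 weights, zero diagonal).  Degree and total weight
    are cached on construction.
    """

    weights: np.ndarray
    flavor: str = "structural"
    degree: np.ndarray = field(init=False, repr=False)
    total_weight: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.degree = self.weights.sum(axis=1)
        self.total_weight = float(self.degree.sum())

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def mean_weight(self) -> float:
        """Mean connection value c̄ = Σc / n²."""
        return self.total_weight / self.n**2

    def degree_deviation(self) -> np.ndarray:
        """Deviation δ = d − n c̄ 1 of degrees around their mean."""
        return self.degree - self.degree.mean()


@dataclass
class EigenSystem:
    """Eigenvectors (columns) and descending eigenvalues of a symmetric matrix."""

    vectors: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) > 1e-12):
            raise UninetError("eigenvalues must be sorted in non-increasing order")


@dataclass
class Partition:
    """Hard assignment of n nodes to k modules (0-based labels internally)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise UninetError("labels must be a vector")
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= self.k
        ):
            raise UninetError("labels out of range for k modules")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise UninetError("every module must be non-empty")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Module sizes N_h."""
        return np.bincount(self.labels, minlength=self.k)

    def indicator(self) -> np.ndarray:
        """Binary n x k indicator matrix M."""
        M = np.zeros((self.n, self.k))
        M[np.arange(self.n), self.labels] = 1.0
        return M

    def module_degrees(self, network: Network) -> np.ndarray:
        """Module degrees D_h = m_hᵀ d with respect to ``network``."""
        return self.indicator().T @ network.degree


def rescale_columns(raw: DataMatrix | np.ndarray) -> DataMatrix:
    """Canonically rescale columns to unit norm and mean (2p)^(-1/2).

    Each raw column χ_i maps to

        x_i = (1/2)^(1/2) normalize(χ_i) + (2p)^(-1/2) 1,

    where ``normalize`` centers to mean 0 and scales to norm 1.  The
    inner products of the rescaled columns equal (corr(χ_i, χ_j) + 1)/2,
    i.e. Pearson correlations mapped onto [0, 1].
    """
    if not isinstance(raw, DataMatrix):
        raw = DataMatrix(raw)
    X = raw.values
    p = X.shape[0]
    centered = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    bad = np.flatnonzero(norms < 1e-12 * max(1.0, np.abs(X).max()))
    if bad.size:
        raise UninetError(f"constant column(s) cannot be rescaled: index {bad[0]}")
    rescaled = np.sqrt(0.5) * centered / norms + (2 * p) ** -0.5
    return DataMatrix(rescaled, rescaled=True)


def correlation_network(X: DataMatrix) -> Network:
    """Correlation network C = XᵀX of a rescaled data matrix."""
    if not isinstance(X, DataMatrix) or not X.rescaled:
        raise UninetError("correlation_network requires a rescaled DataMatrix")
    C = X.values.T @ X.values
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    np.clip(C, 0.0, 1.0, out=C)
    return Network(C, flavor="correlation")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigensystem(N: Network | np.ndarray, k: int | None = None) -> EigenSystem:
    """Eigendecomposition with descending eigenvalues and fixed signs.

    ``k = None`` returns the full decomposition.  Asymmetry beyond the
    relative tolerance is an error.
    """
    W = N.weights if isinstance(N, Network) else np.asarray(N, dtype=float)
    scale = max(np.abs(W).max(), 1e-300)
    if np.abs(W - W.T).max() > 1e-8 * scale:
        raise UninetError("eigensystem requires a symmetric matrix")
    values, vectors = linalg.eigh(0.5 * (W + W.T))
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = _fix_signs(vectors[:, order])
    if k is not None:
        values = values[:k]
        vectors = vectors[:, :k]
    return EigenSystem(vectors, values)


def validate_network(raw: np.ndarray, flavor: str = "structural") -> Network:
    """Validate, symmetrize and wrap a raw square matrix as a Network.

    A tiny asymmetry (below the relative symmetry tolerance) is averaged
    away; larger asymmetries raise.  Correlation flavor enforces a unit
    diagonal (with a logged warning if the input diagonal deviates only
    slightly); structural, co_neighbor and knn_binary flavors enforce a
    zero diagonal.
    """
    W = np.asarray(raw, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise UninetError("network matrix must be square")
    if W.shape[0] < 2:
        raise UninetError("network needs at least 2 nodes")
    if not np.all(np.isfinite(W)):
        raise UninetError("network contains non-finite entries")
    scale = max(np.abs(W).max(), 1e-300)
    asym = np.abs(W - W.T).max()
    if asym > SYMMETRY_RTOL * scale and asym > 1e-12:
        raise UninetError(f"matrix asymmetry {asym:.3g} exceeds tolerance")
    W = 0.5 * (W + W.T)
    if W.min() < -1e-12:
        raise UninetError("negative weights are unsupported for non-residual flavors")
    np.clip(W, 0.0, None, out=W)
    diag = np.diagonal(W)
    if flavor == "correlation":
        if np.abs(diag - 1.0).max() > 1e-4:
            raise UninetError("correlation flavor requires a (near-)unit diagonal")
        if np.abs(diag - 1.0).max() > 1e-12:
            logger.warning("correlation diagonal deviates from 1; resetting")
        np.fill_diagonal(W, 1.0)
    elif flavor in ("structural", "co_neighbor", "knn_binary"):
        if np.abs(diag).max() > 1e-4 * scale:
            raise UninetError(f"{flavor} flavor requires a zero diagonal")
        if np.abs(diag).max() > 0:
            logger.warning("%s diagonal deviates from 0; resetting", flavor)
        np.fill_diagonal(W, 0.0)
    else:
        raise UninetError(f"unknown network flavor: {flavor!r}")
    return Network(W, flavor=flavor)
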