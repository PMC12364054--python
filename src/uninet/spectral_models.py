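"""Eigenspectrum shrinkage and proximity-driven network growth models.

Cubic shrinkage fits a cubic polynomial to every tail of the descending
eigenspectrum, picks the knee of the fit-error curve with a kneedle-style
objective, and re-evaluates the whole spectrum from the knee's cubic —
weakening inflated leading eigenvalues toward the bulk while keeping the
eigenvectors fixed.

The growth family models how a spatially embedded network densifies:

* original (stochastic): one binary edge per step, drawn with probability
  ∝ proximity^α · co-neighbor-count^β over unconnected pairs;
* modified (deterministic, weighted):
  Ŵ(τ+1) = γ(ρ Φ∘α + (1−ρ) Ŵ(τ)²) + Ŵ(τ);
* eigenvalue quadratic map: when the seed shares eigenvectors with Φ∘α
  the modified model reduces to λ(τ+1) = γ((1−ρ)λ² + ρλ*) + λ per mode,
  with the ρ = 1 closed form Ŵ(τ) = Ŵ(0) + τγΦ∘α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Network, UninetError, eigensystem


@dataclass
class ShrinkResult:
    knee_index: int
    fitted_eigenvalues: np.ndarray
    shrunken_matrix: np.ndarray
    rmse_curve: np.ndarray
    kneedle_curve: np.ndarray


def cubic_shrink(
    eigenvalues: np.ndarray, vectors: np.ndarray | None = None
) -> ShrinkResult:
    """Cubic tail-fit shrinkage of a descending eigenspectrum.

    For each candidate start index i a cubic is fit to eigenvalues i..n
    against their rank; the knee maximizes the kneedle-style objective
    (RMSE₀ − RMSE_i)/RMSE₀ − i/(n−1).  The full spectrum is re-evaluated
    from the knee's cubic, and the matrix is rebuilt with the original
    eigenvectors when they are provided.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    n = lam.size
    if n < 8:
        raise UninetError("need at least 8 eigenvalues for stable cubic fits")
    idx = np.arange(n, dtype=float)
    n_cand = n - 3  # need >= 4 points for a cubic
    rmse = np.empty(n_cand)
    coeffs = []
    for i in range(n_cand):
        c = np.polyfit(idx[i:], lam[i:], 3)
        resid = np.polyval(c, idx[i:]) - lam[i:]
        rmse[i] = np.sqrt(np.mean(resid**2))
        coeffs.append(c)
    if rmse[0] <= 0:
        knee = 0
        kneedle = np.zeros(n_cand)
    else:
        kneedle = (rmse[0] - rmse) / rmse[0] - idx[:n_cand] / (n - 1)
        knee = int(np.argmax(kneedle))
    fitted = np.polyval(coeffs[knee], idx)
    shrunk = None
    if vectors is not None:
        V = np.asarray(vectors, dtype=float)
        shrunk = (V * fitted) @ V.T
        shrunk = 0.5 * (shrunk + shrunk.T)
    return ShrinkResult(knee, fitted, shrunk, rmse, kneedle)


def shrink_network(N: Network | np.ndarray) -> tuple[np.ndarray, ShrinkResult]:
    """Shrink a symmetric matrix's eigenspectrum; eigenvectors unchanged."""
    es = eigensystem(N)
    res = cubic_shrink(es.values, es.vectors)
    return res.shrunken_matrix, res


def proximity_matrix(
    coords: np.ndarray, alpha: float = 1.0, form: str = "exponential"
) -> np.ndarray:
    """Spatial proximity Φ∘α from node coordinates.

    ``exponential`` (default): exp(−dist/mean-dist); ``inverse``: d̄/dist.
    The result is raised elementwise to α, symmetric, zero diagonal.
    Coincident points get the maximum finite off-diagonal proximity.
    """
    pts = np.asarray(coords, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    off = ~np.eye(pts.shape[0], dtype=bool)
    dbar = dist[off].mean()
    if dbar <= 0:
        raise UninetError("all points coincide; proximity undefined")
    dup = off & (dist <= 0)
    if np.any(dup):
        warnings.warn("duplicate coordinates; capping proximity at the maximum")
    with np.errstate(divide="ignore"):
        if form == "exponential":
            phi = np.exp(-dist / dbar)
        elif form == "inverse":
            phi = np.where(dist > 0, dbar / np.where(dist > 0, dist, 1.0), np.inf)
        else:
            raise UninetError(f"unknown proximity form {form!r}")
    finite_max = phi[off & np.isfinite(phi)].max()
    phi = np.where(np.isfinite(phi), phi, finite_max)
    phi[dup] = finite_max
    np.fill_diagonal(phi, 0.0)
    return phi**alpha


@dataclass
class GrowthConfig:
    proximity: np.ndarray  # Φ∘α (already exponentiated), zero diagonal
    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.5
    rate: float = 0.1  # γ
    steps: int = 10
    edge_target: int | None = None
    seed_matrix: np.ndarray | None = None
    epsilon: float = 0.0  # probability floor for zero-similarity pairs
    seed: int | None = None

    def __post_init__(self) -> None:
        phi = np.asarray(self.proximity, dtype=float)
        if np.abs(phi - phi.T).max() > 1e-10 or phi.min() < 0:
            raise UninetError("proximity must be symmetric and non-negative")
        self.proximity = phi


def growth_original(config: GrowthConfig) -> np.ndarray:
    """Stochastic binary growth: one edge per step.

    Each step computes the co-neighbor counts 𝒲 = W̃² of the current
    binary network, sets π ∝ Φ^α ⊙ (𝒲 + ε)^β over unconnected pairs, and
    adds a single edge sampled from π, until the edge target is reached.
    """
    phi = config.proximity
    n = phi.shape[0]
    if config.seed_matrix is None:
        raise UninetError("original growth model needs a binary seed matrix")
    W = (np.asarray(config.seed_matrix, dtype=float) > 0).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    e0 = int(W.sum() // 2)
    if config.edge_target is None or config.edge_target < e0:
        raise UninetError("edge target must be at least the seed edge count")
    rng = np.random.default_rng(config.seed)
    iu = np.triu_indices(n, 1)
    for _ in range(config.edge_target - e0):
        conei = W @ W
        weight = phi[iu] ** 1.0 * (conei[iu] + config.epsilon) ** config.beta
        weight = np.where(W[iu] > 0, 0.0, weight)
        total = weight.sum()
        if total <= 0:
            raise UninetError(
                "all candidate pairs have zero probability; "
                "set a positive epsilon floor"
            )
        pick = rng.choice(weight.size, p=weight / total)
        i, j = iu[0][pick], iu[1][pick]
        W[i, j] = W[j, i] = 1.0
    return W


def growth_modified(config: GrowthConfig) -> list[np.ndarray]:
    """Deterministic weighted growth trajectory (length steps + 1).

    Ŵ(τ+1) = γ(ρ Φ∘α + (1−ρ) Ŵ(τ)²) + Ŵ(τ); the seed defaults to the
    shrunken proximity matrix.
    """
    phi = config.proximity
    if config.seed_matrix is not None:
        W = np.asarray(config.seed_matrix, dtype=float).copy()
    else:
        W, _ = shrink_network(phi)
    traj = [W.copy()]
    for _ in range(config.steps):
        W = config.rate * (config.rho * phi + (1 - config.rho) * W @ W) + W
        W = 0.5 * (W + W.T)
        traj.append(W.copy())
    return traj


def growth_eigenmap(
    lam0: np.ndarray, lam_star: np.ndarray, rho: float, rate: float, steps: int
) -> np.ndarray:
    """Quadratic eigenvalue map λ(τ+1) = γ((1−ρ)λ² + ρλ*) + λ.

    Returns the (steps + 1) x n trajectory.  When the seed matrix shares
    the eigenvectors of Φ∘α this reproduces the modified growth model
    mode by mode; at ρ = 1 the closed form is λ(τ) = λ(0) + τγλ*.
    """
    lam = np.asarray(lam0, dtype=float).copy()
    lam_star = np.asarray(lam_star, dtype=float)
    out = [lam.copy()]
    for _ in range(steps):
        lam = rate * ((1 - rho) * lam**2 + rho * lam_star) + lam
        out.append(lam.copy())
    return np.array(out)
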