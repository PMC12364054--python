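"""m-umap: modularity with Cauchy similarity, embedded on a sphere.

The objective couples a symmetric binary κ-NN graph ℭ (degree-corrected
with resolution γ, the analogue of UMAP's negative-sampling rate) to a
spherical embedding U through the Cauchy similarity

    φ_ij = (1 + α H_ij^β)^(−1),  H = 2(1 − UUᵀ),

and minimizes  E(U) = −Σ_ij (ℭ_ij − γ d_i d_j / Σc) φ_ij.

Restricted to binary one-hot embeddings, φ is 1 within modules and the
constant δ = (1 + α 2^β)^(−1) between them, and E reduces (up to an
affine transform) to the negative degree-corrected modularity — so the
binary variant of m-umap is exactly modularity maximization.  The
continuous variant is optimized by Riemannian projected gradient descent
with a backtracking line search and row-renormalization retraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Network, Partition, UninetError, eigensystem
from .loyvain import ClusterResult, louvain_modularity


@dataclass
class MumapConfig:
    d: int = 3
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    max_iter: int = 500
    step_size: float = 1.0
    tol: float = 1e-8
    seed: int | None = None
    init: str = "fib_maximin"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise UninetError("alpha, beta, gamma must be positive")
        if self.d < 2:
            raise UninetError("embedding dimension must be at least 2")

    @property
    def delta(self) -> float:
        """Between-module Cauchy similarity of one-hot embeddings."""
        return 1.0 / (1.0 + self.alpha * 2.0**self.beta)


@dataclass
class SphericalEmbedding:
    coords: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise UninetError("embedding rows must have unit norm")


def _degree_corrected(knn: Network, gamma: float) -> np.ndarray:
    d = knn.degree
    return knn.weights - gamma * np.outer(d, d) / knn.total_weight


def cauchy_similarity(
    U: np.ndarray | SphericalEmbedding, alpha: float = 1.0, beta: float = 1.0
) -> np.ndarray:
    """Elementwise φ = (1 + α H^β)^(−1) with H = 2(1 − UUᵀ) on the sphere."""
    coords = U.coords if isinstance(U, SphericalEmbedding) else np.asarray(U, float)
    norms = np.linalg.norm(coords, axis=1)
    if np.abs(norms - 1.0).max() > 1e-8:
        raise UninetError("Cauchy similarity requires unit-norm rows")
    H = np.clip(2.0 * (1.0 - coords @ coords.T), 0.0, None)
    return 1.0 / (1.0 + alpha * H**beta)


def _objective_general(cres: np.ndarray, coords: np.ndarray, cfg: MumapConfig) -> float:
    """Objective with H as general pairwise squared Euclidean distance.

    Coincides with the spherical form on unit-norm rows but stays defined
    off the sphere, which the finite-difference gradient check exploits.
    """
    sq = np.sum(coords**2, axis=1)
    H = np.clip(sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T, 0.0, None)
    phi = 1.0 / (1.0 + cfg.alpha * H**cfg.beta)
    return float(-(cres * phi).sum())


def mumap_objective(
    knn: Network, U: np.ndarray | SphericalEmbedding, config: MumapConfig | None = None
) -> float:
    """m-umap objective −Σ_ij (ℭ_ij − γ d_i d_j/Σc) φ_ij (lower is better)."""
    cfg = config or MumapConfig()
    coords = U.coords if isinstance(U, SphericalEmbedding) else np.asarray(U, float)
    if coords.shape[0] != knn.n:
        raise UninetError("embedding and graph sizes differ")
    phi = cauchy_similarity(coords, cfg.alpha, cfg.beta)
    return float(-(_degree_corrected(knn, cfg.gamma) * phi).sum())


def mumap_gradient(
    knn: Network, U: np.ndarray | SphericalEmbedding, config: MumapConfig | None = None
) -> np.ndarray:
    """Full Euclidean gradient of the m-umap objective.

    With coef = ℭ⋄ ⊙ H^(β−1) ⊙ (1+αH^β)^(−2) (zero diagonal — H_ii ≡ 0
    contributes nothing), the derivative of −Σ c⋄_ij φ_ij is

        ∂E/∂u_i = 4αβ Σ_j coef_ij (u_i − u_j),

    i.e. −4αβ (coef − diag(coef·1)) U.  The diag(coef·1) U part is purely
    radial on the sphere, so the compact attraction/repulsion form
    −4αβ·coef·U is equivalent after tangent projection; the full form is
    returned so it matches central differences off the sphere too.
    """
    cfg = config or MumapConfig()
    coords = U.coords if isinstance(U, SphericalEmbedding) else np.asarray(U, float)
    cres = _degree_corrected(knn, cfg.gamma)
    sq = np.sum(coords**2, axis=1)
    H = np.clip(sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T, 0.0, None)
    with np.errstate(divide="ignore"):
        Hpow = np.where(H > 0, H ** (cfg.beta - 1.0), 1.0 if cfg.beta == 1 else 0.0)
    coef = cres * Hpow / (1.0 + cfg.alpha * H**cfg.beta) ** 2
    np.fill_diagonal(coef, 0.0)
    return 4.0 * cfg.alpha * cfg.beta * (
        coef.sum(axis=1)[:, None] * coords - coef @ coords
    )


def binary_mumap(
    knn: Network, seed: int | None = None, replicates: int = 100
) -> ClusterResult:
    """Binary m-umap: Louvain modularity maximization of ℭ.

    κ of the underlying graph indirectly controls the number of modules.
    """
    return louvain_modularity(knn, seed=seed, replicates=replicates, finaltune=True)


def fibonacci_sphere(k: int) -> np.ndarray:
    """k near-uniform points on the unit 2-sphere (Fibonacci lattice)."""
    i = np.arange(k) + 0.5
    phi_angle = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / k
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi_angle), r * np.sin(phi_angle), z])


def _row_normalize(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def init_embedding(
    knn: Network,
    partition: Partition | None,
    method: str = "fib_maximin",
    d: int = 3,
    seed: int | None = None,
) -> SphericalEmbedding:
    """Initial spherical coordinates.

    spectral_node: row-normalized eigenvectors 2..d+1 of ℭ.
    spectral_module: row-normalized eigenvectors 1..d of Mᵀℭ⋄M, nodes
    inheriting their module's position.
    fib_maximin: modules placed on Fibonacci points on the 2-sphere —
    the largest-degree module on the most central point, the rest
    farthest-first; nodes inherit module positions.  For d ≠ 3 the
    Fibonacci lattice is replaced by farthest-first placement on random
    unit vectors.
    """
    rng = np.random.default_rng(seed)
    if method == "spectral_node":
        es = eigensystem(knn, k=d + 1)
        return SphericalEmbedding(_row_normalize(es.vectors[:, 1 : d + 1]))
    if partition is None:
        raise UninetError(f"{method} initialization requires a partition")
    M = partition.indicator()
    k = partition.k
    if method == "spectral_module":
        cres = _degree_corrected(knn, 1.0)
        es = eigensystem(M.T @ cres @ M, k=min(d, k))
        pos = _row_normalize(es.vectors[:, :d])
        if pos.shape[1] < d:
            pos = np.pad(pos, ((0, 0), (0, d - pos.shape[1])))
            pos = _row_normalize(pos)
        return SphericalEmbedding(pos[partition.labels])
    if method == "fib_maximin":
        if d == 3:
            points = fibonacci_sphere(max(k, 2))
        else:
            raw = rng.standard_normal((max(4 * k, 16), d))
            points = _row_normalize(raw)
        module_deg = M.T @ knn.degree
        # most central point = highest mean similarity to all points
        centrality = (points @ points.T).mean(axis=1)
        pos = np.zeros((k, d))
        assigned_points: list[int] = [int(np.argmax(centrality))]
        order = np.argsort(module_deg)[::-1]
        pos[order[0]] = points[assigned_points[0]]
        # remaining modules, lowest-degree first, farthest-first placement
        for h in order[1:][::-1]:
            sims = points @ points[assigned_points].T
            sims_max = sims.max(axis=1)
            sims_max[assigned_points] = np.inf
            nxt = int(np.argmin(sims_max))
            assigned_points.append(nxt)
            pos[h] = points[nxt]
        return SphericalEmbedding(pos[partition.labels])
    raise UninetError(f"unknown initialization {method!r}")


def mumap_fit(
    knn: Network,
    config: MumapConfig | None = None,
    partition: Partition | None = None,
) -> SphericalEmbedding:
    """Optimize the spherical embedding by projected gradient descent.

    Modules (from binary m-umap unless given) seed the initialization.
    Each iteration projects the Euclidean gradient onto the tangent
    spaces of the sphere, takes a backtracking step, and retracts by row
    renormalization; accepted steps never increase the objective.
    Disconnected graph components are allowed — the degree-corrected null
    term still couples them repulsively and the sphere bounds the layout.
    """
    cfg = config or MumapConfig()
    if partition is None:
        partition = binary_mumap(knn, seed=cfg.seed, replicates=10).partition
    emb = init_embedding(knn, partition, cfg.init, cfg.d, cfg.seed)
    # jitter identical module positions so nodes can separate within modules
    rng = np.random.default_rng(cfg.seed)
    coords = emb.coords + 0.05 * rng.standard_normal(emb.coords.shape)
    coords = _row_normalize(coords)
    trace = [mumap_objective(knn, coords, cfg)]
    step = cfg.step_size
    for _ in range(cfg.max_iter):
        grad = mumap_gradient(knn, coords, cfg)
        tangent = grad - np.sum(grad * coords, axis=1, keepdims=True) * coords
        gnorm = np.linalg.norm(tangent)
        if gnorm < 1e-12:
            break
        accepted = False
        while step > 1e-12:
            trial = _row_normalize(coords - step * tangent)
            val = mumap_objective(knn, trial, cfg)
            if val <= trace[-1]:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        coords = trial
        trace.append(val)
        step = min(step * 2.0, cfg.step_size)
        if len(trace) > 1 and trace[-2] - trace[-1] < cfg.tol * max(1.0, abs(trace[-2])):
            break
    return SphericalEmbedding(coords, objective_trace=trace)


def embedding_fidelity(
    native_sim: Network, U: np.ndarray | SphericalEmbedding, P: Partition
) -> float:
    """Embedding fidelity: |corr| of node-to-module-centroid distances.

    The native vector holds each node's mean similarity to each module's
    members; the embedding vector holds each node's Euclidean distance to
    each module's centroid.  Returns the absolute Pearson correlation of
    the two flattened n·k vectors.
    """
    coords = U.coords if isinstance(U, SphericalEmbedding) else np.asarray(U, float)
    M = P.indicator()
    native = native_sim.weights @ M / P.sizes
    centroids = (M.T @ coords) / P.sizes[:, None]
    diff = coords[:, None, :] - centroids[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    a, b = native.ravel(), dist.ravel()
    if a.std() < 1e-15 or b.std() < 1e-15:
        raise UninetError("degenerate (constant) distance vectors")
    return float(abs(np.corrcoef(a, b)[0, 1]))
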