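"""Seeded generators of synthetic inputs with planted statistical structure.

These generators emulate the statistical features of brain-imaging
inputs that the analyses in this package assume: correlation-type data
with planted modules and a shared global component, structural-type
networks with distance-decay weights, data whose leading eigenvectors
have a controlled correlation, and time series with prescribed
node-to-module correlations.  All generators are pure functions of their
parameters and seed; latent factors are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, Network, Partition, UninetError, rescale_columns


@dataclass
class SynthSpec:
    """Targets for the planted-module time-series generator.

    ``within_corr`` / ``between_corr`` are target raw Pearson levels for
    node pairs inside one module / across modules; ``global_strength`` is
    the loading on a shared global signal (its square contributes to the
    between-module correlation and must not exceed it); ``noise_sd``
    scales the idiosyncratic residual.
    """

    n: int = 60
    p: int = 1000
    k: int = 4
    within_corr: float = 0.6
    between_corr: float = 0.1
    global_strength: float = 0.2
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.between_corr <= self.within_corr < 1):
            raise UninetError("need 0 <= between <= within < 1")
        if self.n < self.k or self.k < 1:
            raise UninetError("need n >= k >= 1")
        if self.global_strength**2 > self.between_corr + 1e-12:
            raise UninetError(
                "global_strength² must not exceed the between-module target"
            )


def synth_timeseries(spec: SynthSpec) -> tuple[DataMatrix, Partition]:
    """Planted-module node time series (rescaled) and the truth partition.

    Node i in module h:  χ_i = g·G + a·f_h + σ·ε_i with unit-variance
    latent series; centroids f_h share a common factor so that the
    between-module correlation meets its target even when the explicit
    global loading g is zero:

        within  = g² + a²,   between = g² + a² ρ_F,
        a² = within − g²,    ρ_F = (between − g²)/a²,   σ² = 1 − within.
    """
    rng = np.random.default_rng(spec.seed)
    g2 = spec.global_strength**2
    a2 = spec.within_corr - g2
    sigma2 = (1.0 - spec.within_corr) * spec.noise_sd**2
    rho_f = 0.0 if a2 <= 0 else (spec.between_corr - g2) / a2
    if not -1e-12 <= rho_f <= 1 + 1e-12:
        raise UninetError("infeasible within/between/global combination")
    rho_f = float(np.clip(rho_f, 0.0, 1.0))
    G = rng.standard_normal(spec.p)
    shared = rng.standard_normal(spec.p)
    F = np.sqrt(rho_f) * shared[:, None] + np.sqrt(1 - rho_f) * rng.standard_normal(
        (spec.p, spec.k)
    )
    labels = np.arange(spec.n) % spec.k
    noise = rng.standard_normal((spec.p, spec.n))
    X = (
        spec.global_strength * G[:, None]
        + np.sqrt(max(a2, 0.0)) * F[:, labels]
        + np.sqrt(max(sigma2, 0.0)) * noise
    )
    return rescale_columns(DataMatrix(X)), Partition(labels, spec.k)


def synth_structural(
    n: int = 100,
    coords: np.ndarray | None = None,
    decay: float = 0.5,
    modules: Partition | None = None,
    module_bonus: float = 0.5,
    noise_sd: float = 0.25,
    seed: int | None = None,
) -> Network:
    """Distance-decay structural network with optional module bonus.

    weights = exp(−dist/(decay·d̄)) · (1 + bonus·[same module]) ·
    lognormal noise, symmetrized, zero diagonal, non-negative.
    """
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = rng.uniform(size=(n, 3))
    else:
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    dbar = dist[~np.eye(n, dtype=bool)].mean()
    W = np.exp(-dist / (decay * dbar))
    if modules is not None:
        same = modules.labels[:, None] == modules.labels[None, :]
        W = W * (1.0 + module_bonus * same)
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n, n))
    W = W * noise
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return Network(W, flavor="structural")


def synth_constrained_timeseries(
    node_module_corr: np.ndarray,
    module_corr: np.ndarray,
    p: int = 2000,
    seed: int | None = None,
) -> tuple[DataMatrix, np.ndarray, dict]:
    """Gaussian time series with prescribed node-to-module-centroid
    correlations.

    Two steps: (1) draw k centroid series with covariance ``module_corr``;
    (2) draw each node series as x_i = F R^(−1) t_i + τ_i ε_i, which has
    population correlation t_ih with centroid h; feasibility requires
    t_iᵀ R^(−1) t_i ≤ 1 (reported eigenvalue-style in the error if not).
    Returns the rescaled data, the centroid series, and a validation
    report of realized vs. target correlations.
    """
    T = np.asarray(node_module_corr, dtype=float)
    R = np.asarray(module_corr, dtype=float)
    n, k = T.shape
    if R.shape != (k, k):
        raise UninetError("module_corr must be k x k")
    vals = np.linalg.eigvalsh(R)
    if vals.min() < -1e-10:
        raise UninetError(
            f"module_corr is not positive semidefinite (eigenvalue {vals.min():.3g})"
        )
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    F = rng.standard_normal((p, k)) @ L.T
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    B = np.linalg.solve(R + 1e-12 * np.eye(k), T.T)  # k x n
    signal_var = np.einsum("hi,hi->i", B, R @ B)
    if signal_var.max() > 1.0 + 1e-8:
        bad = int(np.argmax(signal_var))
        raise UninetError(
            f"infeasible targets: node {bad} needs signal variance "
            f"{signal_var[bad]:.3f} > 1"
        )
    tau = np.sqrt(np.clip(1.0 - signal_var, 0.0, None))
    X = F @ B + tau * rng.standard_normal((p, n))
    data = rescale_columns(DataMatrix(X))
    # realized correlations against the generated centroids
    Xc = X - X.mean(axis=0)
    Fc = F - F.mean(axis=0)
    realized = (Xc / np.linalg.norm(Xc, axis=0)).T @ (Fc / np.linalg.norm(Fc, axis=0))
    report = {
        "max_abs_error": float(np.abs(realized - T).max()),
        "realized": realized,
    }
    return data, F, report


def synth_vignette1(
    n: int = 80,
    p: int = 2000,
    u1_u2_corr: float = 0.7,
    seed: int | None = None,
) -> DataMatrix:
    """Data whose correlation network has correlated first two eigenvectors.

    Emulates the functional-MRI regime in which nodes that load strongly
    on the global signal also score high on the secondary activity
    pattern: per-node global loadings λ and a secondary pattern loading m
    are drawn with corr(λ, m) equal to the target, and
    χ_i = λ_i G + c·m_i H + σ ε_i.  The network's u₁ tracks λ (plus a
    constant) and u₂ tracks m, so corr(u₁, u₂) lands near the target.
    """
    if not 0 <= u1_u2_corr < 1:
        raise UninetError("target correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 -= z2 @ z1 / n * z1  # orthogonalize, then mix at the target level
    z2 = (z2 - z2.mean()) / z2.std()
    m = u1_u2_corr * z1 + np.sqrt(1 - u1_u2_corr**2) * z2
    lam = 0.75 + 0.15 * z1  # strong, spatially varying global loading
    lam = np.clip(lam, 0.2, 0.95)
    G = rng.standard_normal(p)
    H = rng.standard_normal(p)
    sigma = np.sqrt(np.clip(1.0 - lam**2 - (0.25 * m) ** 2, 0.05, None))
    X = lam * G[:, None] + 0.25 * m * H[:, None] + sigma * rng.standard_normal((p, n))
    return rescale_columns(DataMatrix(X))
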