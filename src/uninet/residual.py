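"""Global residualization: removal of a network's dominant global pattern.

Three approximately equivalent variants are provided:

* first-component removal,  C* = C − ψ₁ u₁ u₁ᵀ
* degree correction,        C⋄ = C − d dᵀ / Σc
* global-signal regression, C′ = X′ᵀ X′  where X′ regresses the mean
  signal out of every column of X and renormalizes.

The third variant obeys the exact identity C′ = η C⋄ η with
η = diag(1 − d∘² / Σc)^(−1/2): the regression residual of column j has
squared norm 1 − d_j²/Σc, so the rescaling factors are a closed-form
function of the network degrees alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, Network, UninetError, eigensystem

VARIANTS = ("first_component", "degree_correction", "gsr")


@dataclass
class ResidualNetwork:
    """Residualized network (weights may be negative)."""

    weights: np.ndarray
    variant: str
    eta: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def remove_first_component(C: Network) -> ResidualNetwork:
    """Subtract the leading eigen-pair: C* = C − ψ₁ u₁ u₁ᵀ."""
    es = eigensystem(C, k=1)
    u1 = es.vectors[:, 0]
    resid = C.weights - es.values[0] * np.outer(u1, u1)
    resid = 0.5 * (resid + resid.T)
    return ResidualNetwork(resid, "first_component")


def degree_correct(C: Network) -> ResidualNetwork:
    """Subtract the degree product: C⋄ = C − d dᵀ / Σc.

    Row sums of the result are exactly zero.
    """
    if C.total_weight <= 0:
        raise UninetError("degree correction requires positive total weight")
    d = C.degree
    resid = C.weights - np.outer(d, d) / C.total_weight
    return ResidualNetwork(0.5 * (resid + resid.T), "degree_correction")


def gsr_eta(C: Network) -> np.ndarray:
    """Exact per-node GSR rescaling factors η_ii = (1 − d_i²/Σc)^(−1/2)."""
    shrink = 1.0 - C.degree**2 / C.total_weight
    bad = np.flatnonzero(shrink <= 1e-12)
    if bad.size:
        raise UninetError(
            f"eta undefined: node {bad[0]} is proportional to the global signal"
        )
    return shrink**-0.5


def global_signal_regress(
    X: DataMatrix,
) -> tuple[DataMatrix, ResidualNetwork, np.ndarray]:
    """Regress the global (mean) signal out of every column of X.

    Returns the renormalized residual data X′, the residual correlation
    network C′ = X′ᵀX′, and the per-node rescaling factors η.
    """
    if not X.rescaled:
        raise UninetError("global_signal_regress requires a rescaled DataMatrix")
    V = X.values
    xbar = X.global_signal()
    d = V.T @ V @ np.ones(X.n)  # degree of C = XᵀX
    sigma_c = float(d.sum())
    if sigma_c <= 0:
        raise UninetError("total network weight must be positive")
    resid = V - np.outer(xbar, d) * (X.n / sigma_c)
    norms_sq = 1.0 - d**2 / sigma_c
    bad = np.flatnonzero(norms_sq <= 1e-12)
    if bad.size:
        raise UninetError(
            f"column {bad[0]} is proportional to the global signal; eta undefined"
        )
    eta = norms_sq**-0.5
    Xp = resid * eta
    Cp = Xp.T @ Xp
    Cp = 0.5 * (Cp + Cp.T)
    Xres = DataMatrix(Xp)  # residual columns have unit norm but shifted means
    return Xres, ResidualNetwork(Cp, "gsr", eta=eta), eta


def residualize(C: Network, variant: str, X: DataMatrix | None = None) -> ResidualNetwork:
    """Dispatch to one of the three residualization variants.

    The gsr variant uses the data matrix when given; otherwise it uses
    the exact identity C′ = η C⋄ η, which depends only on the network.
    """
    if variant in ("first", "first_component"):
        return remove_first_component(C)
    if variant in ("degree", "degree_correction"):
        return degree_correct(C)
    if variant == "gsr":
        if X is not None:
            return global_signal_regress(X)[1]
        eta = gsr_eta(C)
        Cd = degree_correct(C).weights
        return ResidualNetwork(Cd * np.outer(eta, eta), "gsr", eta=eta)
    raise UninetError(f"unknown residualization variant: {variant!r}")


def residual_degree(C: Network, variant: str = "gsr") -> np.ndarray:
    """Residual degree d′ = (residualized C) · 1.

    Degree correction yields exact zeros by construction; first-component
    removal and GSR leave the (small) contributions of the second and
    higher components, which is what makes d′ informative.
    """
    if variant in ("degree", "degree_correction"):
        return np.zeros(C.n)
    return residualize(C, variant).weights.sum(axis=1)
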