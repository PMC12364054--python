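"""Loyvain: a unified local-move optimizer for k-means, k-modularity and
normalized-cut clustering, plus its bipartite (co-Loyvain) and multi-level
(Louvain) relatives.

The Loyvain method interpolates between Lloyd's k-means and phase 1 of the
Louvain method: every sweep splits the nodes into random batches and moves
all nodes of a batch simultaneously into their gain-maximizing modules.
With one batch this is a Lloyd-style simultaneous reassignment; with n
batches it degenerates to sequential single-node moves.  Simultaneous
moves can occasionally overshoot, so a sweep that lowers the objective is
rolled back and the batch count is doubled for that replicate, which
guarantees termination at a local optimum.

Move gains (node i from module g to module h), with d_ih the sum of
similarities from i to module h (including a_ii when i is a member):

size-normalized (k-means / k-modularity) objective Σ_h S_h / N_h:

    Δ = (2 d_ih + a_ii − S_h/N_h) / (N_h + 1)
      − (2 d_ig − a_ii − S_g/N_g) / (N_g − 1)

degree-normalized (normalized cut / s-modularity) objective Σ_h S_h / D_h:

    Δ = (2 d_ih + a_ii − (d_i/D_h) S_h) / (D_h + d_i)
      − (2 d_ig − a_ii − (d_i/D_g) S_g) / (D_g − d_i)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DataMatrix, Network, Partition, UninetError
from .objectives import node_module_correlation
from .residual import degree_correct

OBJECTIVES = ("kmeans", "kmodularity", "spectral")
INITS = ("uniform", "kmeanspp", "greedy_maximin")


@dataclass
class LoyvainConfig:
    """Configuration of a Loyvain run (defaults follow standard practice:
    greedy initialization, 10 batches, 100 replicates)."""

    k: int = 2
    objective: str = "kmodularity"
    init: str = "greedy_maximin"
    batches: int = 10
    replicates: int = 100
    max_iter: int = 300
    tol: float = 1e-10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise UninetError(f"unknown objective {self.objective!r}")
        if self.init not in INITS:
            raise UninetError(f"unknown init {self.init!r}")
        if self.replicates < 1 or self.batches < 1:
            raise UninetError("replicates and batches must be positive")


@dataclass
class ClusterResult:
    partition: Partition
    objective_value: float
    n_iterations: int
    replicate_values: list[float] = field(default_factory=list)


def _similarity(data: Network | DataMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Similarity matrix and total weight for Loyvain input."""
    if isinstance(data, DataMatrix):
        if not data.rescaled:
            raise UninetError("Loyvain on data requires a rescaled DataMatrix")
        C = data.values.T @ data.values
        return 0.5 * (C + C.T), float(C.sum())
    if isinstance(data, Network):
        return data.weights, data.total_weight
    W = np.asarray(data, dtype=float)
    return 0.5 * (W + W.T), float(W.sum())


def initialize(
    data: Network | DataMatrix | np.ndarray,
    k: int,
    method: str = "greedy_maximin",
    seed: int | np.random.Generator | None = None,
) -> Partition:
    """Seed a k-module partition on a similarity matrix or data matrix.

    greedy_maximin starts from the maximum-degree node and repeatedly adds
    the node with the smallest maximal similarity to the chosen centers
    (a greedy k-means++ / maximin rule); remaining nodes join their most
    similar center.  kmeanspp seeds probabilistically with D²-weighting on
    the induced squared Euclidean distance; uniform draws random labels and
    repairs empty modules.
    """
    A, _ = _similarity(data)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise UninetError(f"need 1 <= k <= n, got k={k}, n={n}")
    if k == n:
        return Partition(np.arange(n), k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "uniform":
        labels = rng.integers(0, k, size=n)
        for h in range(k):
            if not np.any(labels == h):
                big = np.flatnonzero(np.bincount(labels, minlength=k)[labels] > 1)
                labels[rng.choice(big)] = h
        return Partition(labels, k)
    if method == "greedy_maximin":
        centers = [int(np.argmax(A.sum(axis=1)))]
        while len(centers) < k:
            sim_to_centers = A[:, centers].max(axis=1)
            sim_to_centers[centers] = np.inf
            centers.append(int(np.argmin(sim_to_centers)))
    elif method == "kmeanspp":
        diag = np.diagonal(A)
        centers = [int(rng.integers(n))]
        while len(centers) < k:
            d2 = diag[:, None] + diag[centers][None, :] - 2 * A[:, centers]
            d2 = np.clip(d2.min(axis=1), 0.0, None)
            d2[centers] = 0.0
            total = d2.sum()
            if total <= 0:
                choices = np.setdiff1d(np.arange(n), centers)
                centers.append(int(rng.choice(choices)))
            else:
                centers.append(int(rng.choice(n, p=d2 / total)))
    else:
        raise UninetError(f"unknown init {method!r}")
    labels = np.asarray(centers)[np.argmax(A[:, centers], axis=1)]
    labels[centers] = centers
    # relabel center ids to 0..k-1
    remap = {c: h for h, c in enumerate(centers)}
    return Partition(np.array([remap[c] for c in labels]), k)


class _LoyvainState:
    """Mutable sufficient statistics of a partition under one objective."""

    def __init__(self, A: np.ndarray, labels: np.ndarray, k: int, objective: str):
        self.A = A
        self.k = k
        self.objective = objective
        self.diag = np.diagonal(A).copy()
        self.node_deg = A.sum(axis=1)
        self.labels = labels.copy()
        self.recompute()

    def recompute(self) -> None:
        M = np.zeros((self.A.shape[0], self.k))
        M[np.arange(self.A.shape[0]), self.labels] = 1.0
        self.M = M
        self.D = self.A @ M  # d_ih for all nodes and modules
        self.S = np.einsum("ih,ih->h", M, self.D)
        self.N = M.sum(axis=0)
        self.Dw = self.node_deg @ M  # module degrees

    def value(self) -> float:
        if self.objective == "spectral":
            return float((self.S / self.Dw).sum())
        return float((self.S / self.N).sum())

    def gains(self, batch: np.ndarray) -> np.ndarray:
        """Move gains for every node in ``batch`` and target module."""
        g = self.labels[batch]
        a_ii = self.diag[batch]
        D_b = self.D[batch]  # (b, k)
        if self.objective == "spectral":
            w_h, v = self.Dw, self.node_deg[batch]
            gain_to = (2 * D_b + a_ii[:, None] - (v[:, None] / w_h) * self.S) / (
                w_h + v[:, None]
            )
            denom = w_h[g] - v
            ok = denom > 1e-12
            loss = np.zeros(batch.size)
            loss[ok] = (
                2 * D_b[np.arange(batch.size), g][ok]
                - a_ii[ok]
                - (v[ok] / w_h[g][ok]) * self.S[g][ok]
            ) / denom[ok]
        else:
            gain_to = (2 * D_b + a_ii[:, None] - self.S / self.N) / (self.N + 1)
            denom = self.N[g] - 1
            ok = denom > 0
            loss = np.zeros(batch.size)
            loss[ok] = (
                2 * D_b[np.arange(batch.size), g][ok]
                - a_ii[ok]
                - self.S[g][ok] / self.N[g][ok]
            ) / denom[ok]
        delta = gain_to - loss[:, None]
        delta[np.arange(batch.size), g] = 0.0
        delta[~ok] = -np.inf  # nodes whose departure would empty a module stay
        delta[~ok, g[~ok]] = 0.0
        return delta

    def apply(self, batch: np.ndarray, new_labels: np.ndarray) -> None:
        self.labels[batch] = new_labels
        # repair any emptied module by re-seeding it with the node that has
        # the lowest size-normalized coherence with its current module
        counts = np.bincount(self.labels, minlength=self.k)
        while np.any(counts == 0):
            h = int(np.flatnonzero(counts == 0)[0])
            movable = np.flatnonzero(counts[self.labels] > 1)
            n = self.labels.size
            M = np.zeros((n, self.k))
            M[np.arange(n), self.labels] = 1.0
            D = self.A[movable] @ M
            fit = D[np.arange(movable.size), self.labels[movable]]
            worst = movable[np.argmin(fit / counts[self.labels[movable]])]
            self.labels[worst] = h
            counts = np.bincount(self.labels, minlength=self.k)
        self.recompute()


def _optimize(
    A: np.ndarray,
    labels: np.ndarray,
    k: int,
    objective: str,
    batches: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    state = _LoyvainState(A, labels, k, objective)
    n = A.shape[0]
    batches = min(batches, n)
    value = state.value()
    for sweep in range(max_iter):
        saved_labels = state.labels.copy()
        order = rng.permutation(n)
        for group in np.array_split(order, batches):
            if group.size == 0:
                continue
            delta = state.gains(group)
            target = np.argmax(delta, axis=1)
            improving = delta[np.arange(group.size), target] > 0
            if np.any(improving):
                state.apply(group[improving], target[improving])
        new_value = state.value()
        if new_value < value - 1e-12:
            # simultaneous moves overshot: roll back, use finer batches
            state.labels = saved_labels
            state.recompute()
            if batches >= n:
                return state.labels, value, sweep + 1
            batches = min(2 * batches, n)
            continue
        if new_value - value < tol:
            return state.labels, new_value, sweep + 1
        value = new_value
    return state.labels, value, max_iter


def _report_value(
    raw_value: float, objective: str, total_weight: float
) -> float:
    """Convert the internal objective to the reported (printed-form) scale."""
    if objective == "kmodularity":
        return raw_value / total_weight
    return raw_value


def loyvain(
    data: Network | DataMatrix | np.ndarray, config: LoyvainConfig
) -> ClusterResult:
    """Batched local-move maximization of the configured objective.

    kmeans maximizes the coherence Σ_h m_hᵀCm_h/N_h on the similarity
    itself; kmodularity maximizes the same form on the degree-corrected
    similarity (reported on the (1/Σc) scale); spectral maximizes the
    normalized-association objective (reported as the normalized cut).
    Deterministic given ``config.seed``; best of ``config.replicates`` wins.
    """
    A, total = _similarity(data)
    if config.objective == "kmodularity":
        if total <= 0:
            raise UninetError("k-modularity requires positive total weight")
        d = A.sum(axis=1)
        A_opt = A - np.outer(d, d) / total
    elif config.objective == "spectral":
        if A.min() < -1e-12:
            raise UninetError("spectral objective requires a non-negative network")
        if np.any(A.sum(axis=1) <= 0):
            raise UninetError("spectral objective requires positive degrees")
        A_opt = A
    else:
        A_opt = A
    best: tuple[float, np.ndarray, int] | None = None
    replicate_values: list[float] = []
    for r in range(config.replicates):
        rng = np.random.default_rng(
            [0 if config.seed is None else config.seed, r]
        )
        init_part = initialize(A, config.k, config.init, rng)
        labels, value, iters = _optimize(
            A_opt,
            init_part.labels,
            config.k,
            config.objective,
            config.batches,
            config.max_iter,
            config.tol,
            rng,
        )
        replicate_values.append(_report_value(value, config.objective, total))
        if best is None or value > best[0] + 1e-15:
            best = (value, labels, iters)
    assert best is not None
    value, labels, iters = best[0], best[1], best[2]
    return ClusterResult(
        Partition(labels, config.k),
        _report_value(value, config.objective, total),
        iters,
        replicate_values,
    )


# ---------------------------------------------------------------------------
# co-Loyvain: alternating bipartite clustering


def _co_value(Z, Ma, Mb, variant) -> float:
    pair = np.einsum("ih,ij,jh->h", Ma, Z, Mb, optimize=True)
    if variant == "spectral":
        denom = np.sqrt((Ma.T @ Z.sum(axis=1)) * (Mb.T @ Z.sum(axis=0)))
    else:
        denom = np.sqrt(Ma.sum(axis=0) * Mb.sum(axis=0))
    return float((pair / denom).sum())


def _co_side_sweep(Y, labels, k, weights, batches, rng) -> tuple[np.ndarray, bool]:
    """One batched sweep of row-side moves for objective Σ_h T_h / sqrt(w_h).

    Y[i, h] is the contribution of row i to pair h; ``weights`` are the
    per-row normalization weights (ones for the k-means variant, row sums
    for the spectral variant).  Exact gains, no linearization.
    """
    n = Y.shape[0]
    moved = False
    order = rng.permutation(n)
    for group in np.array_split(order, min(batches, n)):
        if group.size == 0:
            continue
        M = np.zeros((n, k))
        M[np.arange(n), labels] = 1.0
        T = np.einsum("ih,ih->h", M, Y)
        w = weights @ M
        g = labels[group]
        v = weights[group]
        with np.errstate(divide="ignore", invalid="ignore"):
            new_to = (T + Y[group]) / np.sqrt(w + v[:, None])
            old_to = T / np.sqrt(w)
            w_from = w[g] - v
            ok = w_from > 1e-12
            from_term = np.full(group.size, -np.inf)
            from_term[ok] = (
                T[g][ok] - Y[group[ok], g[ok]]
            ) / np.sqrt(w_from[ok]) - T[g][ok] / np.sqrt(w[g][ok])
        delta = (new_to - old_to) + from_term[:, None]
        delta[np.arange(group.size), g] = 0.0
        delta[~ok] = -np.inf
        delta[~ok, g[~ok]] = 0.0
        target = np.argmax(delta, axis=1)
        improving = delta[np.arange(group.size), target] > 1e-15
        if np.any(improving):
            labels[group[improving]] = target[improving]
            moved = True
            # repair emptied modules with a random donor from a big module
            counts = np.bincount(labels, minlength=k)
            for h in np.flatnonzero(counts == 0):
                donors = np.flatnonzero(counts[labels] > 1)
                labels[rng.choice(donors)] = h
                counts = np.bincount(labels, minlength=k)
    return labels, moved


def co_loyvain(
    Z: np.ndarray,
    ka: int,
    kb: int | None = None,
    config: LoyvainConfig | None = None,
    variant: str = "kmeans",
) -> tuple[Partition, Partition, float]:
    """Alternating bipartite co-clustering of a pa x pb matrix.

    Maximizes Σ_h m_ahᵀ Z m_bh / (N_ah N_bh)^(1/2) (or the degree-
    normalized spectral variant) by alternating Loyvain-style batched
    sweeps over the row and column partitions.  Requires ka == kb.
    """
    Z = np.asarray(Z, dtype=float)
    if kb is None:
        kb = ka
    if ka != kb:
        raise UninetError("co-clustering requires matching k on both sides")
    if not np.any(Z):
        raise UninetError("co-clustering of an all-zero matrix is degenerate")
    config = config or LoyvainConfig(k=ka)
    pa, pb = Z.shape
    if ka > pa or kb > pb:
        raise UninetError("k exceeds the number of rows or columns")
    if variant == "spectral":
        wa, wb = Z.sum(axis=1), Z.sum(axis=0)
    else:
        wa, wb = np.ones(pa), np.ones(pb)
    best = None
    for r in range(config.replicates):
        rng = np.random.default_rng([1 if config.seed is None else config.seed, r])
        la = initialize(Z @ Z.T, ka, config.init, rng).labels
        lb = initialize(Z.T @ Z, kb, config.init, rng).labels
        value = -np.inf
        for _ in range(config.max_iter):
            Mb = np.zeros((pb, kb))
            Mb[np.arange(pb), lb] = 1.0
            denom_b = np.sqrt(wb @ Mb)
            la, moved_a = _co_side_sweep(
                (Z @ Mb) / denom_b, la, ka, wa, config.batches, rng
            )
            Ma = np.zeros((pa, ka))
            Ma[np.arange(pa), la] = 1.0
            denom_a = np.sqrt(wa @ Ma)
            lb, moved_b = _co_side_sweep(
                (Z.T @ Ma) / denom_a, lb, kb, wb, config.batches, rng
            )
            Ma = np.zeros((pa, ka))
            Ma[np.arange(pa), la] = 1.0
            Mb = np.zeros((pb, kb))
            Mb[np.arange(pb), lb] = 1.0
            new_value = _co_value(Z, Ma, Mb, variant)
            if not (moved_a or moved_b) or new_value - value < config.tol:
                value = max(value, new_value)
                break
            value = new_value
        if best is None or value > best[0] + 1e-15:
            best = (value, la.copy(), lb.copy())
    assert best is not None
    return Partition(best[1], ka), Partition(best[2], kb), best[0]


# ---------------------------------------------------------------------------
# Louvain (multi-level modularity maximization) for binary m-umap


def _phase1(A: np.ndarray, labels: np.ndarray, rng, max_pass=100) -> bool:
    """Sequential single-node moves to a local modularity optimum (in place)."""
    n = A.shape[0]
    total = A.sum()
    deg = A.sum(axis=1)
    moved_any = False
    for _ in range(max_pass):
        moved = False
        for i in rng.permutation(n):
            k = labels.max() + 1
            d_ih = np.zeros(k)
            np.add.at(d_ih, labels, A[i])
            D_h = np.zeros(k)
            np.add.at(D_h, labels, deg)
            g = labels[i]
            d_ih[g] -= A[i, i]
            D_h[g] -= deg[i]
            gain = 2 * d_ih / total - 2 * deg[i] * D_h / total**2
            h = int(np.argmax(gain))
            if gain[h] > gain[g] + 1e-15:
                labels[i] = h
                moved = moved_any = True
        if not moved:
            break
    return moved_any


def _compress(labels: np.ndarray) -> np.ndarray:
    _, dense = np.unique(labels, return_inverse=True)
    return dense


def louvain_modularity(
    N: Network | np.ndarray,
    seed: int | None = None,
    replicates: int = 100,
    finaltune: bool = True,
) -> ClusterResult:
    """Multi-level Louvain maximization of the degree-corrected modularity.

    The number of modules emerges from the data.  ``finaltune`` runs one
    extra phase-1 pass on the original nodes after unrolling the module
    hierarchy.  Deterministic given ``seed``; best of ``replicates``.
    """
    A, total = _similarity(N)
    if A.min() < -1e-12:
        raise UninetError("Louvain requires a non-negative network")
    n = A.shape[0]
    best = None
    replicate_values = []
    for r in range(replicates):
        rng = np.random.default_rng([2 if seed is None else seed, r])
        labels = np.arange(n)
        level_assign = [labels]
        A_level = A.copy()
        node_labels = np.arange(n)
        levels = 0
        while True:
            lab = np.arange(A_level.shape[0])
            moved = _phase1(A_level, lab, rng)
            lab = _compress(lab)
            node_labels = lab[node_labels]
            levels += 1
            if not moved or lab.max() + 1 == A_level.shape[0]:
                break
            M = np.zeros((A_level.shape[0], lab.max() + 1))
            M[np.arange(A_level.shape[0]), lab] = 1.0
            A_level = M.T @ A_level @ M
        if finaltune:
            _phase1(A, node_labels, rng)
            node_labels = _compress(node_labels)
        k = node_labels.max() + 1
        M = np.zeros((n, k))
        M[np.arange(n), node_labels] = 1.0
        d = A.sum(axis=1)
        q = float(
            (np.einsum("ih,ij,jh->h", M, A, M, optimize=True) - (d @ M) ** 2 / total).sum()
            / total
        )
        replicate_values.append(q)
        if best is None or q > best[0] + 1e-15:
            best = (q, node_labels.copy(), levels)
    assert best is not None
    q, labels, levels = best
    return ClusterResult(
        Partition(labels, labels.max() + 1), q, levels, replicate_values
    )


# ---------------------------------------------------------------------------
# dynamic node-module affinity


def _match_modules(ref_centroids: np.ndarray, win_centroids: np.ndarray) -> np.ndarray:
    """Greedy maximal-correlation matching of window modules to reference.

    Returns ``match`` with match[window_module] = reference_module.
    """
    k = ref_centroids.shape[1]
    R = np.corrcoef(win_centroids.T, ref_centroids.T)[:k, k:]
    match = np.full(k, -1)
    used = np.zeros(k, dtype=bool)
    flat = np.dstack(np.unravel_index(np.argsort(R, axis=None)[::-1], R.shape))[0]
    for w, rf in flat:
        if match[w] == -1 and not used[rf]:
            match[w] = rf
            used[rf] = True
    return match


def dynamic_affinity(
    X: DataMatrix,
    window_length: int,
    k: int,
    config: LoyvainConfig | None = None,
) -> np.ndarray:
    """Fraction of time windows each node spends in each reference module.

    Non-overlapping windows of ``window_length`` time points are clustered
    independently with Loyvain k-modularity; each window's modules are
    greedily matched to the full-series reference modules by maximal
    centroid correlation (centroids compared on the window's own time
    points).  Rows of the returned n x k matrix sum to 1.
    """
    from .core import rescale_columns

    if X.p < 2 * window_length:
        raise UninetError("need at least two windows of data")
    config = config or LoyvainConfig(k=k, objective="kmodularity", replicates=10)
    config = replace(config, k=k, objective="kmodularity")
    ref = loyvain(X, config)
    M_ref = ref.partition.indicator()
    n_windows = X.p // window_length
    affinity = np.zeros((X.n, k))
    for w in range(n_windows):
        rows = slice(w * window_length, (w + 1) * window_length)
        Xw = rescale_columns(DataMatrix(X.values[rows]))
        win = loyvain(Xw, config)
        ref_centroids = Xw.values @ M_ref / M_ref.sum(axis=0)
        win_M = win.partition.indicator()
        win_centroids = Xw.values @ win_M / win_M.sum(axis=0)
        match = _match_modules(ref_centroids, win_centroids)
        affinity[np.arange(X.n), match[win.partition.labels]] += 1.0
    return affinity / n_windows
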