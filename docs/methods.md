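# Methods

This note documents the models and procedures implemented in `uninet`,
the conventions and numerical choices they rest on, and what the
synthetic generators do and do not emulate.

## Data model and conventions

A data matrix `X` is p features (e.g. time points) by n nodes.  The
canonical rescaling maps each raw column χ to
`x = (1/2)^(1/2)·normalize(χ) + (2p)^(−1/2)·1`, where `normalize`
centers to mean 0 and scales to norm 1.  Every rescaled column then has
unit norm and mean `(2p)^(−1/2)`, and inner products become rescaled
Pearson correlations: `xᵢᵀxⱼ = (corr(χᵢ, χⱼ) + 1)/2 ∈ [0, 1]`.  The
correlation network is `C = XᵀX` (unit diagonal); structural networks
have a zero diagonal.  Negative network weights are out of scope: every
result here assumes symmetric non-negative weights.

Eigendecompositions sort eigenvalues in descending order and fix each
eigenvector's sign by making its largest-magnitude entry positive, so
gradients and embeddings are reproducible.  Under exactly tied
eigenvalues the basis within the tied block is solver-dependent; tests
avoid asserting vector identity there.  Symmetry is enforced at a
relative tolerance of 1e-10 (floating-point round-trip artifacts only);
matrices are stored dense, with sparse matrices used only for κ-NN and
co-neighbor constructions.

## Global residualization

Three variants remove a network's dominant global pattern:

- first-component removal `C* = C − ψ₁u₁u₁ᵀ`;
- degree correction `C⋄ = C − ddᵀ/Σc` (row sums exactly zero);
- global-signal regression: regress x̄ = (1/n)X·1 out of each column and
  renormalize to unit norm.

The residual of column j has squared norm `1 − dⱼ²/Σc` (because
`xⱼᵀx̄ = dⱼ/n` and `‖x̄‖² = Σc/n²`), which yields the exact identity
`C′ = ηC⋄η` with `η = diag(1 − d∘²/Σc)^(−1/2)` — implemented with the
exact η, not its Taylor approximation.  Because η is a closed-form
function of the network degrees, the GSR-variant residual degree
`d′ = C′·1` is available from a bare network; the full regression
(returning residual time series) requires the data matrix, since the
regression itself is defined on time series.  A column proportional to
the global signal makes η diverge and raises an error naming the node.
Residual networks keep their (possibly nonzero) diagonal; objective code
counts diagonal terms explicitly.

First-component removal and degree correction approximately coincide
because `u₁ ≅ d/‖d‖` and `ψ₁ ≅ dᵀd/Σc` in dense networks with a
dominant first eigenvalue; the package asserts this as a correlation,
never as an identity.

## The objective family

With indicator matrix M (columns m_h, sizes N_h, module degrees
D_h = m_hᵀd):

| objective | definition |
|---|---|
| k-means coherence | Σ_h (1/N_h) m_hᵀCm_h |
| k-means distance | n − coherence (unit diagonal) |
| modularity | (1/Σc) Σ_h m_hᵀC⋄m_h |
| k-modularity | (1/Σc) Σ_h (1/N_h) m_hᵀC⋄m_h |
| density-corrected k-modularity | (1/Σc) Σ_h (1/N_h) m_hᵀCm_h − 1/n |
| normalized cut (association form) | Σ_h (1/D_h) m_hᵀCm_h |
| s-modularity | (1/Σc) Σ_h (1/D_h) m_hᵀC⋄m_h |

Density-corrected k-modularity is an affine function of the coherence;
s-modularity equals `(normalized cut − 1)/Σc`.  The normalization
constants are kept so the printed-form identities hold; tests assert the
affine relations as |corr| = 1 over many random partitions rather than
folding constants away.  Bipartite (co-clustering) objectives divide
each pair term `m_ahᵀZm_bh` by `(N_ah·N_bh)^(1/2)` (k-means form) or
`(D_ah·D_bh)^(1/2)` (spectral form).

## Loyvain

Loyvain performs batched local moves: each sweep splits nodes into
`batches` random groups (reshuffled every sweep) and simultaneously
moves all nodes of a group into their gain-maximizing modules.  Gains
for the size-normalized objective (d_ih including the self-similarity
when i ∈ h):

    Δ(i: g→h) = (2d_ih + a_ii − S_h/N_h)/(N_h + 1)
              − (2d_ig − a_ii − S_g/N_g)/(N_g − 1)

and analogously with module degrees D_h and node degree d_i for the
degree-normalized objective.  Simultaneous moves can overshoot, so a
sweep that lowers the objective is rolled back and the batch count
doubled for that replicate — this guarantees termination with a
monotone accepted-objective sequence.  A module emptied by a batch is
re-seeded with the node that has the lowest size-normalized coherence
with its current module.  Defaults: greedy (maximin) initialization,
10 batches, 100 replicates, tolerance 1e-10 absolute gain, 300 sweeps
maximum.  Greedy initialization starts at the maximum-degree node and
repeatedly adds the node with minimal maximal similarity to the chosen
centers; k-means++ seeding uses the induced squared Euclidean distance
`a_ii + a_jj − 2a_ij`.  With one batch the algorithm behaves like
Lloyd-style simultaneous reassignment; with n batches it reduces to
sequential single-node moves.

Co-Loyvain alternates row-side and column-side batched sweeps on the
bipartite objective with exact (non-linearized) move gains until neither
side improves.  The Louvain implementation is the standard multi-level
scheme on degree-corrected modularity (resolution 1) with seeded
determinism, replicate selection, and an optional final tuning pass on
the original nodes; the module count emerges from the data.

Dynamic node-module affinity clusters non-overlapping windows
independently, matches window modules to the full-series reference
modules greedily by maximal centroid correlation (computed on the
window's own time points; greedy matching chosen for determinism), and
reports the fraction of windows each node spends in each reference
module.

## Co-neighbor gradients

`knn_threshold` keeps, per column, the κ largest off-diagonal entries
(ties break toward the lowest node index so exactly κ survive).  The
symmetric binary graph is the union `[C̃>0] ∨ [C̃>0]ᵀ`; the co-neighbor
matrix is `𝒞 = [C̃>0]ᵀ[C̃>0]`, whose diagonal (constantly κ) is zeroed —
a constant diagonal shifts eigenvalues uniformly without changing
eigenvectors, and zeroing matches the zero-diagonal convention.  The
diffusion-map variant builds the cosine kernel `A = η̃C̃ᵀC̃η̃`, applies
the α-normalization `R = A ⊙ vvᵀ` with `v = (A·1)^(−α)` (α = 1/2
default), row-normalizes to a transition matrix, and returns right
eigenvectors 2..k+1 divided elementwise by the constant first
eigenvector (computed through the symmetric similarity transform
`D^(−1/2)RD^(−1/2)`, so no non-symmetric eigensolver is involved).
Eigenvalue rescaling of gradients is omitted as a normalization by
constants.  The simplified route takes eigenvectors 2..k+1 of 𝒞
directly; binary gradients are k-modularity modules of 𝒞.  A
disconnected kernel graph is an error that advises a larger κ; the
default κ is round(0.1·n).

## m-umap

The objective couples the symmetric κ-NN graph ℭ, degree-corrected at
resolution γ (the analogue of the negative-sampling rate; γ = 1
throughout), to spherical coordinates U through the Cauchy similarity
`φ = (1 + αH∘β)^(−1)`, `H = 2(1 − UUᵀ)`:

    E(U) = −Σ_ij (ℭ_ij − γd_id_j/Σc) φ_ij.

Defaults α = β = 1 (standard Cauchy) and d = 3 (the 2-sphere); both are
configurable.  At binary one-hot embeddings φ is 1 within and
δ = (1 + α2^β)^(−1) between modules, and E reduces affinely to the
negative modularity — so binary m-umap is exactly Louvain modularity
maximization.  The Euclidean gradient is
`4αβ Σ_j coef_ij (u_i − u_j)` with
`coef = ℭ⋄ ⊙ H∘(β−1) ⊙ (1 + αH∘β)∘(−2)` (zero diagonal); the term
proportional to u_i is radial on the sphere, which is why the compact
attraction/repulsion form `−4αβ·coef·U` is equivalent after tangent
projection.  The full form is returned so finite differences match it
off the sphere as well.

Optimization is projected gradient descent: project the gradient on the
row-wise tangent spaces, backtrack (factor 0.5, initial step 1.0) until
the objective does not increase, retract by row renormalization, stop at
relative change 1e-8 or 500 iterations.  Accepted steps never increase
the objective.  Initializations: spectral node (row-normalized
eigenvectors 2..d+1 of ℭ), spectral module (row-normalized eigenvectors
of Mᵀℭ⋄M), and Fibonacci maximin (modules on Fibonacci sphere points,
largest-degree module most central, the rest farthest-first; nodes
inherit module positions, with small seeded jitter so nodes can separate
within modules).  For d ≠ 3 the Fibonacci lattice is replaced by
farthest-first placement on random unit vectors.  Disconnected graph
components are allowed: the degree-corrected null term couples them
repulsively and the sphere bounds the layout.  Embedding fidelity is the
absolute Pearson correlation between the n·k node-to-module-centroid
similarities in native space and Euclidean distances in embedding space.

## Centrality

Degree `s = W·1` and second degree `S = (W∘²)·1` are the first and
second raw moments of nodal connectivity.  Networks entering
communicability or controllability are first rescaled to unit spectral
radius.  Mean first passage times come from the fundamental matrix
`Z = (I − Y + 1πᵀ)^(−1)` of the random walk `Y = diag(s)^(−1)W` with
stationary distribution `π = s/Σw`; self-passage time is 0 by
convention.  Diffusion efficiency averages inverse MFPTs into each node
(over sources), the reading under which the measure tracks degree —
"easy to reach" — with the over-targets axis available as an option.
Average controllability is the Gramian diagonal
`diag((I − W²/γ²)^(−1))` with B = I and default γ = 1 + λ₁ = 2.  Modal
controllability `Σ_j v_ij²(1 − λ_j²)` equals `1 − S_i` exactly at unit
spectral radius.  The squared coefficient of variation uses all n
entries of each weight vector, including the zero diagonal, so the mean
is `s_i/n`.  The k-participation coefficient divides each module's
squared degree fraction by N_h, in parallel with k-modularity.

## Spectral models

Cubic shrinkage fits a cubic to eigenvalues i..n against rank for every
start index i ≤ n−3, computes each fit's RMSE over its own range, picks
the knee maximizing `(RMSE₀ − RMSE_i)/RMSE₀ − i/(n−1)` (taken at face
value; a zero-residual first fit places the knee at the top), and
re-evaluates the full spectrum from the knee's cubic.  Eigenvectors are
untouched.

The growth family uses a proximity matrix Φ with zero diagonal; because
the functional form of proximity is a modeling choice, both
`exp(−dist/mean-dist)` (default) and an inverse-distance form are
exposed, raised elementwise to α.  The original stochastic model adds
one binary edge per step with probability ∝ `Φ∘α ⊙ 𝒲∘β` over currently
unconnected pairs (𝒲 = co-neighbor counts, recomputed each step;
probabilities renormalized each step).  Pairs with zero similarity and
β > 0 get probability zero; a configurable ε floor avoids dead ends.
The modified deterministic model iterates
`Ŵ(τ+1) = γ(ρΦ∘α + (1−ρ)Ŵ²) + Ŵ`; when the seed shares the
eigenvectors of Φ∘α this is the per-mode quadratic map
`λ(τ+1) = γ((1−ρ)λ² + ρλ*) + λ`, with closed form `Ŵ₀ + τγΦ∘α` at
ρ = 1.  The default seed is the shrunken proximity matrix.

## Synthetic generators

`synth_timeseries` draws node series `g·G + a·f_h + σ·ε` with
unit-variance Gaussian latents; the module centroids share a common
factor, so the between-module correlation target is met even with a
zero explicit global loading.  Mixing weights are solved from the
target identities (within = g² + a², between = g² + a²ρ_F, total
variance 1).  Defaults n = 60, p = 1000, k = 4, within 0.6, between
0.1, global loading 0.2 — a regime with a dominant global component,
well-separated planted modules, and realized block correlations within
±0.05 of target at p ≥ 500 (Fisher-z sampling error).

`synth_structural` multiplies exponential distance decay, an optional
same-module bonus, and lognormal noise on uniformly random 3-D
coordinates.  `synth_constrained_timeseries` is a Gaussian
latent-factor construction that prescribes node-to-module-centroid
correlations: centroids with covariance R, then
`x_i = F·R^(−1)t_i + τ_i ε_i`, feasible iff `t_iᵀR^(−1)t_i ≤ 1`.  It
reproduces prescribed correlation targets but does not certify maximum
entropy among all matching processes — a difference from
nullspace-sampling generators, documented here deliberately.
`synth_vignette1` emulates the regime in which nodes loading strongly
on the global signal also score high on a secondary activity pattern:
per-node global loadings are correlated, at the target level, with an
orthogonalized secondary loading pattern, which makes the correlation
network's first two eigenvectors correlate near the target (±0.1 for
moderate targets).

What passing tests on these generators show: that the algebraic
identities hold on realistic dense inputs, that the optimizers find
planted optima, and that the approximate equivalences hold in the
dense, globally-coupled regime the generators produce.  What they do
not show: behavior under heavy-tailed degree distributions, extreme
sparsity, autocorrelated (sluggish) time series, or measurement
artifacts — real imaging data differ in all four respects, and the
approximate (not the exact) equivalences are the ones sensitive to
this.

## Problem sizes and determinism

Analyses in the test suite run at n = 40–100 nodes and p = 300–2000
features, where every identity is already well-conditioned and the full
suite stays fast.  Every stochastic component (generators, replicate
initializations, batch schedules, Monte-Carlo oracles) is driven by an
explicit integer seed through independent `default_rng` streams, so
identical configurations reproduce byte-identical outputs.

## Known limitations

Only hard partitions (no overlapping or soft modules); single-component
removal (no multi-component residualization); no negative-weight
networks; dense linear algebra limits practical sizes to a few thousand
nodes except in the sparse κ-NN constructions; the growth models are
demonstrative, with no parameter fitting to empirical networks.
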