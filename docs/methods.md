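# Methods

## Model class

The full system lives on a weighted directed network `W = (w_ij)` with
nonnegative weights, `w_ij` being the strength of the influence of node
`j` on node `i` (row = receiver; edge-list files store `(source, target,
weight)` and are transposed at load).  Node activities obey

```
dx_i/dt = f(x_i) + Σ_j w_ij g(x_i, x_j)
```

with `f`, `g` continuously differentiable and shared by all nodes: all
heterogeneity lives in the adjacency matrix.  Negative (inhibitory)
weights are out of scope — the spectral machinery rests on
Perron–Frobenius theory for positive matrices.

## Reductions

Given a partition of the `N` nodes into `n` groups `G_ν` of sizes `m_ν`
(group members made contiguous by an internal stable relabeling), each
group gets an observable `X_ν = â_νᵀ x̂_ν` with `â_ν ≥ 0`, `Σ_k â_νk = 1`.
Either choice of vectors yields the reduced dynamics

```
dX_ν/dt = f(X_ν) + Σ_ρ 𝒲_νρ g(X_ν, X_ρ) + Σ_ρ (μ_νρ − 𝒲_νρ) g₁(X_ν, X_ρ) X_ν
```

with `𝒲_νρ = â_νᵀ K_νρ 1 = Σ_i â_νi k_i^ρ` and `μ_νρ = â_νᵀ K_νρ â_ν /
‖â_ν‖²`, where `K_νρ` is the diagonal matrix of in-degrees group ν
receives from group ρ.  The correction term (third summand) exists because
the in-degree compatibility equations below are generally not solved
exactly; it vanishes identically when `g` does not depend on the
receiver's activity (`g₁ ≡ 0`, e.g. the neuronal model), and the
implementation skips it in that case.

**Homogeneous reduction.** `â_νk = 1/m_ν`.  Zeroth-order closure; the
reduced couplings are plain mean group-to-group in-degrees.

**Spectral reduction.** First-order Taylor closure demands the
*compatibility equations* `K_νρ â_ν = μ_νρ â_ν` and `W_νρᵀ â_ν = λ_νρ
â_ρ`.  For strictly positive matrices the latter family decouples into
per-group eigen-equations: `â_ν` must be a common dominant eigenvector of
`W_ννᵀ` (1-step interactions) and `W_ρνᵀ W_νρᵀ` for every `ρ ≠ ν` (2-step
interactions through group ρ).  The solver:

1. fixes each scalar `λ'_νρ` at the dominant eigenvalue of its matrix
   (dense solver; the eigenvalue must be real within `1e-8·|λ|`, ties
   between equal-modulus eigenvalues resolved in favour of the real
   positive Perron root);
2. minimizes `Σ_ρ ‖(W'_νρ − λ'_νρ I) â_ν‖²` subject to `1ᵀâ_ν = 1` through
   the KKT linear system of the assembled PSD quadratic form — closed
   form, deterministic, no iteration;
3. if the KKT solution dips below `−10⁻⁶·max(â)` (numerically degenerate
   or badly partitioned instances), re-solves with nonnegativity enforced
   by an active-set iteration, which is exact for the simplex-constrained
   PSD problem; otherwise tiny negatives are clipped and the vector
   renormalized.  Perron–Frobenius structure makes the unconstrained
   solution positive whenever the equations are exactly solvable, so the
   fallback signals a poor partition and is logged.
4. `μ` is computed afterwards as the Rayleigh quotient at the solution
   (its residual-minimizing value); the in-degree equations are *not*
   imposed during the minimization.

Residual norms of both equation families are reported per group pair and
serve as a partition-quality diagnostic.  Limiting behaviour, used as test
oracles: on perfectly homogeneous block networks (`w_ij` depends only on
memberships) the spectral vectors are exactly uniform and the two
reductions coincide; a one-group reduction returns the left Perron vector
and `𝒲₁₁ = ρ(W)`; with singleton groups everything is exact; isolated
nodes grouped with a connected node receive weight proportional to the
positivization strength.

**Positivization.** Matrices with zeros are made strictly positive by
replacing zero entries with a weak `ε` before the spectral solve; default
`ε = 10⁻⁴ ×` (smallest positive weight), small enough not to move the
dominant eigenstructure materially.  `ε` is exposed everywhere; the
isolated-node study verifies the `ε → 0` behaviour explicitly.

## Built-in dynamics

| model | f(x) | g(x, y) | defaults |
|---|---|---|---|
| neuronal | `−x` | `1/(1+exp(−τ(y−μ)))` | `τ=0.3`, `μ=10` |
| sis | `−γx` | `(1−x)y` | `γ=1` |
| ecological | `B + x(1−x/K)(x/C−1)` | `xy/(D+Ex+Hy)` | `B=0.1, C=1, K=5, D=6, E=0.9, H=0.1` |

The neuronal model is a firing-rate (Wilson–Cowan type) unit with
sigmoidal input; its coupling ignores the receiver's state, so no
correction term arises.  The SIS coupling saturates as the receiver's
infected fraction approaches 1.  The ecological model combines migration
`B`, an Allee threshold `C`, carrying capacity `K` and a saturating
(Holling type II) mutualistic benefit; with the default parameters the
uncoupled unit is already bistable (stable states near 0.13 and 5.02).
Custom models plug in through the `(f, g, g1, g2, depends_on_first_arg)`
contract; supplied derivatives are checked against central finite
differences in the tests.

## Bifurcation sweeps

All weights are scaled by a global factor σ over a strictly increasing
grid; at each point the system is integrated to equilibrium (LSODA,
adaptive chunks) and convergence is declared when the infinity norm of the
rhs drops below `tol` (default `1e-9`, `t_max = 2000` time units) — an
integrator-step-independent criterion.  Diverging states (norm `> 1e6`)
are flagged non-converged, not raised: losing an equilibrium is data.  The
up-sweep starts from a low state (`1e-3` by default) and continues each
point from the previous equilibrium; the down-sweep continues from the
final up-sweep state.  A small elementwise floor (default `1e-3`) is
applied to continuation initial conditions so that branches that have
decayed to numerical zero (e.g. the disease-free SIS state) can be
re-excited past a transcritical threshold; without it the sweep would sit
on an invariant manifold forever and miss the bifurcation.

Diagrams are summarized by `⟨X⟩ = (1/N) Σ_ν m_ν X_ν` against the reduced
system's mean in-degree `⟨K⟩ = (1/N) Σ_ν m_ν Σ_ρ 𝒲_νρ`, which is exactly
linear in σ.  Exact and reduced diagrams are matched on the shared
(σ, direction) grid — never by interpolating `⟨K⟩` — and the exact
system's equilibria are projected with the *same* reduction vectors being
evaluated, so each method is scored against its own observables.  The
discrepancy measure is the RMSE of `⟨X⟩` over matched converged records;
non-converged records are excluded and counted.  Full-system equilibrium
states can be recorded once and re-projected for every (method, partition)
combination, which the robustness ensembles exploit.

## Synthetic networks

*Directed SBM*: binary edge `j → i` with probability `p_{g(i) g(j)}`
(receiver-row convention), independent, self-loops excluded by default.
*Degree-corrected variant*: every node draws an in- and an out-propensity,
normalized to mean 1 within each group; edge probability `min(1, p θ_i^in
θ_j^out)`.  The default propensity family is a truncated power law with
density exponent 2.5 on `[1, 50]` — heavy-tailed enough to produce the
strong within-community degree variability seen in real networks (mean
within-group in-degree CV ≈ 0.77 vs ≈ 0.14 for the plain SBM at the
benchmark densities) — with lognormal and constant families selectable.
The min(1, ·) cap follows Chung–Lu convention; a warning is logged when it
binds on more than 1% of pairs, since realized densities then fall short
of nominal ones (unavoidable for heavy tails over blocks as dense as 0.6).
*Homogeneous block fixture*: the deterministic `w_ij = c_{g(i) g(j)}`
network on which homogeneous and spectral reductions provably coincide.

What the generators emulate — and what they do not: block structure with
planted communities, within-community degree heterogeneity, bipartite-like
asymmetric densities.  They do not produce degree–degree correlations,
clustering/motif structure, weighted (non-binary) empirical weights, or
inhibitory interactions; passing the benchmark studies therefore says
nothing about networks dominated by those features.

## Partition refinement and perturbation

*Refinement*: repeatedly compute, for every group and every group-resolved
degree feature (weighted in-degree from, and out-degree to, each *current*
group), the within-group spread `max − min`; split the worst (group,
feature) pair at the feature midpoint.  Deterministic; singleton groups
are never split; perfectly homogeneous partitions return early with a
warning.  The midpoint rule is one concrete spread-reduction criterion and
is pluggable by design; note that because features are recomputed against
the finer partition, the *global* maximum spread is not guaranteed to
decrease monotonically along the trace (only the split feature's spread
halves within each child) — the tests assert exactly the guaranteed
properties.  The rule is scale-free in the degrees: a spread of 1 is
treated the same at degree 1 and at degree 20, which is why very fine
refinements can be needed to separate single-edge heterogeneities.

*Perturbation*: `⌊fN⌋` membership swaps of uniformly drawn cross-group
node pairs (same-group draws rejected), preserving the number of groups
and every group size exactly; seeded and reproducible.  The robustness
ensemble perturbs a base partition `replicates` times per perturbation
fraction, rebuilds both reductions per replicate, and reports mean ± std
of the diagram RMSE relative to the unperturbed spectral RMSE.

## Benchmark studies and sizes

The replication studies (`netreduce.studies`) run on 200-node,
two-equal-community networks with block densities 0.3 / 0.05 / 0.1 / 0.6
and neuronal dynamics (`τ=0.3`, threshold 10), swept both ways over 40
log-spaced points spanning mean in-degree 2–30 (bracketing the sigmoid
threshold) with equilibrium tolerance `1e-6`:

- *homogeneous study*: 5 network draws; RMSE at `n=1` and at the true
  `n=2` partition for both methods;
- *heterogeneous study*: 8 draws of the degree-corrected variant; the true
  partition refined to `n = 2, 5, 13` (8 draws rather than the minimal 5
  to tame the Monte Carlo error of a between-method comparison whose gap
  is small at `n=2`);
- *perturbation study*: one draw, 30 replicates per `f ∈ {0, 0.1, 0.3}`.

Observed behaviour (recomputed by `scripts/acceptance.py` and the
acceptance tests, not quoted from elsewhere): both methods are nearly
equivalent on plain block models at the true partition and much better
than a one-group reduction; on degree-corrected networks refinement
improves both methods and the spectral one stays at least as accurate at
every dimension; perturbing the partition degrades both methods, the
homogeneous one faster, with the two tied at `f = 0`.

## Numerical choices and degenerate inputs

- Reduction-vector normalization is enforced to `1e-12`; residuals are
  Euclidean norms, reported per pair and as summed squares.
- Dominant eigenvalues use dense solvers (intended for groups up to a few
  thousand nodes); a complex dominant pair beyond tolerance raises with
  the offending group pair named.
- The one-node group case short-circuits to `â = (1)`.
- Equilibrium integration is deterministic; no seeds are involved in any
  flow.  All stochastic stages (generation, perturbation) draw from
  independent streams spawned from one global seed, so adding replicates
  never shifts earlier draws.
- Empty groups, non-contiguous partitions passed to block decomposition,
  negative weights, duplicate edges and malformed files are rejected with
  specific messages (line numbers for file errors).

## Known limitations

- Positive-weight networks only; no inhibition.
- Linear observables only (no higher-order closures).
- Partition *search* is out of scope: partitions come from the user, the
  generators' ground truth, or spread-based refinement of either.
- The sweep tracks stable equilibria reachable by natural continuation;
  disconnected attractor branches that neither sweep direction visits are
  not reported.
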