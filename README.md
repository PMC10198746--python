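# netreduce

Dimension reduction of dynamical systems on weighted directed networks,
with an emphasis on modular and heterogeneous connectivity.

Large networked systems — neuronal circuits, ecosystems, contact networks —
evolve by

```
dx_i/dt = f(x_i) + Σ_j w_ij g(x_i, x_j),      i = 1, …, N,
```

where `f` is the self-dynamics, `g` the pairwise coupling, and `w_ij ≥ 0`
the strength of the influence of node `j` on node `i` (row = receiver
throughout).  Predicting their tipping points — the coupling strengths at
which equilibria appear, vanish, or exchange stability — is hard at full
dimension.  `netreduce` replaces the N-dimensional system with an
n-dimensional one built on a node partition into `n` groups of similar
connectivity.  Each group `G_ν` gets an *observable*

```
X_ν = Σ_{i∈G_ν} a_νi x_i,      a_ν ≥ 0,  Σ_i a_νi = 1,
```

and the reduced dynamics mirrors the original with an n×n reduced
adjacency matrix `𝒲_νρ = Σ_{i∈G_ν} a_νi k_i^ρ` (the a-weighted in-degrees
received from group ρ) plus, when `g` depends on the receiver's activity,
a correction term driven by the Rayleigh-quotient in-degree averages
`μ_νρ = â_νᵀ K_νρ â_ν / ‖â_ν‖²`.

Two choices of reduction vectors are implemented:

- **homogeneous** — `a_νi = 1/m_ν`: plain group averages, the baseline
  coarse-graining;
- **spectral** — the vectors approximately solve eigenvector-type
  *compatibility equations*: each `â_ν` should simultaneously be the
  dominant (Perron) eigenvector of the within-group interaction matrix
  `W_ννᵀ` and of every 2-step matrix `W_ρνᵀ W_νρᵀ` (paths through group ρ).
  Since these equations are generically incompatible, each scalar is fixed
  at the dominant eigenvalue of its matrix and `â_ν` minimizes the summed
  quadratic residual over the probability simplex (closed-form KKT solve,
  with an active-set fallback when nonnegativity needs to be enforced).
  The weights are, in effect, within-group eigenvector centralities.

The package also ships the synthetic network families used to exercise the
methods (directed stochastic block model, Chung–Lu-style degree-corrected
block model, perfectly homogeneous block fixtures), the three classic
dynamics (firing-rate/neuronal, SIS epidemic, mutualistic ecological),
hysteresis bifurcation sweeps, degree-spread partition refinement, and
partition-perturbation robustness ensembles.

## Worked example

Reduce a 200-node directed network with two planted communities (densities
0.3 / 0.05 / 0.1 / 0.6) under firing-rate dynamics, and compare full and
reduced bifurcation diagrams:

```python
import numpy as np
import netreduce as nr

spec = nr.BlockSpec(sizes=np.array([100, 100]),
                    density=np.array([[0.3, 0.05], [0.1, 0.6]]))
net = nr.directed_sbm(spec, seed=1)
part = spec.partition()

rsys = nr.reduce_network(net, part, "spectral")
print(np.round(rsys.reduced_adjacency, 2))

model = nr.builtin_model("neuronal")          # tau=0.3, threshold 10
cfg = nr.SweepConfig(
    sigmas=nr.default_sigma_grid(nr.mean_indegree(rsys), 2.0, 30.0, 40),
    tol=1e-6)
exact = nr.sweep_full(model, net, rsys, cfg, record_states=True)
reduced = nr.sweep_reduced(model, rsys, cfg)
print("RMSE(spectral, n=2) =", round(nr.diagram_rmse(exact, reduced), 3))

r1 = nr.reduce_network(net, nr.NodePartition.single_group(200), "spectral")
e1 = nr.reproject_full_diagram(exact, r1)
d1 = nr.sweep_reduced(model, r1, cfg)
print("RMSE(spectral, n=1) =", round(nr.diagram_rmse(e1, d1), 3))
```

Output:

```
[[29.93  5.1 ]
 [ 9.7  60.03]]
RMSE(spectral, n=2) = 0.151
RMSE(spectral, n=1) = 1.701
```

The reduced adjacency says each node of community 1 receives, on a
centrality-weighted average, coupling 29.93 from its own community and 5.1
from community 2 (community 2 is the denser one: 60.03 internally).  The
RMSE is the root-mean-square gap in the mean equilibrium observable `⟨X⟩`
between the exact and reduced bifurcation diagrams over the swept coupling
range: the two-group reduction tracks the 200-dimensional system an order
of magnitude better than collapsing the network to a single group.

The same workflow is available from the shell:

```bash
netreduce generate sbm --config block.yaml --seed 1 --out net.tsv
netreduce reduce --method spectral --net net.tsv --partition part.tsv --out red.json
netreduce sweep --net net.tsv --partition part.tsv --method spectral \
    --model neuronal --out reduced.csv
netreduce run --config run.yaml          # full pipeline incl. RMSE
```

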