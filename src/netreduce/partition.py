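"""Partition refinement and perturbation, and reduction-robustness ensembles.

Refinement splits groups to reduce the within-group spread of
group-resolved weighted in/out-degrees, producing nested partitions of
increasing dimension.  Perturbation randomly swaps node memberships while
preserving all group sizes, to probe how sensitive each reduction method is
to a misspecified partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .bifurcation import (
    BifurcationDiagram,
    SweepConfig,
    diagram_rmse,
    reproject_full_diagram,
    sweep_full,
    sweep_reduced,
)
from .dynamics import DynamicsModel
from .graph import NodePartition, WeightedDigraph
from .reduction import reduce_network

logger = logging.getLogger(__name__)

METHODS = ("spectral", "homogeneous")


@dataclass(frozen=True)
class SplitStep:
    """One refinement step: which group was split on which degree feature."""

    group: int
    feature_kind: str  # "in" (weighted in-degree from) | "out" (weighted out-degree to)
    other_group: int
    spread: float
    threshold: float


@dataclass(frozen=True)
class RefinementTrace:
    """Nested partitions of strictly increasing dimension."""

    partitions: list[NodePartition]
    steps: list[SplitStep]

    @property
    def final(self) -> NodePartition:
        return self.partitions[-1]

    def partition_with(self, n_groups: int) -> NodePartition:
        for p in self.partitions:
            if p.n_groups == n_groups:
                return p
        raise ValueError(f"no partition with {n_groups} groups in the trace")


def _group_features(
    w: npt.NDArray[np.float64], groups: list[npt.NDArray[np.intp]], nu: int
) -> list[tuple[str, int, npt.NDArray[np.float64]]]:
    """Group-resolved degree features of the nodes of group ``nu``.

    For every group ``rho`` of the *current* partition: the weighted
    in-degree received from ``rho`` and the weighted out-degree sent to
    ``rho``.
    """
    g = groups[nu]
    feats = []
    for rho, h in enumerate(groups):
        feats.append(("in", rho, w[np.ix_(g, h)].sum(axis=1)))
    for rho, h in enumerate(groups):
        feats.append(("out", rho, w[np.ix_(h, g)].sum(axis=0)))
    return feats


def refine(
    net: WeightedDigraph,
    part: NodePartition,
    target_n: int,
    *,
    spread_tol: float = 0.0,
) -> RefinementTrace:
    """Split groups until ``target_n`` groups, reducing degree spread.

    At every step, for every group and every group-resolved degree feature
    (weighted in-degree from / out-degree to each current group) the spread
    ``max - min`` over the group's nodes is computed; the (group, feature)
    pair with the largest spread is split at the feature's midpoint (nodes
    at or below the midpoint keep the old label, the rest form a new
    group).  Features are recomputed against the current partition after
    every split.  Deterministic; singleton groups are never split.  If
    every spread is ``<= spread_tol`` before ``target_n`` is reached the
    trace returns early with a warning (perfectly homogeneous groups).
    """
    if not (part.n_groups < target_n <= part.n_nodes):
        raise ValueError(
            f"target_n must lie in ({part.n_groups}, {part.n_nodes}], got {target_n}"
        )
    w = net.weights
    membership = part.membership.copy()
    partitions = [part]
    steps: list[SplitStep] = []
    while partitions[-1].n_groups < target_n:
        current = partitions[-1]
        groups = current.groups()
        best = None  # (spread, nu, kind, rho, values)
        for nu, g in enumerate(groups):
            if g.size <= 1:
                continue
            for kind, rho, vals in _group_features(w, groups, nu):
                spread = float(vals.max() - vals.min())
                if best is None or spread > best[0]:
                    best = (spread, nu, kind, rho, vals)
        if best is None or best[0] <= spread_tol:
            logger.warning(
                "all within-group degree spreads are <= %g at n=%d; "
                "stopping refinement before target_n=%d",
                spread_tol,
                current.n_groups,
                target_n,
            )
            break
        spread, nu, kind, rho, vals = best
        mid = float(vals.min() + vals.max()) / 2.0
        g = groups[nu]
        movers = g[vals > mid]
        membership = membership.copy()
        membership[movers] = current.n_groups
        partitions.append(NodePartition(membership, current.n_groups + 1))
        steps.append(
            SplitStep(group=nu, feature_kind=kind, other_group=rho, spread=spread, threshold=mid)
        )
    return RefinementTrace(partitions=partitions, steps=steps)


def perturb(
    part: NodePartition, f: float, seed: int | np.random.Generator
) -> NodePartition:
    """Randomly swap memberships of ``floor(f * N)`` cross-group node pairs.

    Each swap exchanges the group labels of two nodes drawn uniformly from
    *different* groups (same-group draws are rejected and redrawn), so the
    number of groups and every group size are preserved exactly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("perturbation fraction f must lie in [0, 1]")
    if part.n_groups < 2:
        raise ValueError("perturbation needs at least 2 groups")
    rng = np.random.default_rng(seed)
    membership = part.membership.copy()
    n = part.n_nodes
    for _ in range(int(np.floor(f * n))):
        while True:
            i, j = rng.integers(0, n, size=2)
            if membership[i] != membership[j]:
                break
        membership[i], membership[j] = membership[j], membership[i]
    return NodePartition(membership, part.n_groups)


@dataclass(frozen=True)
class PerturbationEnsemble:
    """Robustness of each reduction method under partition perturbation.

    ``rel_rmse_mean[method][k]`` / ``rel_rmse_std[method][k]`` summarize,
    over replicates, the diagram RMSE at perturbation fraction
    ``f_grid[k]``, divided by the spectral RMSE of the unperturbed
    partition.
    """

    f_grid: npt.NDArray[np.float64]
    n_replicates: int
    baseline_rmse: float  # spectral RMSE at f = 0
    rmse: dict = field(default_factory=dict)  # method -> (n_f, n_rep) array
    n_failures: int = 0

    def rel_rmse_mean(self, method: str) -> npt.NDArray[np.float64]:
        return np.nanmean(self.rmse[method], axis=1) / self.baseline_rmse

    def rel_rmse_std(self, method: str) -> npt.NDArray[np.float64]:
        return np.nanstd(self.rmse[method], axis=1) / self.baseline_rmse


def robustness_ensemble(
    net: WeightedDigraph,
    model: DynamicsModel,
    part0: NodePartition,
    f_grid,
    replicates: int,
    seed: int,
    cfg: SweepConfig,
    *,
    full_diagram: BifurcationDiagram | None = None,
    methods=METHODS,
) -> PerturbationEnsemble:
    """Measure diagram RMSE of both reductions under partition perturbation.

    For each fraction ``f`` and each replicate, the base partition is
    randomly perturbed, both reductions are built, and the RMSE between
    each reduced diagram and the exact one (projected with the replicate's
    own vectors) is recorded.  The full-system sweep does not depend on the
    partition, so it is computed once (or accepted precomputed through
    ``full_diagram``) and re-projected per replicate.  Failed sweeps are
    counted, not fatal.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    f_grid = np.asarray(f_grid, dtype=float)
    rng = np.random.default_rng(seed)

    rsys0 = {m: reduce_network(net, part0, m) for m in methods}
    if full_diagram is None:
        full_diagram = sweep_full(
            model, net, rsys0["spectral"], cfg, record_states=True
        )
    if full_diagram.states is None:
        raise ValueError("full diagram must carry states (record_states=True)")

    def rmse_for(rsys) -> float:
        exact = reproject_full_diagram(full_diagram, rsys)
        red = sweep_reduced(model, rsys, cfg)
        return diagram_rmse(exact, red)

    baseline = {m: rmse_for(rsys0[m]) for m in methods}
    out = {m: np.full((f_grid.size, replicates), np.nan) for m in methods}
    failures = 0
    for k, f in enumerate(f_grid):
        for r in range(replicates):
            if f == 0.0:
                for m in methods:
                    out[m][k, r] = baseline[m]
                continue
            pf = perturb(part0, float(f), rng)
            for m in methods:
                try:
                    out[m][k, r] = rmse_for(reduce_network(net, pf, m))
                except Exception:  # noqa: BLE001 - sweep failures are data
                    failures += 1
                    logger.exception("sweep failed at f=%g replicate %d", f, r)
    return PerturbationEnsemble(
        f_grid=f_grid,
        n_replicates=replicates,
        baseline_rmse=baseline["spectral"],
        rmse=out,
        n_failures=failures,
    )
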