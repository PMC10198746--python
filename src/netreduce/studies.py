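"""Reproducible benchmark studies on synthetic two-community networks.

These functions package the standard experiments used to validate the
reduction methods: a 200-node directed network with two communities of
equal size and asymmetric block densities (0.3 / 0.05 / 0.1 / 0.6),
firing-rate dynamics with sigmoid steepness 0.3 and threshold 10, and
bifurcation sweeps over a mean in-degree window covering the transitions.
The homogeneous variant draws from the plain block model; the
heterogeneous variant adds heavy-tailed degree propensities and exercises
partition refinement; the perturbation study measures robustness to a
misspecified partition.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import SweepConfig, default_sigma_grid, mean_indegree, sweep_full
from .dynamics import builtin_model
from .generators import BlockSpec, HeterogeneitySpec, directed_sbm, heterogeneous_sbm
from .graph import NodePartition, WeightedDigraph
from .partition import PerturbationEnsemble, refine, robustness_ensemble
from .reduction import reduce_network
from .validation import rmse_by_partition

#: Block densities of the benchmark two-community network (row = receiver).
TWO_COMMUNITY_DENSITY = np.array([[0.3, 0.05], [0.1, 0.6]])


def two_community_spec(n_nodes: int = 200) -> BlockSpec:
    half = n_nodes // 2
    return BlockSpec(sizes=np.array([half, n_nodes - half]), density=TWO_COMMUNITY_DENSITY)


def benchmark_sweep_config(
    base_mean_k: float,
    *,
    k_range: tuple[float, float] = (2.0, 30.0),
    num: int = 40,
    tol: float = 1e-6,
) -> SweepConfig:
    """Sweep protocol of the benchmark studies.

    40 log-spaced points per direction over a mean in-degree window of
    2-30 (bracketing the sigmoid threshold), both directions, equilibrium
    tolerance 1e-6 on the rhs infinity norm.
    """
    return SweepConfig(
        sigmas=default_sigma_grid(base_mean_k, k_range[0], k_range[1], num),
        direction="both",
        tol=tol,
    )


def _study_for_network(net: WeightedDigraph, partitions: dict[int, NodePartition]):
    model = builtin_model("neuronal")
    some = next(iter(partitions.values()))
    ref = reduce_network(net, some, "spectral")
    cfg = benchmark_sweep_config(mean_indegree(ref))
    full = sweep_full(model, net, ref, cfg, record_states=True)
    return rmse_by_partition(model, net, partitions, cfg, full_diagram=full)


def homogeneous_reduction_study(seeds, n_nodes: int = 200) -> dict:
    """Diagram RMSE at n=1 and n=2 on plain two-community block models.

    Returns per-seed RMSE lists and their means, keyed by ``(n, method)``.
    """
    spec = two_community_spec(n_nodes)
    acc: dict[tuple[int, str], list[float]] = {}
    for seed in seeds:
        net = directed_sbm(spec, int(seed))
        partitions = {
            1: NodePartition.single_group(net.n_nodes),
            2: spec.partition(),
        }
        for key, val in _study_for_network(net, partitions).items():
            acc.setdefault(key, []).append(val)
    return {
        "per_seed": acc,
        "mean": {key: float(np.mean(vals)) for key, vals in acc.items()},
    }


def heterogeneous_refinement_study(
    seeds, n_nodes: int = 200, refinement_ns: tuple[int, ...] = (2, 5, 13)
) -> dict:
    """Diagram RMSE along a refinement trace on degree-corrected networks.

    The two-community partition is refined by degree-spread splitting to
    each dimension in ``refinement_ns``; both reduction methods are scored
    against the same full sweep.
    """
    spec = two_community_spec(n_nodes)
    het = HeterogeneitySpec()
    target = max(refinement_ns)
    acc: dict[tuple[int, str], list[float]] = {}
    for seed in seeds:
        net = heterogeneous_sbm(spec, het, int(seed))
        trace = refine(net, spec.partition(), target)
        partitions = {n: trace.partition_with(n) for n in refinement_ns}
        for key, val in _study_for_network(net, partitions).items():
            acc.setdefault(key, []).append(val)
    return {
        "per_seed": acc,
        "mean": {key: float(np.mean(vals)) for key, vals in acc.items()},
    }


def perturbation_robustness_study(
    seed: int,
    *,
    n_nodes: int = 200,
    f_grid=(0.0, 0.1, 0.3),
    replicates: int = 30,
) -> PerturbationEnsemble:
    """Partition-perturbation robustness on a plain two-community network."""
    spec = two_community_spec(n_nodes)
    net = directed_sbm(spec, int(seed))
    part = spec.partition()
    model = builtin_model("neuronal")
    ref = reduce_network(net, part, "spectral")
    cfg = benchmark_sweep_config(mean_indegree(ref))
    return robustness_ensemble(
        net, model, part, list(f_grid), replicates, int(seed) + 1, cfg
    )
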