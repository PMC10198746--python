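"""Synthetic network generators with planted community structure.

Three families are provided:

* :func:`directed_sbm` — the directed stochastic block model: binary edges
  appear independently with a probability that depends only on the group
  membership of the two endpoints.  In the dense regime this produces
  *nearly homogeneous* communities (all nodes of a group have similar
  in/out-degrees).
* :func:`heterogeneous_sbm` — a degree-corrected variant inspired by the
  Chung–Lu model: each node carries an in- and an out-propensity drawn from
  a heavy-tailed distribution (mean 1 within each group), multiplying the
  block connection probability.  This plants strong degree heterogeneity
  *within* communities while preserving the expected block densities.
* :func:`homogeneous_block_fixture` — the deterministic, perfectly
  homogeneous modular network (``w_ij`` depends only on memberships); the
  setting in which homogeneous and spectral reductions provably coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .graph import NodePartition, WeightedDigraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockSpec:
    """Planted block structure: group sizes and connection densities.

    ``density[nu, rho]`` is the probability of an edge from a node of group
    ``rho`` to a node of group ``nu`` (receiver-row convention, matching the
    adjacency-matrix orientation).
    """

    sizes: npt.NDArray[np.intp]
    density: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.intp)
        dens = np.asarray(self.density, dtype=float)
        if sizes.ndim != 1 or np.any(sizes <= 0):
            raise ValueError("group sizes must be positive integers")
        n = sizes.size
        if dens.shape != (n, n):
            raise ValueError(f"density must be {n}x{n}, got {dens.shape}")
        if np.any(dens < 0) or np.any(dens > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "density", dens)

    @property
    def n_groups(self) -> int:
        return self.sizes.size

    @property
    def n_nodes(self) -> int:
        return int(self.sizes.sum())

    def partition(self) -> NodePartition:
        return NodePartition.from_sizes(self.sizes)


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Per-node propensity model for the degree-corrected block model.

    family
        ``"pareto"`` — truncated power law with density ``x^-(exponent)`` on
        ``[1, cutoff]``; heavy-tailed, the default emulation of real-network
        degree heterogeneity.
        ``"lognormal"`` — lognormal with shape ``sigma``.
        ``"constant"`` — all propensities 1 (degenerates to the plain SBM).
    params
        Family parameters: ``exponent`` and ``cutoff`` for ``"pareto"``
        (exponent > 1 required so the truncated mean exists at any cutoff),
        ``sigma`` for ``"lognormal"``.

    Propensities are drawn independently for the in- and out- direction of
    every node and normalized to mean 1 *within each group*, so expected
    block densities match the :class:`BlockSpec` up to the min(1, .) cap.
    """

    family: str = "pareto"
    params: dict = field(default_factory=lambda: {"exponent": 2.5, "cutoff": 50.0})

    def __post_init__(self) -> None:
        if self.family not in ("pareto", "lognormal", "constant"):
            raise ValueError(f"unknown propensity family {self.family!r}")
        if self.family == "pareto":
            a = float(self.params.get("exponent", 2.5))
            c = float(self.params.get("cutoff", 50.0))
            if a <= 1.0:
                raise ValueError("pareto exponent must exceed 1")
            if c <= 1.0:
                raise ValueError("pareto cutoff must exceed 1")
        if self.family == "lognormal" and float(self.params.get("sigma", 1.0)) <= 0:
            raise ValueError("lognormal sigma must be positive")

    def draw(self, size: int, rng: np.random.Generator) -> npt.NDArray[np.float64]:
        """Draw ``size`` positive propensities, normalized to mean 1."""
        if self.family == "constant":
            return np.ones(size)
        if self.family == "pareto":
            a = float(self.params.get("exponent", 2.5))
            c = float(self.params.get("cutoff", 50.0))
            # inverse-CDF sampling of a Pareto(a-1) truncated to [1, cutoff]
            u = rng.random(size)
            alpha = a - 1.0
            theta = (1.0 - u * (1.0 - c**-alpha)) ** (-1.0 / alpha)
        else:  # lognormal
            sigma = float(self.params.get("sigma", 1.0))
            theta = rng.lognormal(mean=0.0, sigma=sigma, size=size)
        return theta / theta.mean()


def directed_sbm(
    spec: BlockSpec, seed: int | np.random.Generator, *, self_loops: bool = False
) -> WeightedDigraph:
    """Sample a binary directed stochastic block model.

    Edge ``j -> i`` (entry ``(i, j)``) is present independently with
    probability ``density[g(i), g(j)]``.  Self-loops are excluded by
    default.
    """
    rng = np.random.default_rng(seed)
    part = spec.partition()
    p = spec.density[np.ix_(part.membership, part.membership)]
    w = (rng.random((spec.n_nodes, spec.n_nodes)) < p).astype(float)
    if not self_loops:
        np.fill_diagonal(w, 0.0)
    return WeightedDigraph(w)


def heterogeneous_sbm(
    spec: BlockSpec,
    het: HeterogeneitySpec,
    seed: int | np.random.Generator,
    *,
    self_loops: bool = False,
) -> WeightedDigraph:
    """Sample the degree-corrected (Chung–Lu style) directed block model.

    Edge ``j -> i`` appears with probability
    ``min(1, density[g(i), g(j)] * theta_in[i] * theta_out[j])``.  A warning
    is logged when the cap binds on more than 1% of node pairs, since then
    realized densities fall below the specification.
    """
    rng = np.random.default_rng(seed)
    part = spec.partition()
    n = spec.n_nodes
    theta_in = np.empty(n)
    theta_out = np.empty(n)
    for g in part.groups():
        theta_in[g] = het.draw(g.size, rng)
        theta_out[g] = het.draw(g.size, rng)
    p = spec.density[np.ix_(part.membership, part.membership)]
    p = p * np.outer(theta_in, theta_out)
    capped = p > 1.0
    if capped.mean() > 0.01:
        logger.warning(
            "probability cap min(1, .) binds on %.1f%% of pairs; realized "
            "densities will fall below the requested ones",
            100 * capped.mean(),
        )
    np.minimum(p, 1.0, out=p)
    w = (rng.random((n, n)) < p).astype(float)
    if not self_loops:
        np.fill_diagonal(w, 0.0)
    return WeightedDigraph(w)


def homogeneous_block_fixture(sizes, block_weights) -> WeightedDigraph:
    """Deterministic, perfectly homogeneous modular network.

    ``w_ij = c[nu, rho]`` for every ``i`` in group ``nu`` and ``j`` in group
    ``rho``, with ``c`` strictly positive.  On such networks the spectral
    reduction vectors are exactly uniform and coincide with the homogeneous
    reduction.
    """
    sizes = np.asarray(sizes, dtype=np.intp)
    c = np.asarray(block_weights, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("group sizes must be positive")
    if c.shape != (sizes.size, sizes.size):
        raise ValueError("block weight matrix shape must match number of groups")
    if np.any(c <= 0):
        raise ValueError("block weights must be strictly positive")
    member = np.repeat(np.arange(sizes.size), sizes)
    return WeightedDigraph(c[np.ix_(member, member)])
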