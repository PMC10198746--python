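"""Weighted directed networks, node partitions and block decompositions.

Orientation convention
----------------------
Throughout the package the adjacency matrix is stored with *row = receiver*:
``weights[i, j]`` is the strength of the interaction from node ``j`` to node
``i``, so that the dynamics reads ``dx_i/dt = f(x_i) + sum_j w_ij g(x_i, x_j)``
and the weighted in-degree of node ``i`` is the ``i``-th row sum.  Edge-list
files store ``(source, target, weight)`` and are transposed at the I/O
boundary (see :mod:`netreduce.io`).

Group indices are 0-based internally and 1-based in partition files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt


class ContiguityError(ValueError):
    """Partition is not contiguous with respect to node ordering."""


@dataclass(frozen=True)
class WeightedDigraph:
    """A weighted directed network on ``N`` nodes.

    Parameters
    ----------
    weights
        Square matrix of nonnegative interaction weights; entry ``(i, j)``
        is the strength of the influence of node ``j`` on node ``i``.
    """

    weights: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("network must have at least one node")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency matrix contains non-finite entries")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(
                f"negative weight at ({i}, {j}); only nonnegative interactions are supported"
            )
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def in_degrees(self) -> npt.NDArray[np.float64]:
        """Weighted in-degree of every node (row sums)."""
        return self.weights.sum(axis=1)

    @property
    def out_degrees(self) -> npt.NDArray[np.float64]:
        """Weighted out-degree of every node (column sums)."""
        return self.weights.sum(axis=0)

    def is_positive(self) -> bool:
        return bool(np.all(self.weights > 0))

    def scaled(self, sigma: float) -> "WeightedDigraph":
        """Uniformly rescale every interaction weight by ``sigma > 0``."""
        if sigma <= 0:
            raise ValueError("scale must be positive")
        return WeightedDigraph(self.weights * sigma)


@dataclass(frozen=True)
class NodePartition:
    """Assignment of each node to exactly one of ``n`` groups.

    ``membership[i]`` is the (0-based) group index of node ``i``.  Every
    group must be nonempty and group indices must cover ``0..n-1``.
    """

    membership: npt.NDArray[np.intp]
    n_groups: int = field(default=0)

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=np.intp)
        if m.ndim != 1 or m.size == 0:
            raise ValueError("membership must be a nonempty 1-d sequence")
        n = self.n_groups if self.n_groups else int(m.max()) + 1
        if m.min() < 0 or m.max() >= n:
            raise ValueError(f"group indices must lie in 0..{n - 1}")
        counts = np.bincount(m, minlength=n)
        if np.any(counts == 0):
            empty = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(f"group {empty} is empty")
        object.__setattr__(self, "membership", m)
        object.__setattr__(self, "n_groups", n)

    @property
    def n_nodes(self) -> int:
        return self.membership.size

    @property
    def group_sizes(self) -> npt.NDArray[np.intp]:
        return np.bincount(self.membership, minlength=self.n_groups)

    def groups(self) -> list[npt.NDArray[np.intp]]:
        """Node indices of each group, in group order."""
        return [np.flatnonzero(self.membership == nu) for nu in range(self.n_groups)]

    def is_contiguous(self) -> bool:
        """True if group members occupy consecutive indices in group order."""
        expected = np.repeat(np.arange(self.n_groups), self.group_sizes)
        return bool(np.array_equal(self.membership, expected))

    def offsets(self) -> npt.NDArray[np.intp]:
        """Start index of each group (and N) for a contiguous partition."""
        if not self.is_contiguous():
            raise ContiguityError("partition is not contiguous; relabel first")
        return np.concatenate([[0], np.cumsum(self.group_sizes)])

    @classmethod
    def singletons(cls, n_nodes: int) -> "NodePartition":
        return cls(np.arange(n_nodes))

    @classmethod
    def single_group(cls, n_nodes: int) -> "NodePartition":
        return cls(np.zeros(n_nodes, dtype=np.intp))

    @classmethod
    def from_sizes(cls, sizes) -> "NodePartition":
        sizes = np.asarray(sizes, dtype=np.intp)
        if np.any(sizes <= 0):
            raise ValueError("group sizes must be positive")
        return cls(np.repeat(np.arange(sizes.size), sizes))


@dataclass(frozen=True)
class BlockDecomposition:
    """Group-to-group submatrices and diagonal in-degree blocks.

    ``blocks[nu][rho]`` is the ``m_nu x m_rho`` submatrix of interactions
    from group ``rho`` to group ``nu``; ``indegree[nu][rho]`` is the length
    ``m_nu`` diagonal of the group-to-group weighted in-degree matrix, i.e.
    ``indegree[nu][rho][k]`` is the total weight node ``k`` of group ``nu``
    receives from group ``rho``.
    """

    blocks: list[list[npt.NDArray[np.float64]]]
    indegree: list[list[npt.NDArray[np.float64]]]
    partition: NodePartition

    @property
    def n_groups(self) -> int:
        return self.partition.n_groups

    def reassemble(self) -> npt.NDArray[np.float64]:
        """Stitch the blocks back into the full adjacency matrix."""
        return np.block(self.blocks)


def relabel_by_partition(
    net: WeightedDigraph, part: NodePartition
) -> tuple[WeightedDigraph, NodePartition, npt.NDArray[np.intp]]:
    """Permute nodes so members of each group are contiguous, in group order.

    Returns the relabeled network, the relabeled (contiguous) partition and
    the permutation ``perm`` with ``new_index k  <-  old_index perm[k]``,
    i.e. ``W_new = W[perm][:, perm]``.  A stable sort is used, so the
    relative order of nodes within a group is preserved.
    """
    if part.n_nodes != net.n_nodes:
        raise ValueError(
            f"partition covers {part.n_nodes} nodes but network has {net.n_nodes}"
        )
    perm = np.argsort(part.membership, kind="stable")
    new_net = WeightedDigraph(net.weights[np.ix_(perm, perm)])
    new_part = NodePartition(part.membership[perm], part.n_groups)
    return new_net, new_part, perm


def inverse_permutation(perm: npt.NDArray[np.intp]) -> npt.NDArray[np.intp]:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return inv


def block_decompose(net: WeightedDigraph, part: NodePartition) -> BlockDecomposition:
    """Split the adjacency matrix into group-to-group blocks.

    The network must already be contiguous with respect to ``part``
    (call :func:`relabel_by_partition` first if not).
    """
    if part.n_nodes != net.n_nodes:
        raise ValueError("partition size does not match network size")
    off = part.offsets()  # raises ContiguityError when not contiguous
    w = net.weights
    blocks: list[list[np.ndarray]] = []
    indeg: list[list[np.ndarray]] = []
    for nu in range(part.n_groups):
        row_b, row_k = [], []
        rows = slice(off[nu], off[nu + 1])
        for rho in range(part.n_groups):
            sub = w[rows, off[rho]:off[rho + 1]]
            row_b.append(sub)
            row_k.append(sub.sum(axis=1))
        blocks.append(row_b)
        indeg.append(row_k)
    return BlockDecomposition(blocks=blocks, indegree=indeg, partition=part)


def positivize(net: WeightedDigraph, epsilon: float | None = None) -> WeightedDigraph:
    """Replace zero weights by a small positive ``epsilon``.

    The compatibility-equation machinery relies on Perron–Frobenius theory
    and therefore needs a strictly positive matrix; missing interactions are
    treated as arbitrarily weak ones.  When ``epsilon`` is not given it
    defaults to ``1e-4`` times the smallest positive weight, small enough
    not to shift the dominant eigenstructure materially.
    """
    w = net.weights
    if epsilon is None:
        pos = w[w > 0]
        if pos.size == 0:
            raise ValueError("all-zero matrix: supply epsilon explicitly")
        epsilon = 1e-4 * float(pos.min())
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not np.any(w == 0):
        return net
    out = w.copy()
    out[out == 0] = epsilon
    return WeightedDigraph(out)
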