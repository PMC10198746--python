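"""Plain-text file formats for networks, partitions and reduction results.

Formats
-------
Edge-list TSV
    Header line ``source\\ttarget\\tweight`` required; node ids 1-based.
    Rows store ``source -> target``; at load the matrix is transposed into
    the package's row = receiver convention (``w[target, source]``).
Dense matrix
    Whitespace-delimited text; row ``i`` is receiver ``i`` (no transpose).
Partition TSV
    ``node_id\\tgroup_id``, both 1-based; converted to 0-based group
    indices at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .graph import NodePartition, WeightedDigraph
from .reduction import ReducedSystem

EDGELIST_HEADER = ("source", "target", "weight")


def load_dense(path) -> WeightedDigraph:
    w = np.loadtxt(path, ndmin=2)
    return WeightedDigraph(w)


def save_dense(path, net: WeightedDigraph) -> None:
    np.savetxt(path, net.weights)


def load_edgelist(path, n_nodes: int | None = None) -> WeightedDigraph:
    """Load a TSV edge list (source, target, weight; 1-based node ids).

    Duplicate (source, target) rows and negative weights are rejected.  The
    number of nodes defaults to the largest node id seen.
    """
    path = Path(path)
    edges: dict[tuple[int, int], float] = {}
    first_line: dict[tuple[int, int], int] = {}
    with open(path) as fh:
        header = fh.readline()
        cols = tuple(tok.strip().lower() for tok in header.rstrip("\n").split("\t"))
        if cols != EDGELIST_HEADER:
            raise ValueError(
                f"{path}: expected header {'	'.join(EDGELIST_HEADER)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                s, t = int(parts[0]), int(parts[1])
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if s < 1 or t < 1:
                raise ValueError(f"{path}:{lineno}: node ids must be >= 1")
            if w < 0:
                raise ValueError(
                    f"{path}:{lineno}: negative weight {w}; only nonnegative "
                    "(excitatory/facilitating) interactions are supported"
                )
            key = (s, t)
            if key in edges:
                raise ValueError(
                    f"{path}:{lineno}: duplicate edge ({s}, {t}) first seen on "
                    f"line {first_line[key]}"
                )
            edges[key] = w
            first_line[key] = lineno
    if not edges:
        raise ValueError(f"{path}: no edges")
    max_id = max(max(s, t) for s, t in edges)
    n = n_nodes if n_nodes is not None else max_id
    if max_id > n:
        raise ValueError(f"{path}: node id {max_id} exceeds n_nodes={n}")
    mat = np.zeros((n, n))
    for (s, t), w in edges.items():
        mat[t - 1, s - 1] = w  # transpose into row = receiver
    return WeightedDigraph(mat)


def save_edgelist(path, net: WeightedDigraph) -> None:
    """Write nonzero entries as a 1-based (source, target, weight) TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGELIST_HEADER) + "\n")
        rows, cols = np.nonzero(net.weights)
        for i, j in zip(rows, cols):  # entry (i, j): j -> i
            fh.write(f"{j + 1}\t{i + 1}\t{net.weights[i, j]:.17g}\n")


def load_partition(path, n_nodes: int | None = None) -> NodePartition:
    """Load a ``node_id<TAB>group_id`` file (both 1-based)."""
    path = Path(path)
    assignments: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node_id group_id'")
            node, group = int(parts[0]), int(parts[1])
            if node < 1 or group < 1:
                raise ValueError(f"{path}:{lineno}: ids must be >= 1")
            if node in assignments:
                raise ValueError(f"{path}:{lineno}: node {node} assigned twice")
            assignments[node] = group
    n = n_nodes if n_nodes is not None else max(assignments)
    if set(assignments) != set(range(1, n + 1)):
        missing = sorted(set(range(1, n + 1)) - set(assignments))[:5]
        raise ValueError(f"{path}: missing assignments for nodes {missing}")
    membership = np.array([assignments[i + 1] - 1 for i in range(n)], dtype=np.intp)
    # compress group labels to consecutive 0..n-1 preserving order
    uniq = np.unique(membership)
    remap = {g: k for k, g in enumerate(uniq)}
    membership = np.array([remap[g] for g in membership], dtype=np.intp)
    return NodePartition(membership)


def save_partition(path, part: NodePartition) -> None:
    with open(path, "w") as fh:
        for i, g in enumerate(part.membership):
            fh.write(f"{i + 1}\t{g + 1}\n")


def reduction_to_dict(rsys: ReducedSystem) -> dict:
    """JSON-serializable summary of a reduced system."""
    doc = {
        "method": rsys.vectors.method,
        "n_groups": rsys.n_groups,
        "group_sizes": rsys.partition.group_sizes.tolist(),
        "reduced_adjacency": rsys.reduced_adjacency.tolist(),
        "correction": rsys.correction.tolist(),
        "partial_vectors": [v.tolist() for v in rsys.vectors.partial_vectors],
        "permutation": rsys.permutation.tolist(),
    }
    if rsys.report is not None:
        doc["lambda_prime"] = rsys.report.lambda_prime.tolist()
        doc["residual_adjacency"] = rsys.report.residual_adjacency.tolist()
        doc["residual_indegree"] = rsys.report.residual_indegree.tolist()
    return doc


def save_reduction(path, rsys: ReducedSystem, extra: dict | None = None) -> None:
    doc = reduction_to_dict(rsys)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
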