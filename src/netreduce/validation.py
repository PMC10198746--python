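"""Diagram-based validation utilities: hysteresis windows and quality studies.

These helpers implement the standard protocol for judging a reduction:
sweep the full and the reduced system over the same coupling grid and
compare the diagrams.  The scalar-system root/stability analysis provides
an ODE-free cross-check of bistable windows for one-dimensional reductions.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt
from scipy.optimize import brentq

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


def hysteresis_window(
    diagram: BifurcationDiagram, atol: float = 1e-3
) -> tuple[float, float] | None:
    """``<K>`` interval over which the up and down branches disagree.

    Returns ``None`` when the diagram exhibits no hysteresis beyond
    ``atol``.  Requires a both-directions sweep on a single grid.
    """
    up = diagram.direction == "up"
    k_up = diagram.mean_k[up]
    x_up = diagram.mean_x[up]
    order = np.argsort(diagram.mean_k[~up])
    k_dn = diagram.mean_k[~up][order]
    x_dn = diagram.mean_x[~up][order]
    if k_up.size != k_dn.size or not np.allclose(k_up, k_dn):
        raise ValueError("up and down sweeps do not share a grid")
    differ = np.abs(x_up - x_dn) > atol
    if not differ.any():
        return None
    return float(k_up[differ].min()), float(k_up[differ].max())


def stable_equilibria_1d(
    model: DynamicsModel, k: float, *, x_max: float = 50.0, n_scan: int = 4001
) -> list[float]:
    """Stable equilibria of the scalar system ``dX/dt = f(X) + k g(X, X)``.

    Root-finding on a fine bracket scan plus a derivative-sign stability
    test; independent of any ODE integration.
    """

    def h(x: float) -> float:
        return float(model.f(np.asarray(x)) + k * model.g(np.asarray(x), np.asarray(x)))

    xs = np.linspace(1e-9, x_max, n_scan)
    vals = np.array([h(x) for x in xs])
    roots = []
    for a, b, va, vb in zip(xs[:-1], xs[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(float(a))
        elif va * vb < 0:
            roots.append(float(brentq(h, a, b, xtol=1e-12)))
    eps = 1e-7
    return [r for r in roots if h(r + eps) < h(r - eps)]


def bistable_window_1d(
    model: DynamicsModel, k_grid: npt.NDArray[np.float64], *, x_max: float = 50.0
) -> tuple[float, float] | None:
    """``k`` interval of the grid on which the scalar system is bistable."""
    bist = np.array(
        [len(stable_equilibria_1d(model, float(k), x_max=x_max)) >= 2 for k in k_grid]
    )
    if not bist.any():
        return None
    return float(k_grid[bist].min()), float(k_grid[bist].max())


def rmse_by_partition(
    model: DynamicsModel,
    net: WeightedDigraph,
    partitions: dict[int, NodePartition],
    cfg: SweepConfig,
    *,
    methods=("spectral", "homogeneous"),
    full_diagram: BifurcationDiagram | None = None,
) -> dict[tuple[int, str], float]:
    """Diagram RMSE for every (partition dimension, method) combination.

    The expensive full-system sweep is run once (states recorded) and
    re-projected with each reduction's own vectors, as the comparison
    protocol prescribes.
    """
    some_part = next(iter(partitions.values()))
    if full_diagram is None:
        ref = reduce_network(net, some_part, methods[0])
        full_diagram = sweep_full(model, net, ref, cfg, record_states=True)
    out: dict[tuple[int, str], float] = {}
    for n, part in partitions.items():
        for m in methods:
            rsys = reduce_network(net, part, m)
            exact = reproject_full_diagram(full_diagram, rsys)
            reduced = sweep_reduced(model, rsys, cfg)
            out[(n, m)] = diagram_rmse(exact, reduced)
    return out
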