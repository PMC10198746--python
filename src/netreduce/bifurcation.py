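"""Equilibrium sweeps, bifurcation diagrams and diagram discrepancy.

A bifurcation diagram is traced by scaling every interaction weight by a
global factor ``sigma``, integrating the system to equilibrium at each grid
point, and using the equilibrium found at one point as the initial
condition of the next (natural continuation).  Sweeping ``sigma`` up and
then back down exposes bistable windows as hysteresis between the two
branches.

Diagrams are summarized by the group-size-weighted average observable
``<X> = (1/N) sum_nu m_nu X_nu`` plotted against the average weighted
in-degree of the reduced system ``<K> = (1/N) sum_nu m_nu sum_rho W_red[nu,
rho]`` (linear in ``sigma``).  The discrepancy between an exact and a
reduced diagram is the root-mean-square error of ``<X>`` over matched grid
points; the exact system's observables are always projected with the same
reduction vectors being evaluated, so each method is compared against its
own projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import numpy.typing as npt
import pandas as pd

from .dynamics import DynamicsModel, full_rhs, integrate_to_equilibrium, reduced_rhs
from .graph import NodePartition, WeightedDigraph
from .reduction import ReducedSystem

Array = npt.NDArray[np.float64]


@dataclass(frozen=True)
class SweepConfig:
    """Protocol for a bifurcation sweep.

    sigmas
        Strictly increasing grid of positive global coupling multipliers.
    direction
        ``"up"``, ``"down"`` or ``"both"`` (up first, then down continuing
        from the final up-sweep equilibrium).
    x0_low
        Initial activity (scalar, broadcast) of the first up-sweep point: a
        "low" state.  Slightly positive by default so that invariant
        manifolds at zero (e.g. the disease-free state of epidemic models)
        do not trap the continuation.
    x0_high
        Initial activity of the first point of a standalone down-sweep;
        ignored when ``direction="both"``.
    continuation_floor
        Elementwise lower bound applied to the initial condition of every
        continuation step, so that a branch that has decayed to numerical
        zero can still be re-excited past a transcritical threshold.  Set
        to ``None`` to disable.
    tol, t_max
        Equilibrium detection: infinity norm of the rhs below ``tol``
        within ``t_max`` time units, else the record is flagged
        non-converged.
    """

    sigmas: npt.NDArray[np.float64]
    direction: str = "both"
    x0_low: float = 1e-3
    x0_high: float | None = None
    continuation_floor: float | None = 1e-3
    tol: float = 1e-9
    t_max: float = 2000.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        s = np.asarray(self.sigmas, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("sigma grid must be a nonempty 1-d array")
        if np.any(s <= 0):
            raise ValueError("sigma values must be positive")
        if s.size > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("sigma grid must be strictly increasing")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be 'up', 'down' or 'both'")
        object.__setattr__(self, "sigmas", s)


def default_sigma_grid(
    base_mean_k: float, k_min: float, k_max: float, num: int = 60
) -> npt.NDArray[np.float64]:
    """Log-spaced sigma grid mapping the sweep onto a target ``<K>`` range."""
    if base_mean_k <= 0 or k_min <= 0 or k_max <= k_min:
        raise ValueError("need 0 < k_min < k_max and positive base mean in-degree")
    return np.geomspace(k_min / base_mean_k, k_max / base_mean_k, num)


@dataclass(frozen=True)
class BifurcationDiagram:
    """Sequence of equilibrium records along a sweep.

    ``X`` holds the per-group observables (``n_records x n``); ``states``
    optionally holds the full equilibrium states (original node order) so
    that the same sweep can be re-projected with different reduction
    vectors.  Non-converged records carry NaN observables.
    """

    sigma: npt.NDArray[np.float64]
    direction: npt.NDArray  # "up" / "down" per record
    mean_k: npt.NDArray[np.float64]
    mean_x: npt.NDArray[np.float64]
    X: npt.NDArray[np.float64]
    converged: npt.NDArray[np.bool_]
    kind: str = "reduced"  # "full" | "reduced"
    states: npt.NDArray[np.float64] | None = None

    @property
    def n_records(self) -> int:
        return self.sigma.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sigma": self.sigma,
                "direction": self.direction,
                "mean_K": self.mean_k,
                "mean_X": self.mean_x,
                "converged": self.converged,
            }
        )
        for nu in range(self.X.shape[1]):
            df[f"X_{nu + 1}"] = self.X[:, nu]
        return df


def mean_observable(part: NodePartition, X: Array) -> float:
    """Group-size-weighted average of the observables."""
    X = np.asarray(X, dtype=float)
    sizes = part.group_sizes
    if X.shape != (part.n_groups,):
        raise ValueError(f"expected {part.n_groups} observables, got {X.shape}")
    return float(sizes @ X / part.n_nodes)


def mean_indegree(rsys: ReducedSystem, part: NodePartition | None = None) -> float:
    """Group-size-weighted average in-degree of the reduced network.

    Linear in a uniform weight scaling: scaling all original weights by
    ``sigma`` scales this quantity by exactly ``sigma``.
    """
    part = part if part is not None else rsys.partition
    k_nu = rsys.reduced_adjacency.sum(axis=1)
    return float(part.group_sizes @ k_nu / part.n_nodes)


def _run_sweep(
    cfg: SweepConfig,
    dim: int,
    equilibrate: Callable[[float, Array], tuple[Array, bool]],
) -> tuple[list[float], list[str], list[Array], list[bool]]:
    """Shared continuation loop over the sigma grid, both directions."""
    sigmas, dirs, states, flags = [], [], [], []

    def initial(which: str) -> Array:
        if which == "low":
            return np.full(dim, cfg.x0_low, dtype=float)
        high = cfg.x0_high if cfg.x0_high is not None else cfg.x0_low
        return np.full(dim, high, dtype=float)

    legs = []
    if cfg.direction in ("up", "both"):
        legs.append(("up", cfg.sigmas))
    if cfg.direction in ("down", "both"):
        legs.append(("down", cfg.sigmas[::-1]))

    x = None
    for leg, grid in legs:
        if x is None or cfg.direction != "both":
            x = initial("low" if leg == "up" else "high")
        for sigma in grid:
            x0 = x.copy()
            if cfg.continuation_floor is not None:
                np.maximum(x0, cfg.continuation_floor, out=x0)
            state, ok = equilibrate(float(sigma), x0)
            sigmas.append(float(sigma))
            dirs.append(leg)
            states.append(state)
            flags.append(ok)
            if ok:
                x = state
            else:
                # restart the continuation from the leg's initial policy
                x = initial("low" if leg == "up" else "high")
    return sigmas, dirs, states, flags


def sweep_reduced(
    model: DynamicsModel,
    rsys: ReducedSystem,
    cfg: SweepConfig,
    *,
    with_correction: bool = True,
) -> BifurcationDiagram:
    """Bifurcation diagram of the n-dimensional reduced system."""
    base_k = mean_indegree(rsys)
    part = rsys.partition

    def equilibrate(sigma: float, x0: Array) -> tuple[Array, bool]:
        rs = rsys.scaled(sigma)
        res = integrate_to_equilibrium(
            lambda X: reduced_rhs(model, rs, X, with_correction=with_correction),
            x0,
            tol=cfg.tol,
            t_max=cfg.t_max,
            rtol=cfg.rtol,
            atol=cfg.atol,
        )
        return res.state, res.converged

    sig, dirs, xs, ok = _run_sweep(cfg, rsys.n_groups, equilibrate)
    X = np.vstack(xs)
    ok = np.asarray(ok)
    X[~ok] = np.nan
    mean_x = np.array(
        [mean_observable(part, row) if c else np.nan for row, c in zip(X, ok)]
    )
    return BifurcationDiagram(
        sigma=np.asarray(sig),
        direction=np.asarray(dirs),
        mean_k=np.asarray(sig) * base_k,
        mean_x=mean_x,
        X=X,
        converged=ok,
        kind="reduced",
    )


def sweep_full(
    model: DynamicsModel,
    net: WeightedDigraph,
    rsys: ReducedSystem,
    cfg: SweepConfig,
    *,
    record_states: bool = False,
) -> BifurcationDiagram:
    """Bifurcation diagram of the full N-dimensional system.

    Equilibria are projected onto observables with the reduction vectors of
    ``rsys``, and the x-axis ``<K>`` is the reduced system's (scaled), so
    that the exact diagram is directly comparable with the reduced one.
    With ``record_states=True`` the full equilibrium states are kept so the
    sweep can later be re-projected with other vectors
    (:func:`reproject_full_diagram`) without re-integrating.
    """
    base_k = mean_indegree(rsys)

    def equilibrate(sigma: float, x0: Array) -> tuple[Array, bool]:
        w = net.scaled(sigma)
        res = integrate_to_equilibrium(
            lambda x: full_rhs(model, w, x),
            x0,
            tol=cfg.tol,
            t_max=cfg.t_max,
            rtol=cfg.rtol,
            atol=cfg.atol,
        )
        return res.state, res.converged

    sig, dirs, xs, ok = _run_sweep(cfg, net.n_nodes, equilibrate)
    ok = np.asarray(ok)
    states = np.vstack(xs)
    X = np.full((len(sig), rsys.n_groups), np.nan)
    for i, (x, c) in enumerate(zip(states, ok)):
        if c:
            X[i] = rsys.observe(x)
    mean_x = np.array(
        [
            mean_observable(rsys.partition, row) if c else np.nan
            for row, c in zip(X, ok)
        ]
    )
    return BifurcationDiagram(
        sigma=np.asarray(sig),
        direction=np.asarray(dirs),
        mean_k=np.asarray(sig) * base_k,
        mean_x=mean_x,
        X=X,
        converged=ok,
        kind="full",
        states=states if record_states else None,
    )


def reproject_full_diagram(
    diagram: BifurcationDiagram, rsys: ReducedSystem
) -> BifurcationDiagram:
    """Re-project a state-carrying full sweep with different vectors.

    The full equilibrium states do not depend on the reduction, so one
    expensive full sweep can serve every (method, partition) combination.
    """
    if diagram.states is None:
        raise ValueError("diagram carries no states; rerun with record_states=True")
    base_k = mean_indegree(rsys)
    X = np.full((diagram.n_records, rsys.n_groups), np.nan)
    mean_x = np.full(diagram.n_records, np.nan)
    for i, c in enumerate(diagram.converged):
        if c:
            X[i] = rsys.observe(diagram.states[i])
            mean_x[i] = mean_observable(rsys.partition, X[i])
    return replace(
        diagram, X=X, mean_x=mean_x, mean_k=diagram.sigma * base_k, kind="full"
    )


def diagram_rmse(
    exact: BifurcationDiagram,
    reduced: BifurcationDiagram,
    *,
    return_details: bool = False,
):
    """RMSE of ``<X>`` between two diagrams over matched grid points.

    Records are matched by (sigma, direction); only pairs in which both
    records converged enter the error.  The count of excluded records is
    available via ``return_details``.
    """
    key_e = {(s, d): i for i, (s, d) in enumerate(zip(exact.sigma, exact.direction))}
    diffs = []
    excluded = 0
    matched = 0
    for j, (s, d) in enumerate(zip(reduced.sigma, reduced.direction)):
        i = key_e.get((s, d))
        if i is None:
            continue
        matched += 1
        if exact.converged[i] and reduced.converged[j]:
            diffs.append(exact.mean_x[i] - reduced.mean_x[j])
        else:
            excluded += 1
    if matched == 0:
        raise ValueError("diagrams share no (sigma, direction) records")
    if not diffs:
        raise ValueError("no matched record converged in both diagrams")
    rmse = float(np.sqrt(np.mean(np.square(diffs))))
    if return_details:
        return rmse, {"n_matched": matched, "n_excluded": excluded}
    return rmse
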