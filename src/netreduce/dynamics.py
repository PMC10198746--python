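"""Node dynamics models and right-hand-side evaluation, full and reduced.

The full system on ``N`` nodes is
``dx_i/dt = f(x_i) + sum_j w_ij g(x_i, x_j)``: ``f`` defines the
self-dynamics, ``g`` the pairwise coupling, and ``w_ij`` the strength of
the influence of node ``j`` on node ``i``.  Three classic models ship with
the package:

* ``neuronal`` — firing-rate (Wilson–Cowan type) dynamics: linear decay
  ``f(x) = -x`` plus sigmoidal input ``g(x, y) = 1/(1 + exp(-tau (y - mu)))``
  with steepness ``tau`` and threshold ``mu``.  ``g`` is independent of the
  receiver's activity, so the reduced dynamics needs no correction term.
* ``sis`` — susceptible-infected-susceptible epidemic spreading:
  ``f(x) = -gamma x`` (recovery), ``g(x, y) = (1 - x) y`` (infection of the
  remaining susceptible fraction).
* ``ecological`` — mutualistic population dynamics with migration ``B``,
  Allee threshold ``C``, carrying capacity ``K`` and a saturating
  (Holling type II) mutualistic benefit:
  ``f(x) = B + x (1 - x/K)(x/C - 1)``, ``g(x, y) = x y / (D + E x + H y)``.

The reduced system on ``n`` observables mirrors the full one with the
reduced adjacency matrix in place of ``W`` and, when ``g`` depends on its
first argument, an additive correction
``sum_rho (mu - W_red)[nu, rho] g1(X_nu, X_rho) X_nu`` accounting for the
in-degree compatibility equations not being solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import numpy.typing as npt
from scipy.integrate import solve_ivp

from .graph import WeightedDigraph
from .reduction import ReducedSystem

Array = npt.NDArray[np.float64]
BivFunc = Callable[[Array, Array], Array]


@dataclass(frozen=True)
class DynamicsModel:
    """Contract for a node dynamics: ``f``, ``g`` and the partials of ``g``.

    All callables must be numpy-vectorized (accept and broadcast arrays).
    ``depends_on_first_arg`` flags whether ``g`` varies with the receiver's
    activity; when it does not, the correction machinery is skipped.
    """

    name: str
    f: Callable[[Array], Array]
    g: BivFunc
    g1: BivFunc
    g2: BivFunc
    depends_on_first_arg: bool
    params: dict = field(default_factory=dict)


def _neuronal(tau: float = 0.3, mu_thr: float = 10.0) -> DynamicsModel:
    if tau <= 0:
        raise ValueError("sigmoid steepness tau must be positive")

    def g(x, y):
        return 1.0 / (1.0 + np.exp(-tau * (y - mu_thr)))

    def g2(x, y):
        s = g(x, y)
        return tau * s * (1.0 - s)

    return DynamicsModel(
        name="neuronal",
        f=lambda x: -x,
        g=g,
        g1=lambda x, y: np.zeros(np.broadcast(x, y).shape),
        g2=g2,
        depends_on_first_arg=False,
        params={"tau": tau, "mu_thr": mu_thr},
    )


def _sis(gamma: float = 1.0) -> DynamicsModel:
    if gamma <= 0:
        raise ValueError("recovery rate gamma must be positive")
    return DynamicsModel(
        name="sis",
        f=lambda x: -gamma * x,
        g=lambda x, y: (1.0 - x) * y,
        g1=lambda x, y: -y * np.ones(np.broadcast(x, y).shape),
        g2=lambda x, y: (1.0 - x) * np.ones(np.broadcast(x, y).shape),
        depends_on_first_arg=True,
        params={"gamma": gamma},
    )


def _ecological(
    B: float = 0.1,
    C: float = 1.0,
    K_cap: float = 5.0,
    D: float = 6.0,
    E: float = 0.9,
    H: float = 0.1,
) -> DynamicsModel:
    for name, val in (("B", B), ("C", C), ("K_cap", K_cap), ("D", D), ("E", E), ("H", H)):
        if val <= 0:
            raise ValueError(f"ecological parameter {name} must be positive")
    if K_cap <= C:
        raise ValueError("carrying capacity K_cap must exceed the Allee threshold C")

    def g(x, y):
        return x * y / (D + E * x + H * y)

    def g1(x, y):
        den = D + E * x + H * y
        return y * (D + H * y) / den**2

    def g2(x, y):
        den = D + E * x + H * y
        return x * (D + E * x) / den**2

    return DynamicsModel(
        name="ecological",
        f=lambda x: B + x * (1.0 - x / K_cap) * (x / C - 1.0),
        g=g,
        g1=g1,
        g2=g2,
        depends_on_first_arg=True,
        params={"B": B, "C": C, "K_cap": K_cap, "D": D, "E": E, "H": H},
    )


_BUILTINS = {"neuronal": _neuronal, "sis": _sis, "ecological": _ecological}


def builtin_model(name: str, **params) -> DynamicsModel:
    """Instantiate one of the built-in dynamics by name.

    Defaults: neuronal ``tau=0.3, mu_thr=10``; SIS ``gamma=1``; ecological
    ``B=0.1, C=1, K_cap=5, D=6, E=0.9, H=0.1``.
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    return factory(**params)


def affine_model(a: float, b: float, c: float, d: float, e: float) -> DynamicsModel:
    """Affine dynamics ``f(x) = a + b x``, ``g(x, y) = c + d x + e y``.

    For affine ``f`` and ``g`` the first-order Taylor closure is exact, so
    on partitions where the compatibility equations hold exactly the reduced
    observables reproduce the projected full trajectory to integrator
    accuracy.  Used mainly for validation.
    """
    return DynamicsModel(
        name="affine",
        f=lambda x: a + b * x,
        g=lambda x, y: c + d * x + e * y,
        g1=lambda x, y: d * np.ones(np.broadcast(x, y).shape),
        g2=lambda x, y: e * np.ones(np.broadcast(x, y).shape),
        depends_on_first_arg=(d != 0.0),
        params={"a": a, "b": b, "c": c, "d": d, "e": e},
    )


def full_rhs(model: DynamicsModel, net: WeightedDigraph, x: Array) -> Array:
    """Time derivative of every node activity of the full system."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite activity at node {bad}")
    coupling = model.g(x[:, None], x[None, :])
    return model.f(x) + np.einsum("ij,ij->i", net.weights, coupling)


def reduced_rhs(
    model: DynamicsModel,
    rsys: ReducedSystem,
    X: Array,
    *,
    with_correction: bool = True,
) -> Array:
    """Time derivative of the observables of the reduced system.

    The correction term is included only when requested *and* the coupling
    function depends on its first argument; otherwise it vanishes
    identically (for models like the neuronal one, where ``g(x, y) = g(y)``,
    the in-degree compatibility equations are not needed at all).
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (rsys.n_groups,):
        raise ValueError(
            f"state has shape {X.shape}, expected ({rsys.n_groups},)"
        )
    if not np.all(np.isfinite(X)):
        bad = int(np.flatnonzero(~np.isfinite(X))[0])
        raise ValueError(f"non-finite observable at group {bad}")
    W = rsys.reduced_adjacency
    G = model.g(X[:, None], X[None, :])
    out = model.f(X) + np.einsum("ij,ij->i", W, G)
    if with_correction and model.depends_on_first_arg:
        G1 = model.g1(X[:, None], X[None, :])
        out = out + X * np.einsum("ij,ij->i", rsys.correction - W, G1)
    return out


@dataclass(frozen=True)
class EquilibriumResult:
    state: Array
    converged: bool
    time: float


def integrate_to_equilibrium(
    rhs: Callable[[Array], Array],
    x0: Array,
    *,
    tol: float = 1e-9,
    t_max: float = 2000.0,
    blowup: float = 1e6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EquilibriumResult:
    """Integrate an autonomous system until the rhs settles.

    Convergence is declared when the infinity norm of the rhs drops below
    ``tol`` (integrator-step independent, unlike a state-difference test).
    If the state norm exceeds ``blowup`` the run is flagged non-converged —
    loss of equilibrium is meaningful information, not an error.  The flow
    is deterministic, so no seeding is involved.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.asarray(x0, dtype=float).copy()
    t = 0.0
    if np.linalg.norm(rhs(x), np.inf) < tol:
        return EquilibriumResult(state=x, converged=True, time=0.0)
    # adaptive chunk length: start short to catch fast transients cheaply
    chunk = 10.0
    fun = lambda _t, y: rhs(y)
    while t < t_max:
        span = min(chunk, t_max - t)
        sol = solve_ivp(fun, (t, t + span), x, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            return EquilibriumResult(state=x, converged=False, time=t)
        x = sol.y[:, -1]
        t = sol.t[-1]
        if not np.all(np.isfinite(x)) or np.linalg.norm(x, np.inf) > blowup:
            return EquilibriumResult(state=x, converged=False, time=t)
        if np.linalg.norm(rhs(x), np.inf) < tol:
            return EquilibriumResult(state=x, converged=True, time=t)
        chunk = min(chunk * 2.0, 200.0)
    return EquilibriumResult(state=x, converged=False, time=t)
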