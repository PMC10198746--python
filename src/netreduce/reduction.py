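"""Reduction vectors, reduced adjacency matrix and correction matrix.

The goal is to replace an ``N``-dimensional dynamical system on a weighted
directed network by an ``n``-dimensional system on *observables*: one
nonnegative, sum-1 weighted average of node activities per group of a node
partition.  Two choices of weights are implemented:

* **homogeneous** — every node of a group contributes equally (``1/m_nu``);
  the baseline coarse-graining.
* **spectral** — the weights approximately solve the *compatibility
  equations*: eigenvector-type conditions, derived from a first-order
  Taylor closure of the dynamics, which require each partial reduction
  vector to be simultaneously a dominant eigenvector of a family of 1-step
  and 2-step group interaction matrices.  Since those equations are
  generically incompatible, the vector is obtained by constrained least
  squares: fix each scalar at the dominant (Perron) eigenvalue of its
  matrix, then minimize the summed quadratic residual over the simplex.

Either choice yields an ``n x n`` reduced adjacency matrix (the
group-to-group in-degrees averaged by the reduction vectors) and, for the
spectral method, a correction matrix of Rayleigh-quotient in-degree
averages that enters the reduced dynamics whenever the coupling function
depends on the receiver's activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
import scipy.linalg

from .graph import (
    BlockDecomposition,
    NodePartition,
    WeightedDigraph,
    block_decompose,
    relabel_by_partition,
    positivize as _positivize,
)

_SUM_TOL = 1e-12


class EigenpairError(RuntimeError):
    """Dominant eigenpair is complex or defective beyond tolerance."""


@dataclass(frozen=True)
class ReductionVectors:
    """Per-group nonnegative weight vectors, each summing to 1."""

    partial_vectors: list[npt.NDArray[np.float64]]
    method: str  # "homogeneous" | "spectral"

    def __post_init__(self) -> None:
        vecs = [np.asarray(v, dtype=float) for v in self.partial_vectors]
        for nu, v in enumerate(vecs):
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"partial vector {nu} must be a nonempty 1-d array")
            if np.any(v < 0):
                raise ValueError(f"partial vector {nu} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"partial vector {nu} does not sum to 1")
        object.__setattr__(self, "partial_vectors", vecs)

    @property
    def n_groups(self) -> int:
        return len(self.partial_vectors)

    def full_vectors(self, part: NodePartition) -> npt.NDArray[np.float64]:
        """The ``n x N`` matrix of full-length reduction vectors.

        Row ``nu`` has support only on the nodes of group ``nu`` (contiguous
        ordering assumed).
        """
        off = part.offsets()
        out = np.zeros((self.n_groups, part.n_nodes))
        for nu, v in enumerate(self.partial_vectors):
            if v.size != part.group_sizes[nu]:
                raise ValueError("vector lengths do not match group sizes")
            out[nu, off[nu]:off[nu + 1]] = v
        return out

    def observe(self, part: NodePartition, x: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        """Project a full state (contiguous node order) onto the observables."""
        off = part.offsets()
        x = np.asarray(x, dtype=float)
        return np.array(
            [v @ x[off[nu]:off[nu + 1]] for nu, v in enumerate(self.partial_vectors)]
        )


@dataclass(frozen=True)
class CompatibilityReport:
    """Residual diagnostics of the decoupled compatibility equations.

    ``lambda_prime[nu, rho]`` is the dominant eigenvalue of the decoupled
    interaction matrix for the pair; ``residual_adjacency[nu, rho]`` the
    Euclidean norm of the eigen-equation residual at the returned vector,
    and ``residual_indegree[nu, rho]`` the corresponding residual of the
    in-degree equation at the correction scalar.
    """

    lambda_prime: npt.NDArray[np.float64]
    residual_adjacency: npt.NDArray[np.float64]
    residual_indegree: npt.NDArray[np.float64]

    def total_adjacency_residual(self) -> float:
        return float(np.sum(self.residual_adjacency**2))

    def total_indegree_residual(self) -> float:
        return float(np.sum(self.residual_indegree**2))


@dataclass(frozen=True)
class ReducedSystem:
    """Everything the reduced dynamics needs.

    ``reduced_adjacency`` is the ``n x n`` effective coupling matrix,
    ``correction`` the matrix of Rayleigh-quotient in-degree averages, and
    ``permutation`` maps contiguous (relabeled) node indices back to the
    original ordering: ``x_contiguous = x_original[permutation]``.
    """

    reduced_adjacency: npt.NDArray[np.float64]
    correction: npt.NDArray[np.float64]
    partition: NodePartition
    vectors: ReductionVectors
    permutation: npt.NDArray[np.intp]
    report: CompatibilityReport | None = None

    @property
    def n_groups(self) -> int:
        return self.partition.n_groups

    def observe(self, x_original: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        """Observables of a full state given in *original* node order."""
        x = np.asarray(x_original, dtype=float)[self.permutation]
        return self.vectors.observe(self.partition, x)

    def scaled(self, sigma: float) -> "ReducedSystem":
        """Reduced system after uniformly scaling all weights by ``sigma``.

        Both the reduced adjacency and the correction matrix are linear in
        the weights, and the reduction vectors are scale-invariant.
        """
        return ReducedSystem(
            reduced_adjacency=self.reduced_adjacency * sigma,
            correction=self.correction * sigma,
            partition=self.partition,
            vectors=self.vectors,
            permutation=self.permutation,
            report=self.report,
        )


def homogeneous_vectors(part: NodePartition) -> ReductionVectors:
    """Uniform weights ``1/m_nu`` within each group."""
    return ReductionVectors(
        partial_vectors=[np.full(m, 1.0 / m) for m in part.group_sizes],
        method="homogeneous",
    )


def decoupled_matrices(blocks: BlockDecomposition, nu: int) -> list[npt.NDArray[np.float64]]:
    """The 1-step and 2-step interaction matrices constraining group ``nu``.

    For ``rho == nu`` this is the transposed diagonal block (direct
    interactions within the group); for ``rho != nu`` the product
    ``W[rho,nu]^T W[nu,rho]^T``, whose entries accumulate the weights of all
    2-step paths between nodes of group ``nu`` through group ``rho``.  The
    partial reduction vector of group ``nu`` must (ideally) be a common
    dominant eigenvector of all of them.
    """
    n = blocks.n_groups
    out = []
    for rho in range(n):
        if rho == nu:
            out.append(blocks.blocks[nu][nu].T.copy())
        else:
            out.append(blocks.blocks[rho][nu].T @ blocks.blocks[nu][rho].T)
    return out


def dominant_eigenvalue(mat: npt.NDArray[np.float64], *, imag_tol: float = 1e-8) -> float:
    """Largest-real-part eigenvalue, required to be essentially real.

    For entrywise-positive matrices this is the Perron root.  Ties between
    equal-modulus eigenvalues are broken in favour of the real positive one.
    """
    eigvals = scipy.linalg.eigvals(mat)
    # prefer the real positive root among (near-)maximal-modulus eigenvalues
    mod = np.abs(eigvals)
    near_max = eigvals[mod >= mod.max() * (1 - 1e-12)]
    real_pos = near_max[np.abs(near_max.imag) <= imag_tol * max(mod.max(), 1.0)]
    if real_pos.size:
        lam = real_pos[np.argmax(real_pos.real)]
    else:
        lam = near_max[np.argmax(near_max.real)]
    if abs(lam.imag) > imag_tol * max(abs(lam), 1.0):
        raise EigenpairError(
            f"dominant eigenvalue {lam} has a non-negligible imaginary part"
        )
    return float(lam.real)


def _solve_simplex_quadratic(
    M: npt.NDArray[np.float64], *, tol_neg_rel: float = 1e-6, max_iter: int = 200
) -> npt.NDArray[np.float64]:
    """Minimize ``a^T M a`` subject to ``sum(a) = 1`` (and ``a >= 0``).

    The equality-constrained problem is solved in closed form through its
    KKT linear system.  If the solution has negative entries beyond a small
    tolerance (numerical artifacts aside, Perron–Frobenius structure makes
    the unconstrained solution positive in the exactly-solvable case), an
    active-set iteration re-solves with nonnegativity enforced, which is
    optimal over the simplex since ``M`` is PSD.
    """
    m = M.shape[0]
    if m == 1:
        return np.ones(1)

    def kkt_solve(free: npt.NDArray[np.bool_]) -> npt.NDArray[np.float64]:
        k = int(free.sum())
        sys = np.zeros((k + 1, k + 1))
        sys[:k, :k] = 2.0 * M[np.ix_(free, free)]
        sys[:k, k] = 1.0
        sys[k, :k] = 1.0
        rhs = np.zeros(k + 1)
        rhs[k] = 1.0
        try:
            sol = np.linalg.solve(sys, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sys, rhs, rcond=None)[0]
        a = np.zeros(m)
        a[free] = sol[:k]
        return a

    a = kkt_solve(np.ones(m, dtype=bool))
    scale = max(float(np.abs(a).max()), 1.0)
    if a.min() >= -tol_neg_rel * scale:
        a = np.clip(a, 0.0, None)
        return a / a.sum()

    # active-set iteration on the simplex
    free = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        a = kkt_solve(free)
        neg = free & (a < -1e-12)
        if np.any(neg):
            # fix the most negative coordinate at zero
            idx = np.argmin(np.where(free, a, np.inf))
            free[idx] = False
            if free.sum() == 0:  # pragma: no cover - cannot happen for PSD M
                free[np.argmin(M.diagonal())] = True
            continue
        # check Lagrange multipliers of the fixed (zero) coordinates
        a = np.clip(a, 0.0, None)
        grad = 2.0 * M @ a
        kappa = float(grad[free].mean()) if free.any() else 0.0
        fixed = ~free
        viol = fixed & (grad - kappa < -1e-10 * max(np.abs(grad).max(), 1.0))
        if np.any(viol):
            free[np.argmin(np.where(viol, grad - kappa, np.inf))] = True
            continue
        break
    a = np.clip(a, 0.0, None)
    s = a.sum()
    if s <= 0:  # pragma: no cover - defensive
        raise RuntimeError("active-set solver collapsed to the zero vector")
    return a / s


def spectral_vectors(
    net: WeightedDigraph,
    part: NodePartition,
    *,
    tol_neg_rel: float = 1e-6,
    imag_tol: float = 1e-8,
) -> tuple[ReductionVectors, CompatibilityReport]:
    """Solve the decoupled compatibility equations in the least-squares sense.

    For each group ``nu`` independently: (1) the scalar of every decoupled
    eigen-equation is fixed at the dominant eigenvalue of its matrix, as
    would hold if the equations were exactly solvable; (2) the partial
    reduction vector minimizing the summed quadratic eigen-residual subject
    to sum 1 (and nonnegativity) is computed; (3) residuals are reported.

    The network must be strictly positive — apply
    :func:`netreduce.graph.positivize` first for matrices with zeros.
    """
    if not net.is_positive():
        raise ValueError(
            "spectral reduction requires a strictly positive matrix; "
            "call positivize() first"
        )
    blocks = block_decompose(net, part)
    n = part.n_groups
    lam = np.zeros((n, n))
    vecs: list[np.ndarray] = []
    for nu in range(n):
        mats = decoupled_matrices(blocks, nu)
        for rho, A in enumerate(mats):
            try:
                lam[nu, rho] = dominant_eigenvalue(A, imag_tol=imag_tol)
            except EigenpairError as exc:
                raise EigenpairError(
                    f"group pair ({nu}, {rho}): {exc}"
                ) from exc
        m = mats[0].shape[0]
        M = np.zeros((m, m))
        for rho, A in enumerate(mats):
            C = A - lam[nu, rho] * np.eye(m)
            M += C.T @ C
        vecs.append(_solve_simplex_quadratic(M, tol_neg_rel=tol_neg_rel))
    vectors = ReductionVectors(partial_vectors=vecs, method="spectral")
    mu = correction_matrix(blocks, vectors)
    report = compatibility_residuals(blocks, vectors, lam, mu)
    return vectors, report


def reduced_adjacency(
    blocks: BlockDecomposition, vectors: ReductionVectors
) -> npt.NDArray[np.float64]:
    """Group-to-group in-degrees averaged by the reduction vectors.

    Entry ``(nu, rho)`` is ``sum_i a_nu[i] * k_i(rho)`` over nodes ``i`` of
    group ``nu``, where ``k_i(rho)`` is the weighted in-degree of ``i``
    restricted to senders in group ``rho``; equivalently
    ``a_nu^T W[nu,rho] 1``.
    """
    n = blocks.n_groups
    out = np.zeros((n, n))
    for nu in range(n):
        v = vectors.partial_vectors[nu]
        for rho in range(n):
            k = blocks.indegree[nu][rho]
            if v.size != k.size:
                raise ValueError("vector lengths do not match group sizes")
            out[nu, rho] = v @ k
    return out


def correction_matrix(
    blocks: BlockDecomposition, vectors: ReductionVectors
) -> npt.NDArray[np.float64]:
    """Rayleigh-quotient in-degree averages.

    Entry ``(nu, rho)`` is ``a^T K a / ||a||^2`` with ``K`` the diagonal
    group-to-group in-degree matrix — the scalar minimizing the quadratic
    residual of the in-degree compatibility equation at the given vector.
    It always lies between the smallest and largest diagonal entry of ``K``.
    """
    n = blocks.n_groups
    out = np.zeros((n, n))
    for nu in range(n):
        v = vectors.partial_vectors[nu]
        nrm2 = float(v @ v)
        for rho in range(n):
            k = blocks.indegree[nu][rho]
            if v.size != k.size:
                raise ValueError("vector lengths do not match group sizes")
            out[nu, rho] = (v * k) @ v / nrm2
    return out


def compatibility_residuals(
    blocks: BlockDecomposition,
    vectors: ReductionVectors,
    lambda_prime: npt.NDArray[np.float64],
    mu: npt.NDArray[np.float64] | None = None,
) -> CompatibilityReport:
    """Residual norms of both families of decoupled compatibility equations.

    ``mu`` defaults to the Rayleigh-quotient correction matrix at the given
    vectors (its residual-minimizing value).
    """
    if mu is None:
        mu = correction_matrix(blocks, vectors)
    n = blocks.n_groups
    res_adj = np.zeros((n, n))
    res_deg = np.zeros((n, n))
    for nu in range(n):
        v = vectors.partial_vectors[nu]
        mats = decoupled_matrices(blocks, nu)
        for rho in range(n):
            res_adj[nu, rho] = np.linalg.norm(mats[rho] @ v - lambda_prime[nu, rho] * v)
            k = blocks.indegree[nu][rho]
            res_deg[nu, rho] = np.linalg.norm((k - mu[nu, rho]) * v)
    return CompatibilityReport(
        lambda_prime=np.asarray(lambda_prime, dtype=float),
        residual_adjacency=res_adj,
        residual_indegree=res_deg,
    )


def reduce_network(
    net: WeightedDigraph,
    part: NodePartition,
    method: str = "spectral",
    *,
    epsilon: float | None = None,
    tol_neg_rel: float = 1e-6,
) -> ReducedSystem:
    """End-to-end reduction: relabel, (positivize,) solve, assemble.

    The partition need not be contiguous; nodes are relabeled internally and
    the permutation is stored on the returned :class:`ReducedSystem` so that
    full states in original node order can be projected with ``observe``.
    For the spectral method the matrix is positivized (zeros replaced by a
    weak ``epsilon``) before solving the compatibility equations.
    """
    cnet, cpart, perm = relabel_by_partition(net, part)
    if method == "homogeneous":
        vectors = homogeneous_vectors(cpart)
        blocks = block_decompose(cnet, cpart)
        report = None
    elif method == "spectral":
        pnet = cnet if cnet.is_positive() else _positivize(cnet, epsilon)
        vectors, report = spectral_vectors(pnet, cpart, tol_neg_rel=tol_neg_rel)
        blocks = block_decompose(pnet, cpart)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    W = reduced_adjacency(blocks, vectors)
    mu = correction_matrix(blocks, vectors)
    return ReducedSystem(
        reduced_adjacency=W,
        correction=mu,
        partition=cpart,
        vectors=vectors,
        permutation=perm,
        report=report,
    )
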