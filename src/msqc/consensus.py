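"""Consensus of the per-feature assessments by constrained quadratic optimization.

Given the bipartite graph (A, Y) from :mod:`msqc.ensemble`, the consensus
problem estimates a row-stochastic n x k matrix U (u_iz = probability that
spectrum i is in class z) and v x k matrix Q (q_jz = probability that group
j represents class z) minimizing

    J(U, Q) = sum_z sum_ij a_ij (u_iz - q_jz)^2 + alpha * sum_z sum_j (q_jz - y_jz)^2

subject to each row of U and Q lying on the probability simplex. The first
term asks each spectrum to agree with the groups that contain it (and vice
versa); the second anchors the groups to their initial labels Y with
confidence alpha. J = 0 exactly when all m per-feature assessments agree on
every spectrum.

The objective is quadratic in U for fixed Q and in Q for fixed U, so it is
solved by alternating exact minimizations from Q = Y:

    u_iz <- (1/m) * sum_j a_ij q_jz          (mean over the spectrum's groups)
    q_jz <- (sum_i a_ij u_iz + alpha y_jz) / (alpha + sum_i a_ij)

Starting from any Y with one-hot rows, every iterate is automatically
row-stochastic (no projection needed) and the cost is non-increasing, which
guarantees convergence; both properties are asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleGraph


@dataclass(frozen=True)
class ConsensusParams:
    """Solver settings.

    alpha
        Confidence in the initial group labels, > 0. Large alpha pins Q to Y
        so U becomes the per-spectrum average of its feature votes; small
        alpha lets the spectra reshape the group probabilities. Default 90.
    epsilon
        Stopping tolerance on the Frobenius norm of U^t - U^{t-1}.
    max_iter
        Iteration cap; hitting it flags the result as non-converged rather
        than raising.
    """

    alpha: float = 90.0
    epsilon: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ConsensusResult:
    """Solver output: probabilities, cost trajectory and convergence state."""

    U: np.ndarray
    Q: np.ndarray
    costs: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def p_high(self) -> np.ndarray:
        """Per-spectrum probability of being high quality (class 1)."""
        return self.U[:, 0]


@dataclass(frozen=True)
class QualityCall:
    """Thresholded decision for one spectrum, with its probability."""

    id: str
    p_high: float
    call: str  # "high" | "poor"


def cost(graph: EnsembleGraph, U: np.ndarray, Q: np.ndarray, alpha: float) -> float:
    """The quadratic disagreement cost J(U, Q)."""
    U = np.asarray(U, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if U.shape != (graph.n, graph.k) or Q.shape != (graph.v, graph.k):
        raise ValueError("U/Q shapes do not match the graph")
    A = graph.A
    # sum_ij a_ij ||u_i - q_j||^2 expanded to avoid the n x v x k intermediate
    row = A.sum(axis=1, dtype=float)
    col = A.sum(axis=0, dtype=float)
    agree = (row @ (U ** 2).sum(axis=1)
             + col @ (Q ** 2).sum(axis=1)
             - 2.0 * np.sum((A @ Q) * U))
    anchor = float(((Q - graph.Y) ** 2).sum())
    return float(agree + alpha * anchor)


def update_U(graph: EnsembleGraph, Q: np.ndarray) -> np.ndarray:
    """Exact minimizer in U: average of q_j over the m groups holding each spectrum."""
    row = graph.A.sum(axis=1, dtype=float)
    if (row == 0).any():
        raise ValueError("a spectrum belongs to no group (zero row in A)")
    return (graph.A @ np.asarray(Q, dtype=float)) / row[:, None]


def update_Q(graph: EnsembleGraph, U: np.ndarray, alpha: float) -> np.ndarray:
    """Exact minimizer in Q: label-anchored average of member spectra.

    Empty groups fall back to their initial label exactly (q_j = y_j).
    """
    col = graph.A.sum(axis=0, dtype=float)
    num = graph.A.T @ np.asarray(U, dtype=float) + alpha * graph.Y
    return num / (alpha + col)[:, None]


def _assert_row_stochastic(M: np.ndarray, name: str) -> None:
    if (M < -1e-12).any() or (M > 1 + 1e-12).any():
        raise AssertionError(f"{name} has entries outside [0, 1]")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise AssertionError(f"rows of {name} do not sum to 1")


def solve(graph: EnsembleGraph, params: ConsensusParams = ConsensusParams()) -> ConsensusResult:
    """Alternating minimization from Q = Y with invariant checking.

    Every iterate is verified row-stochastic and the cost trajectory
    non-increasing (up to round-off); violations raise, as they would
    indicate a broken graph rather than a numerical issue.
    """
    graph.validate()
    Y = graph.Y.astype(float)
    Q = Y.copy()
    U_prev: np.ndarray | None = None
    costs: list[float] = []
    converged = False
    iterations = 0
    for t in range(1, params.max_iter + 1):
        U = update_U(graph, Q)
        Q = update_Q(graph, U, params.alpha)
        _assert_row_stochastic(U, "U")
        _assert_row_stochastic(Q, "Q")
        J = cost(graph, U, Q, params.alpha)
        if costs and J > costs[-1] + 1e-8 * max(1.0, abs(costs[-1])):
            raise AssertionError("cost increased between iterations")
        costs.append(J)
        iterations = t
        if U_prev is not None and np.linalg.norm(U - U_prev) <= params.epsilon:
            converged = True
            U_prev = U
            break
        U_prev = U
    return ConsensusResult(U=U_prev, Q=Q, costs=costs,
                           iterations=iterations, converged=converged)


def classify(result: ConsensusResult, ids, threshold: float = 0.5) -> list[QualityCall]:
    """Binary high/poor calls: high iff p_high >= threshold."""
    ids = list(ids)
    if len(ids) != result.U.shape[0]:
        raise ValueError("number of ids does not match U")
    return [
        QualityCall(id=sid, p_high=float(p), call="high" if p >= threshold else "poor")
        for sid, p in zip(ids, result.p_high)
    ]
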