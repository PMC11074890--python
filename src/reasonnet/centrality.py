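"""Eigenvector centrality of co-mention matrices via power iteration.

The importance of a reason in the co-mention network is scored by the
leading eigenvector X of the symmetric nonnegative adjacency matrix A
(A X = lambda X): a reason is important both when it is mentioned often and
when it is co-mentioned with other important reasons.  For nonnegative A and
a strictly positive start vector, the Perron–Frobenius theorem guarantees a
nonnegative leading eigenvector, so centrality scores are comparable across
networks once renormalized to a fixed norm.

Power iteration from the uniform positive vector runs for at most
``max_iter`` (default 500) steps or until the L1 change between successive
iterates drops below ``tol``; the eigenvalue is estimated by the Rayleigh
quotient at termination.  The iteration applies a small spectral shift,
multiplying by A + cI (c proportional to the largest row sum) instead of A:
the eigenvectors are unchanged, but the Perron eigenvalue becomes strictly
dominant in magnitude, so the iteration converges even on bipartite-like
networks where lambda_min = -lambda_max (e.g. a star graph) would otherwise
make the iterates oscillate indefinitely.  The reported eigenvalue is the
Rayleigh quotient of the *unshifted* matrix.  A small deflated iteration
estimates the second eigenvalue to flag near-degenerate spectral gaps,
where power iteration is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import CoMentionMatrix

__all__ = [
    "CentralityResult",
    "power_iteration",
    "normalized_eigencentrality",
    "rank_reasons",
]

NORMS = ("l2", "max")


@dataclass(frozen=True)
class CentralityResult:
    """Leading eigenvector of a co-mention matrix with convergence diagnostics.

    ``X`` is entrywise nonnegative and renormalized per ``norm``
    (unit Euclidean length for ``"l2"``, maximum entry 1 for ``"max"``),
    unless the matrix is all zero, in which case X is the zero vector and
    ``converged`` is false.  ``gap_degenerate`` flags a spectral gap
    lambda1 - lambda2 <= 1e-3 * lambda1, where the iteration may not have
    isolated a unique leading direction.
    """

    reasons: tuple
    X: np.ndarray
    lam: float
    n_iterations: int
    converged: bool
    norm: str = "l2"
    gap_degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.X, index=list(self.reasons), name="centrality")


def _estimate_second_eigenvalue(A: np.ndarray, v1: np.ndarray, lam1: float, n_iter: int = 100) -> float:
    """Power iteration on the deflated matrix A - lam1 v1 v1^T (diagnostic only)."""
    k = A.shape[0]
    if k < 2 or lam1 == 0:
        return 0.0
    rng = np.random.default_rng(0)
    x = rng.standard_normal(k)
    x -= (x @ v1) * v1
    nx_ = np.linalg.norm(x)
    if nx_ == 0:
        return 0.0
    x /= nx_
    ny = 0.0
    for _ in range(n_iter):
        y = A @ x - lam1 * (v1 @ x) * v1
        ny = np.linalg.norm(y)
        if ny == 0:
            return 0.0
        x = y / ny
    # |lam2| estimate: the product norm is robust when the subdominant
    # eigenvalues come in +/- pairs and the iterate oscillates in sign
    return float(ny)


def power_iteration(
    M,
    max_iter: int = 500,
    tol: float = 1e-10,
    norm: str = "l2",
) -> CentralityResult:
    """Leading-eigenvector centrality by power iteration.

    Parameters
    ----------
    M
        A :class:`~reasonnet.network.CoMentionMatrix`, or a square symmetric
        nonnegative array (reason labels default to string indices).
    max_iter
        Iteration cap (>= 1).
    tol
        Convergence threshold on the L1 change between successive
        L2-normalized iterates.
    norm
        Output normalization: ``"l2"`` (unit Euclidean norm) or ``"max"``
        (largest entry 1).

    Returns
    -------
    CentralityResult
        With nonnegative X, the Rayleigh-quotient eigenvalue estimate, the
        iteration count and convergence/degeneracy flags.  An all-zero
        matrix yields the zero vector with ``converged=False`` and a warning.
    """
    if isinstance(M, CoMentionMatrix):
        A = M.A
        reasons = M.reasons
    else:
        A = np.asarray(M, dtype=float)
        reasons = tuple(str(i) for i in range(A.shape[0]))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency matrix must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency matrix must be nonnegative")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if norm not in NORMS:
        raise ValueError(f"norm must be one of {NORMS}")

    k = A.shape[0]
    if not A.any():
        warnings.warn("all-zero adjacency matrix; centrality undefined", stacklevel=2)
        return CentralityResult(
            reasons=reasons, X=np.zeros(k), lam=0.0, n_iterations=0,
            converged=False, norm=norm,
        )

    # Shift keeps eigenvectors, guarantees |lam1 + c| > |lam_i + c| for the
    # Perron eigenvalue (|lam_i| <= lam1 for symmetric nonnegative A); scaled
    # to the matrix so centrality(cA) == centrality(A) still holds.
    shift = 0.1 * float(A.sum(axis=1).max())
    A_shifted = A + shift * np.eye(k)

    x = np.full(k, 1.0 / np.sqrt(k))
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        y = A_shifted @ x
        ny = np.linalg.norm(y)
        if ny == 0:
            # uniform start landed in the null space (possible only for
            # structured zero patterns); restart from a perturbed vector
            x = np.abs(x + np.linspace(0.0, 1.0, k)) + 1e-12
            x /= np.linalg.norm(x)
            continue
        x_new = y / ny
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    lam = float(x @ A @ x)
    # Perron vector of a nonnegative matrix reached from a positive start is
    # nonnegative; clip the roundoff negatives.
    x = np.clip(x, 0.0, None)
    lam2 = _estimate_second_eigenvalue(A, x / (np.linalg.norm(x) or 1.0), lam)
    gap_degenerate = bool(lam > 0 and (lam - lam2) <= 1e-3 * lam)
    if norm == "l2":
        nrm = np.linalg.norm(x)
    else:
        nrm = x.max()
    if nrm > 0:
        x = x / nrm
    return CentralityResult(
        reasons=reasons, X=x, lam=lam, n_iterations=n_it,
        converged=converged, norm=norm, gap_degenerate=gap_degenerate,
    )


def normalized_eigencentrality(M, norm: str = "l2") -> CentralityResult:
    """Default-settings wrapper: 500 iterations max, tol 1e-10, L2 norm."""
    return power_iteration(M, max_iter=500, tol=1e-10, norm=norm)


def rank_reasons(result: CentralityResult) -> pd.DataFrame:
    """Rank reasons by descending centrality.

    Ties (including the degenerate all-zero vector) break by canonical
    codebook position, so rankings are deterministic.  The ``degenerate``
    column flags an all-zero centrality vector.
    """
    order = sorted(
        range(len(result.reasons)),
        key=lambda i: (-result.X[i], i),
    )
    degenerate = not result.X.any()
    return pd.DataFrame(
        {
            "reason": [result.reasons[i] for i in order],
            "centrality": [float(result.X[i]) for i in order],
            "rank": list(range(1, len(order) + 1)),
            "degenerate": degenerate,
        }
    )
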