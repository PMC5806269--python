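"""Network normalization and single-network label propagation.

Label propagation scores every node against a set of labelled seeds by
balancing smoothness along edges against fidelity to the initial labels.
On a network with weight matrix W and diagonal degree matrix D, the
propagation operator is the symmetric normalization

    S̄ = D^{-1/2} W D^{-1/2},

whose spectral radius is at most 1 when all degrees are positive.  Two
equivalent solvers are provided: the fixed-point iteration

    Y_t = α S Y_{t-1} + (1 - α) Ŷ

and its closed-form limit Y* = (1-α)(I - αS)^{-1} Ŷ, computed by LU
factorization (Gaussian elimination), never by forming an explicit inverse.
The restart weight α ∈ (0,1) trades network smoothing (α→1) against label
fidelity (α→0); the fidelity weight is always β = 1-α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse import linalg as spla

from .netio import (
    AssociationMatrix,
    IndexedNetwork,
    NumericalError,
    ScoreMatrix,
    ValidationError,
)

__all__ = [
    "NormalizedNetwork",
    "normalize",
    "propagate_closed_form",
    "propagate_iterative",
    "ConvergenceRecord",
    "solve_lp_system",
]

# Matrices below this dimension are solved densely; larger symmetric systems
# go through sparse LU when the operator is sparse.
_DENSE_SOLVE_LIMIT = 2000


@dataclass
class NormalizedNetwork:
    """Degree-normalized network S̄ = D^{-1/2} W D^{-1/2} with provenance."""

    node_ids: list[str]
    matrix: np.ndarray
    provenance: IndexedNetwork | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ConvergenceRecord:
    """Outcome of an iterative propagation run."""

    n_iter: int
    converged: bool
    final_delta: float


def normalize(net: IndexedNetwork) -> NormalizedNetwork:
    """Symmetric degree normalization of a network.

    Every node must have strictly positive (weighted) degree; run
    :func:`idlp.netio.align_universe` first to guarantee this.
    """
    deg = net.degrees()
    if (deg <= 0).any():
        bad = [nid for nid, d in zip(net.node_ids, deg) if d <= 0]
        raise ValidationError(
            f"zero-degree node(s) cannot be normalized: {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = net.weights * inv_sqrt[:, None] * inv_sqrt[None, :]
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    return NormalizedNetwork(list(net.node_ids), S, provenance=net)


def solve_lp_system(S: np.ndarray, B: np.ndarray, alpha: float) -> np.ndarray:
    """Solve (I - alpha*S) X = B by elimination (LU), dense or sparse.

    Raises :class:`NumericalError` when the system is singular or the
    solution is not finite (numerically singular).
    """
    n = S.shape[0]
    A_dense = None
    try:
        if sparse.issparse(S) and n >= _DENSE_SOLVE_LIMIT:
            A = sparse.identity(n, format="csc") - alpha * S.tocsc()
            X = spla.splu(A).solve(np.asarray(B))
        else:
            if sparse.issparse(S):
                S = S.toarray()
            A_dense = np.eye(n) - alpha * S
            X = sla.solve(A_dense, B, assume_a="sym")
    except (np.linalg.LinAlgError, RuntimeError, sla.LinAlgError) as exc:
        raise NumericalError(
            f"(I - alpha*S) is singular (alpha={alpha}); try a smaller alpha "
            "or a smaller network-learning rate gamma"
        ) from exc
    if not np.isfinite(X).all():
        raise NumericalError(
            f"(I - alpha*S) is numerically singular (alpha={alpha}); try a "
            "smaller alpha or a smaller network-learning rate gamma"
        )
    return X


def _as_matrix(S: "NormalizedNetwork | np.ndarray") -> np.ndarray:
    return S.matrix if isinstance(S, NormalizedNetwork) else np.asarray(S, dtype=float)


def propagate_closed_form(
    S: "NormalizedNetwork | np.ndarray",
    assoc: AssociationMatrix,
    alpha: float,
    side: str = "gene",
) -> ScoreMatrix:
    """Closed-form label propagation limit on one side of the network pair.

    ``side='gene'`` solves Y = (1-α)(I - αS)^{-1} Ŷ over an n×n gene
    network; ``side='phenotype'`` solves the transposed system
    Y = (1-α) Ŷ (I - αS)^{-1} over an m×m phenotype network.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie strictly between 0 and 1")
    M = _as_matrix(S)
    Yhat = assoc.values
    beta = 1.0 - alpha
    if side == "gene":
        if M.shape[0] != Yhat.shape[0]:
            raise ValidationError("gene-side operator does not match associations")
        Y = solve_lp_system(M, beta * Yhat, alpha)
    elif side == "phenotype":
        if M.shape[0] != Yhat.shape[1]:
            raise ValidationError(
                "phenotype-side operator does not match associations"
            )
        # Ŷ (I-αS)^{-1} == ((I-αSᵀ)^{-1} Ŷᵀ)ᵀ ; S is symmetric but we
        # transpose anyway so the identity holds for any learned matrix.
        Y = solve_lp_system(M.T, beta * Yhat.T, alpha).T
    else:
        raise ValidationError(f"side must be 'gene' or 'phenotype', got {side!r}")
    return ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), Y)


def propagate_iterative(
    S: "NormalizedNetwork | np.ndarray",
    assoc: AssociationMatrix,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    side: str = "gene",
) -> tuple[ScoreMatrix, ConvergenceRecord]:
    """Fixed-point iteration Y_t = αSY_{t-1} + (1-α)Ŷ (or the right-side analogue).

    Stops when the max-abs change between iterates falls below ``tol`` or
    after ``max_iter`` steps.  Divergence (growing change norm for five
    consecutive steps) raises :class:`NumericalError`.
    """
    if not 0 <= alpha < 1:
        raise ValidationError("alpha must lie in [0, 1)")
    M = _as_matrix(S)
    Yhat = assoc.values
    beta = 1.0 - alpha
    Y = Yhat.copy()
    prev_delta = np.inf
    growth_streak = 0
    n_iter = 0
    converged = False
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        if side == "gene":
            Y_new = alpha * (M @ Y) + beta * Yhat
        elif side == "phenotype":
            Y_new = alpha * (Y @ M) + beta * Yhat
        else:
            raise ValidationError(f"side must be 'gene' or 'phenotype', got {side!r}")
        delta = float(np.max(np.abs(Y_new - Y))) if Y.size else 0.0
        Y = Y_new
        if delta < tol:
            converged = True
            break
        growth_streak = growth_streak + 1 if delta > prev_delta else 0
        if growth_streak >= 5:
            raise NumericalError(
                "propagation iterates are diverging (alpha * spectral radius "
                ">= 1?); use a smaller alpha"
            )
        prev_delta = delta
    scores = ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), Y)
    return scores, ConvergenceRecord(n_iter=n_iter, converged=converged, final_delta=delta)
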