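"""Improved dual label propagation (IDLP): alternating closed-form updates.

IDLP scores gene–phenotype associations Y on a heterogeneous network built
from a (noisy, sparse, binary) gene interaction network and a (dense)
phenotype similarity network, while *learning* denoised copies S1, S2 of the
two normalized networks.  The loss couples four ingredients:

    L(Y, S1, S2) = tr(Yᵀ(I - S1)Y) + tr(Y(I - S2)Yᵀ)
                   + (μ + ζ)‖Y - Ŷ‖²_F
                   + ν‖S1 - S̄1‖²_F + η‖S2 - S̄2‖²_F,

with μ, ζ, ν, η > 0: Laplacian smoothness on both networks, fidelity of Y to
the known binary associations Ŷ, and Frobenius penalties tying the learned
networks to their observed normalizations.  L is not jointly convex, but it
is convex in each block with the others fixed, so the solver performs block
coordinate descent where every block has a closed-form minimizer:

    S1 ← S̄1 + γ Y Yᵀ            (γ  = 1/(2ν))
    Y  ← β (I - α S1)^{-1} Ŷ     (α  = 1/(1+μ),  β  = 1-α)
    S2 ← S̄2 + γ' Yᵀ Y           (γ' = 1/(2η))
    Y  ← β' Ŷ (I - α' S2)^{-1}   (α' = 1/(1+ζ), β' = 1-α')

Users parameterize the model by (α, α', γ, γ'); the Lagrange-style weights
μ, ζ, ν, η are recovered internally.  γ = 0 (resp. γ' = 0) is read as the
ν→∞ limit: the corresponding network is pinned to its observed normalization
and not learned.  With both pinned the per-side Y updates reduce exactly to
the bi-random-walk closed forms (see :mod:`idlp.baselines`).

Linear systems are solved by LU elimination; explicit inverses are never
formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .netio import (
    AssociationMatrix,
    IndexedNetwork,
    NumericalError,
    ScoreMatrix,
    ValidationError,
)
from .propagation import NormalizedNetwork, normalize, solve_lp_system

logger = logging.getLogger(__name__)

__all__ = [
    "IDLPParams",
    "LearnedNetworks",
    "FitTrace",
    "IDLPFit",
    "update_gene_network",
    "update_scores_gene_side",
    "update_phenotype_network",
    "update_scores_phenotype_side",
    "objective_value",
    "psi_gene",
    "psi_phenotype",
    "fit_idlp",
]

_VARIANTS = ("idlp", "idlp-g", "idlp-p", "birw")


@dataclass
class IDLPParams:
    """Hyperparameters of the IDLP solver.

    Parameters
    ----------
    alpha, alpha2:
        Propagation weights in (0, 1) for the gene and phenotype side;
        the fidelity weights are tied as β = 1-α, β' = 1-α'.
    gamma, gamma2:
        Non-negative network-learning rates.  0 pins the corresponding
        network to its observed normalization (the network is not learned).
    max_outer_iter, tol:
        Outer-loop controls; the loop stops when the relative Frobenius
        change of Y drops below ``tol``.
    variant:
        'idlp' learns both networks, 'idlp-g' learns only the gene network
        (S2 pinned), 'idlp-p' learns only the phenotype network (S1 pinned),
        'birw' learns neither (the bi-random-walk special case).
    block_order:
        Which network/score block pair is updated first; the method
        converges under either order.
    """

    alpha: float = 0.1
    alpha2: float = 0.1
    gamma: float = 1000.0
    gamma2: float = 1000.0
    max_outer_iter: int = 20
    tol: float = 1e-6
    variant: str = "idlp"
    block_order: tuple[str, str] = ("gene", "phenotype")
    check_spectral_radius: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie strictly between 0 and 1")
        if not 0 < self.alpha2 < 1:
            raise ValidationError("alpha2 must lie strictly between 0 and 1")
        if self.gamma < 0 or self.gamma2 < 0:
            raise ValidationError("gamma and gamma2 must be non-negative")
        if self.max_outer_iter < 1:
            raise ValidationError("max_outer_iter must be a positive integer")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.variant not in _VARIANTS:
            raise ValidationError(f"variant must be one of {_VARIANTS}")
        if tuple(self.block_order) not in (("gene", "phenotype"), ("phenotype", "gene")):
            raise ValidationError(
                "block_order must be ('gene','phenotype') or ('phenotype','gene')"
            )

    @property
    def effective_gamma(self) -> float:
        """Gene-network learning rate after applying the variant."""
        return 0.0 if self.variant in ("idlp-p", "birw") else self.gamma

    @property
    def effective_gamma2(self) -> float:
        """Phenotype-network learning rate after applying the variant."""
        return 0.0 if self.variant in ("idlp-g", "birw") else self.gamma2

    @property
    def mu(self) -> float:
        return (1.0 - self.alpha) / self.alpha

    @property
    def zeta(self) -> float:
        return (1.0 - self.alpha2) / self.alpha2

    @property
    def nu(self) -> float:
        """Gene-network deviation weight; inf when the network is pinned."""
        g = self.effective_gamma
        return np.inf if g == 0 else 1.0 / (2.0 * g)

    @property
    def eta(self) -> float:
        g = self.effective_gamma2
        return np.inf if g == 0 else 1.0 / (2.0 * g)


@dataclass
class LearnedNetworks:
    """The learned (denoised) network matrices after a fit."""

    S1: np.ndarray
    S2: np.ndarray


@dataclass
class FitTrace:
    """Per-outer-iteration diagnostics of an IDLP fit."""

    iterations: list[int] = field(default_factory=list)
    psi1: list[float] = field(default_factory=list)
    psi2: list[float] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    rel_change: list[float] = field(default_factory=list)
    converged: bool = False

    def append(self, it: int, p1: float, p2: float, obj: float, rel: float) -> None:
        self.iterations.append(it)
        self.psi1.append(p1)
        self.psi2.append(p2)
        self.objective.append(obj)
        self.rel_change.append(rel)

    def __len__(self) -> int:
        return len(self.iterations)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "psi1": self.psi1,
                "psi2": self.psi2,
                "objective": self.objective,
                "rel_change": self.rel_change,
            }
        )


class IDLPFit(NamedTuple):
    scores: ScoreMatrix
    networks: LearnedNetworks
    trace: FitTrace


# ---------------------------------------------------------------------------
# Block updates (each is the exact minimizer of its convex sub-problem)
# ---------------------------------------------------------------------------


def _matrix_of(S) -> np.ndarray:
    return S.matrix if isinstance(S, NormalizedNetwork) else np.asarray(S, dtype=float)


def update_gene_network(S1_bar, Y, gamma: float) -> np.ndarray:
    """Closed-form gene-network update S1 = S̄1 + γ Y Yᵀ (exactly symmetric)."""
    Yv = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    if not np.isfinite(Yv).all():
        raise NumericalError("score matrix contains non-finite entries")
    base = _matrix_of(S1_bar)
    if gamma == 0:
        return base.copy()
    G = gamma * (Yv @ Yv.T)
    return base + (G + G.T) / 2.0


def update_phenotype_network(S2_bar, Y, gamma2: float) -> np.ndarray:
    """Closed-form phenotype-network update S2 = S̄2 + γ' Yᵀ Y."""
    Yv = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    if not np.isfinite(Yv).all():
        raise NumericalError("score matrix contains non-finite entries")
    base = _matrix_of(S2_bar)
    if gamma2 == 0:
        return base.copy()
    G = gamma2 * (Yv.T @ Yv)
    return base + (G + G.T) / 2.0


def update_scores_gene_side(S1, assoc: AssociationMatrix, alpha: float) -> ScoreMatrix:
    """Closed-form score update Y = (1-α)(I - α S1)^{-1} Ŷ."""
    M = _matrix_of(S1)
    Y = solve_lp_system(M, (1.0 - alpha) * assoc.values, alpha)
    return ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), Y)


def update_scores_phenotype_side(
    S2, assoc: AssociationMatrix, alpha2: float
) -> ScoreMatrix:
    """Closed-form score update Y = (1-α') Ŷ (I - α' S2)^{-1}."""
    M = _matrix_of(S2)
    Y = solve_lp_system(M.T, (1.0 - alpha2) * assoc.values.T, alpha2).T
    return ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), Y)


# ---------------------------------------------------------------------------
# Objective bookkeeping
# ---------------------------------------------------------------------------


def _laplacian_term(Y: np.ndarray, S: np.ndarray, side: str) -> float:
    if side == "gene":
        return float(np.trace(Y.T @ Y) - np.trace(Y.T @ (S @ Y)))
    return float(np.trace(Y @ Y.T) - np.trace(Y @ (S @ Y.T)))


def _deviation_term(S: np.ndarray, S_bar: np.ndarray, weight: float) -> float:
    # infinite-weight convention: a pinned network contributes exactly 0
    if np.isinf(weight):
        return 0.0
    return weight * float(np.sum((S - S_bar) ** 2))


def psi_gene(
    Y: np.ndarray,
    S1: np.ndarray,
    assoc: np.ndarray,
    S1_bar: np.ndarray,
    mu: float,
    nu: float,
) -> float:
    """Gene-side sub-objective: smoothness + fidelity + network deviation."""
    return (
        _laplacian_term(Y, S1, "gene")
        + mu * float(np.sum((Y - assoc) ** 2))
        + _deviation_term(S1, S1_bar, nu)
    )


def psi_phenotype(
    Y: np.ndarray,
    S2: np.ndarray,
    assoc: np.ndarray,
    S2_bar: np.ndarray,
    zeta: float,
    eta: float,
) -> float:
    """Phenotype-side sub-objective."""
    return (
        _laplacian_term(Y, S2, "phenotype")
        + zeta * float(np.sum((Y - assoc) ** 2))
        + _deviation_term(S2, S2_bar, eta)
    )


def objective_value(
    Y,
    S1,
    S2,
    assoc: AssociationMatrix,
    S1_bar,
    S2_bar,
    params: IDLPParams,
) -> float:
    """Overall loss L(Y, S1, S2); pinned networks contribute no deviation term."""
    Yv = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    S1v, S2v = _matrix_of(S1), _matrix_of(S2)
    S1b, S2b = _matrix_of(S1_bar), _matrix_of(S2_bar)
    return (
        _laplacian_term(Yv, S1v, "gene")
        + _laplacian_term(Yv, S2v, "phenotype")
        + (params.mu + params.zeta) * float(np.sum((Yv - assoc.values) ** 2))
        + _deviation_term(S1v, S1b, params.nu)
        + _deviation_term(S2v, S2b, params.eta)
    )


# ---------------------------------------------------------------------------
# The solver
# ---------------------------------------------------------------------------


def fit_idlp(
    gene_net: IndexedNetwork,
    pheno_net: IndexedNetwork,
    assoc: AssociationMatrix,
    params: IDLPParams | None = None,
) -> IDLPFit:
    """Fit IDLP by alternating closed-form block updates.

    The association matrix must already be aligned to the two networks
    (same id order on both axes; see :func:`idlp.netio.align_universe`).
    Y is initialized to Ŷ.  Each outer iteration updates, in the configured
    block order, a network block followed by the matching score block, on
    both sides.  The loop stops when the relative Frobenius change of Y
    falls below ``params.tol`` or after ``params.max_outer_iter`` sweeps;
    non-convergence is recorded in the trace, not raised.

    The solver itself is deterministic: identical inputs give bit-identical
    outputs.
    """
    if params is None:
        params = IDLPParams()
    if list(assoc.gene_ids) != list(gene_net.node_ids):
        raise ValidationError("association gene axis does not match gene network")
    if list(assoc.phenotype_ids) != list(pheno_net.node_ids):
        raise ValidationError(
            "association phenotype axis does not match phenotype network"
        )
    S1_bar = normalize(gene_net)
    S2_bar = normalize(pheno_net)
    return _fit_idlp_normalized(S1_bar, S2_bar, assoc, params)


def _fit_idlp_normalized(
    S1_bar: NormalizedNetwork,
    S2_bar: NormalizedNetwork,
    assoc: AssociationMatrix,
    params: IDLPParams,
) -> IDLPFit:
    """Solver core operating on pre-normalized networks."""
    gamma = params.effective_gamma
    gamma2 = params.effective_gamma2
    Yhat = assoc.values
    Y = Yhat.copy()
    S1 = S1_bar.matrix
    S2 = S2_bar.matrix
    trace = FitTrace()

    def sweep_side(side: str, Y: np.ndarray):
        nonlocal S1, S2
        if side == "gene":
            S1 = update_gene_network(S1_bar, Y, gamma)
            if params.check_spectral_radius:
                _warn_if_expansive(S1, params.alpha, "gene")
            return update_scores_gene_side(S1, assoc, params.alpha).values
        S2 = update_phenotype_network(S2_bar, Y, gamma2)
        if params.check_spectral_radius:
            _warn_if_expansive(S2, params.alpha2, "phenotype")
        return update_scores_phenotype_side(S2, assoc, params.alpha2).values

    for it in range(1, params.max_outer_iter + 1):
        Y_prev = Y
        for side in params.block_order:
            Y = sweep_side(side, Y)
        denom = max(float(np.linalg.norm(Y_prev)), 1e-300)
        rel = float(np.linalg.norm(Y - Y_prev)) / denom
        p1 = psi_gene(Y, S1, Yhat, S1_bar.matrix, params.mu, params.nu)
        p2 = psi_phenotype(Y, S2, Yhat, S2_bar.matrix, params.zeta, params.eta)
        obj = objective_value(Y, S1, S2, assoc, S1_bar, S2_bar, params)
        trace.append(it, p1, p2, obj, rel)
        if rel < params.tol:
            trace.converged = True
            break
    if not trace.converged:
        logger.warning(
            "IDLP did not reach tol=%g within %d outer iterations "
            "(last relative change %.3g)",
            params.tol,
            params.max_outer_iter,
            trace.rel_change[-1] if trace.rel_change else float("nan"),
        )
    scores = ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), Y)
    return IDLPFit(scores, LearnedNetworks(S1=S1, S2=S2), trace)


def _warn_if_expansive(S: np.ndarray, alpha: float, side: str) -> None:
    # power-iteration estimate is enough for a diagnostic
    rho = float(np.max(np.abs(np.linalg.eigvalsh(S))))
    if alpha * rho >= 1.0:
        logger.warning(
            "%s-side operator has alpha*rho(S) = %.3f >= 1; the closed form "
            "remains valid while (I - alpha*S) is nonsingular, but the "
            "update is outside the convergent-series regime",
            side,
            alpha * rho,
        )
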