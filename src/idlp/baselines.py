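"""Baseline scorers: bi-random walk (BiRW) and random walk with restart (RWR).

BiRW alternates a "left" walk on the gene network, Y_t = αS1Y_{t-1}+(1-α)Ŷ,
with a "right" walk on the phenotype network, Y_t = αY_{t-1}S2+(1-α)Ŷ, and
combines the two walk results.  After sufficiently many steps each walk
reaches its own closed-form limit

    Y*_left  = β (I - αS1)^{-1} Ŷ,
    Y*_right = β Ŷ (I - αS2)^{-1},      β = 1 - α,

which are exactly the per-side score updates of the IDLP solver when neither
network is learned (γ = γ' = 0): BiRW is the no-network-learning special
case of IDLP, and the test-suite asserts that equality to solver tolerance.

The "averaged" BiRW variant combines the left and right iterates by their
mean at every step; this is the combination rule used here (the variant
family leaves it open — documented interpretation).

RWR scores genes from a seed set on the gene network alone; it cannot rank
genes for a phenotype with no known genes (no seeds), which is exactly the
failure mode on singleton phenotypes that motivates phenotype-side
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .netio import (
    AssociationMatrix,
    ScoreMatrix,
    ValidationError,
)
from .propagation import NormalizedNetwork, solve_lp_system

__all__ = ["BiRWParams", "birw_closed_form", "birw_iterative", "rwr"]


@dataclass
class BiRWParams:
    """Bi-random-walk controls: walk weight, step counts, combination mode."""

    alpha: float = 0.5
    left_steps: int = 4
    right_steps: int = 4
    mode: str = "averaged"  # 'averaged', 'iterative' per-side, or 'closed_form'

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValidationError("alpha must lie in [0, 1)")
        if self.left_steps < 0 or self.right_steps < 0:
            raise ValidationError("step counts must be non-negative")


def _matrix(S) -> np.ndarray:
    return S.matrix if isinstance(S, NormalizedNetwork) else np.asarray(S, dtype=float)


def birw_closed_form(
    S1_bar,
    S2_bar,
    assoc: AssociationMatrix,
    alpha: float,
) -> tuple[ScoreMatrix, ScoreMatrix]:
    """Closed-form left/right walk limits; combine by averaging if desired.

    Returns ``(left, right)`` score matrices.  The averaged-BiRW combined
    score is ``(left.values + right.values) / 2``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie strictly between 0 and 1")
    S1 = _matrix(S1_bar)
    S2 = _matrix(S2_bar)
    beta = 1.0 - alpha
    left = solve_lp_system(S1, beta * assoc.values, alpha)
    right = solve_lp_system(S2.T, beta * assoc.values.T, alpha).T
    axes = (list(assoc.gene_ids), list(assoc.phenotype_ids))
    return ScoreMatrix(*axes, left), ScoreMatrix(*axes, right)


def birw_iterative(
    S1_bar,
    S2_bar,
    assoc: AssociationMatrix,
    params: BiRWParams | None = None,
) -> ScoreMatrix:
    """Run finite left/right walks and combine them (averaged variant).

    The left and right walks are independent recursions started at Ŷ; the
    returned score is the mean of the two final iterates (a walk with zero
    steps contributes Ŷ itself, so 0/0 steps returns Ŷ exactly).
    """
    if params is None:
        params = BiRWParams()
    S1 = _matrix(S1_bar)
    S2 = _matrix(S2_bar)
    Yhat = assoc.values
    a, b = params.alpha, 1.0 - params.alpha
    Yl = Yhat.copy()
    Yr = Yhat.copy()
    for _ in range(params.left_steps):
        Yl = a * (S1 @ Yl) + b * Yhat
    for _ in range(params.right_steps):
        Yr = a * (Yr @ S2) + b * Yhat
    combined = (Yl + Yr) / 2.0
    return ScoreMatrix(list(assoc.gene_ids), list(assoc.phenotype_ids), combined)


def rwr(
    S1_bar,
    seed_genes: Iterable[str],
    restart: float,
    gene_ids: list[str] | None = None,
    allow_empty: bool = False,
) -> np.ndarray:
    """Random walk with restart on the gene network from a seed gene set.

    Solves the fixed point y = (1-r) S̄1 y + r y0 with y0 uniform over the
    seeds.  An empty seed set is refused by default — a gene-side-only
    walker has nothing to start from on a singleton phenotype — unless
    ``allow_empty`` is set, in which case the all-zero vector is returned.
    """
    if not 0 < restart <= 1:
        raise ValidationError("restart probability must lie in (0, 1]")
    if gene_ids is None:
        if not isinstance(S1_bar, NormalizedNetwork):
            raise ValidationError("gene_ids required when S1_bar is a bare matrix")
        gene_ids = S1_bar.node_ids
    S = _matrix(S1_bar)
    seeds = list(seed_genes)
    if not seeds:
        if allow_empty:
            return np.zeros(len(gene_ids))
        raise ValidationError("RWR requires a non-empty seed gene set")
    index = {g: i for i, g in enumerate(gene_ids)}
    unknown = [g for g in seeds if g not in index]
    if unknown:
        raise ValidationError(f"seed gene(s) not in network: {unknown[:5]}")
    y0 = np.zeros(len(gene_ids))
    for g in seeds:
        y0[index[g]] = 1.0 / len(seeds)
    if restart == 1.0:
        return y0
    # y = (1-r) S y + r y0  <=>  (I - (1-r) S) y = r y0
    return solve_lp_system(S, restart * y0, 1.0 - restart)
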