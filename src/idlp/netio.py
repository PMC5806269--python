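"""Domain containers and file I/O for heterogeneous gene/phenotype networks.

The package works with three kinds of objects: symmetric weighted networks
(:class:`IndexedNetwork`), binary gene–phenotype association matrices
(:class:`AssociationMatrix`) and real-valued learned score matrices
(:class:`ScoreMatrix`).  All of them carry explicit, ordered node-id axes so
that every matrix row/column is unambiguously attached to a gene or phenotype
identifier.  Identifiers are opaque strings; no symbol normalization is
attempted.

Canonical on-disk formats are plain TSV: edge lists
(``node_a<TAB>node_b<TAB>weight?``), association pair lists
(``gene_id<TAB>phenotype_id``) and ranking tables.  Sparse matrices can
additionally be exchanged as MatrixMarket files with a sidecar id list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "NumericalError",
    "IndexedNetwork",
    "AssociationMatrix",
    "ScoreMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_associations",
    "write_associations",
    "align_universe",
    "write_rankings",
    "save_matrix_market",
    "load_matrix_market",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Input violates a documented contract."""


class NumericalError(RuntimeError):
    """A linear solve failed or iterates diverged."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class IndexedNetwork:
    """An undirected weighted network: ordered node ids + symmetric matrix.

    ``weights`` is a dense float array with one row/column per entry of
    ``node_ids``.  Entries are non-negative; the diagonal is zero for binary
    interaction networks and may be positive for similarity networks
    (self-similarity).
    """

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        W = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node ids in network")
        if W.shape != (n, n):
            raise ValidationError(
                f"weight matrix shape {W.shape} does not match {n} node ids"
            )
        if n and not np.allclose(W, W.T, atol=1e-12):
            raise ValidationError("weight matrix is not symmetric")
        if n and W.min() < 0:
            raise ValidationError("negative edge weight in network")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def index(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.node_ids)}

    def degrees(self) -> np.ndarray:
        """Row sums of the weight matrix (weighted degrees)."""
        return self.weights.sum(axis=1)

    def n_edges(self) -> int:
        """Number of off-diagonal undirected edges with positive weight."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return int((self.weights[iu, ju] > 0).sum())

    def subnetwork(self, keep: Sequence[str]) -> "IndexedNetwork":
        idx = self.index
        rows = [idx[k] for k in keep]
        return IndexedNetwork(list(keep), self.weights[np.ix_(rows, rows)])


@dataclass
class AssociationMatrix:
    """Binary n×m gene–phenotype association matrix with id maps on both axes."""

    gene_ids: list[str]
    phenotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.phenotype_ids = list(self.phenotype_ids)
        Y = np.asarray(self.values, dtype=float)
        if Y.shape != (len(self.gene_ids), len(self.phenotype_ids)):
            raise ValidationError(
                f"association matrix shape {Y.shape} does not match id axes "
                f"({len(self.gene_ids)}, {len(self.phenotype_ids)})"
            )
        if Y.size and not np.isin(Y, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        self.values = Y

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def phenotype_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.phenotype_ids)}

    def pairs(self) -> list[tuple[str, str]]:
        """Known (gene_id, phenotype_id) pairs in row-major order."""
        gi, pj = np.nonzero(self.values)
        return [(self.gene_ids[i], self.phenotype_ids[j]) for i, j in zip(gi, pj)]

    def reindexed(
        self, gene_ids: Sequence[str], phenotype_ids: Sequence[str]
    ) -> "AssociationMatrix":
        """Project onto new axes; pairs outside the new universe are dropped."""
        out = np.zeros((len(gene_ids), len(phenotype_ids)))
        gidx = {g: i for i, g in enumerate(gene_ids)}
        pidx = {p: j for j, p in enumerate(phenotype_ids)}
        for g, p in self.pairs():
            if g in gidx and p in pidx:
                out[gidx[g], pidx[p]] = 1.0
        return AssociationMatrix(list(gene_ids), list(phenotype_ids), out)


@dataclass
class ScoreMatrix:
    """Real-valued learned association scores, aligned like an AssociationMatrix."""

    gene_ids: list[str]
    phenotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.phenotype_ids = list(self.phenotype_ids)
        Y = np.asarray(self.values, dtype=float)
        if Y.shape != (len(self.gene_ids), len(self.phenotype_ids)):
            raise ValidationError("score matrix shape does not match id axes")
        if Y.size and not np.isfinite(Y).all():
            raise ValidationError("score matrix contains non-finite entries")
        self.values = Y

    @property
    def phenotype_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.phenotype_ids)}

    def column(self, phenotype_id: str) -> np.ndarray:
        try:
            j = self.phenotype_index[phenotype_id]
        except KeyError:
            raise KeyError(f"unknown phenotype id: {phenotype_id!r}") from None
        return self.values[:, j]

    def ranked_genes(
        self, phenotype_id: str, exclude: Iterable[str] = ()
    ) -> list[str]:
        """Genes ordered by descending score, ties broken by ascending id."""
        col = self.column(phenotype_id)
        excl = set(exclude)
        order = sorted(
            (g for g in self.gene_ids if g not in excl),
            key=lambda g: (-col[self.gene_ids.index(g)], g),
        )
        return order


# faster ranking helper used internally (ScoreMatrix.ranked_genes is O(n^2))
def ranked_gene_list(
    scores: ScoreMatrix, phenotype_id: str, exclude: Iterable[str] = ()
) -> list[str]:
    col = scores.column(phenotype_id)
    excl = set(exclude)
    genes = np.asarray(scores.gene_ids, dtype=object)
    order = np.lexsort((genes, -col))
    return [genes[i] for i in order if genes[i] not in excl]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, directed_ok: bool = False) -> IndexedNetwork:
    """Read a TSV edge list ``node_a<TAB>node_b<TAB>weight?`` into a network.

    The result is always symmetric.  If an edge appears in both orientations
    with different weights the maximum is kept and a warning is logged
    (conservative for binary interaction data, where any report implies an
    interaction).  Self-loops become diagonal entries.

    Parameters
    ----------
    path:
        TSV file; whitespace-delimited fields also accepted.
    directed_ok:
        Accepted for signature compatibility; input is symmetrized regardless.
    """
    path = Path(path)
    node_ids: list[str] = []
    index: dict[str, int] = {}
    entries: dict[tuple[int, int], float] = {}
    conflicts = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise ValidationError(
                    f"{path.name}:{lineno}: negative edge weight {w}"
                )
            for node in (a, b):
                if node not in index:
                    index[node] = len(node_ids)
                    node_ids.append(node)
            i, j = index[a], index[b]
            key = (min(i, j), max(i, j))
            if key in entries and entries[key] != w:
                conflicts += 1
                w = max(entries[key], w)
            entries[key] = max(entries.get(key, w), w)
    if conflicts:
        logger.warning(
            "%s: %d duplicate edges with conflicting weights; kept the maximum",
            path.name,
            conflicts,
        )
    n = len(node_ids)
    W = np.zeros((n, n))
    for (i, j), w in entries.items():
        W[i, j] = w
        W[j, i] = w
    return IndexedNetwork(node_ids, W)


def write_edge_list(net: IndexedNetwork, path: str | Path) -> None:
    """Write the upper triangle (plus diagonal self-loops) as a TSV edge list."""
    path = Path(path)
    with path.open("w") as fh:
        n = net.n_nodes
        for i in range(n):
            for j in range(i, n):
                w = net.weights[i, j]
                if w != 0:
                    fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{w:.17g}\n")


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a TSV pair list ``gene_id<TAB>phenotype_id`` into a binary matrix.

    Duplicate pairs collapse to a single 1.  Axis order is first-seen order.
    """
    path = Path(path)
    gene_ids: list[str] = []
    pheno_ids: list[str] = []
    gidx: dict[str, int] = {}
    pidx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            g, p = fields
            if g not in gidx:
                gidx[g] = len(gene_ids)
                gene_ids.append(g)
            if p not in pidx:
                pidx[p] = len(pheno_ids)
                pheno_ids.append(p)
            pairs.add((gidx[g], pidx[p]))
    if not pairs:
        raise ValidationError(f"{path.name}: no association pairs found")
    Y = np.zeros((len(gene_ids), len(pheno_ids)))
    for i, j in pairs:
        Y[i, j] = 1.0
    return AssociationMatrix(gene_ids, pheno_ids, Y)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g, p in assoc.pairs():
            fh.write(f"{g}\t{p}\n")


def align_universe(
    gene_net: IndexedNetwork,
    pheno_net: IndexedNetwork,
    assoc: AssociationMatrix,
) -> tuple[IndexedNetwork, IndexedNetwork, AssociationMatrix]:
    """Filter out isolated nodes and project associations onto the networks.

    Zero-degree nodes cannot receive or send propagated label mass (and make
    the symmetric normalization undefined), so they are removed.  Association
    pairs referencing removed or unknown ids are dropped with a logged count.
    The returned association matrix has axes exactly equal to the filtered
    networks' node orders, so downstream matrix algebra lines up.
    """
    gene_keep = [
        nid for nid, d in zip(gene_net.node_ids, gene_net.degrees()) if d > 0
    ]
    pheno_keep = [
        nid for nid, d in zip(pheno_net.node_ids, pheno_net.degrees()) if d > 0
    ]
    if not gene_keep:
        raise ValidationError("gene universe is empty after removing isolated nodes")
    if not pheno_keep:
        raise ValidationError(
            "phenotype universe is empty after removing isolated nodes"
        )
    g_sub = gene_net.subnetwork(gene_keep)
    p_sub = pheno_net.subnetwork(pheno_keep)
    before = int(assoc.values.sum())
    new_assoc = assoc.reindexed(gene_keep, pheno_keep)
    dropped = before - int(new_assoc.values.sum())
    if dropped:
        logger.info(
            "align_universe: dropped %d association(s) referencing removed or "
            "unknown ids",
            dropped,
        )
    return g_sub, p_sub, new_assoc


def write_rankings(
    scores: ScoreMatrix,
    query_phenotypes: Sequence[str],
    top_k: int,
    path: str | Path,
) -> None:
    """Write per-query top-k gene rankings as TSV.

    Columns: phenotype_id, rank, gene_id, score.  Genes are ordered by
    descending score with ties broken by ascending gene id, which makes
    every downstream metric deterministic.  ``top_k`` larger than the gene
    universe is clamped.
    """
    if top_k < 1:
        raise ValidationError("top_k must be a positive integer")
    rows = []
    for p in query_phenotypes:
        col = scores.column(p)  # raises KeyError naming unknown ids
        ranked = ranked_gene_list(scores, p)
        gidx = {g: i for i, g in enumerate(scores.gene_ids)}
        for rank, g in enumerate(ranked[:top_k], start=1):
            rows.append((p, rank, g, col[gidx[g]]))
    frame = pd.DataFrame(rows, columns=["phenotype_id", "rank", "gene_id", "score"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MatrixMarket exchange
# ---------------------------------------------------------------------------


def save_matrix_market(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    path: str | Path,
    col_ids: Sequence[str] | None = None,
) -> None:
    """Write a matrix as MatrixMarket plus ``<path>.rows``/``.cols`` sidecars."""
    path = Path(path)
    spio.mmwrite(str(path), sparse.coo_matrix(np.asarray(matrix)))
    Path(str(path) + ".rows").write_text("\n".join(row_ids) + "\n")
    if col_ids is not None:
        Path(str(path) + ".cols").write_text("\n".join(col_ids) + "\n")


def load_matrix_market(
    path: str | Path,
) -> tuple[np.ndarray, list[str], list[str] | None]:
    path = Path(path)
    mat = spio.mmread(str(path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    rows = Path(str(path) + ".rows").read_text().splitlines()
    cols_file = Path(str(path) + ".cols")
    cols = cols_file.read_text().splitlines() if cols_file.exists() else None
    return np.asarray(mat, dtype=float), rows, cols
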