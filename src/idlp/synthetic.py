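"""Synthetic heterogeneous-network benchmarks with planted association structure.

The generator emulates the statistical shape of real gene/phenotype
prioritization data: a sparse binary gene interaction network, a dense
non-negative phenotype similarity network, very few known genes per
phenotype (≈1.1 on average, most phenotypes having exactly one), and a
sizeable fraction of "singleton" query phenotypes whose associations are
entirely held out of training.

The generative model is module-based, honoring the premise that genes that
are physically or functionally close tend to affect similar phenotypes:
genes and phenotypes are partitioned into modules; gene edges are Bernoulli
with a higher probability within modules than between; phenotype similarity
is module-membership agreement plus clipped symmetric Gaussian noise; each
phenotype draws its true genes from its own module.  Training-network noise
(false-positive / false-negative edges) is injected by the same perturbation
operator used in the robustness protocol, so the clean network is retained
in the truth record.

All randomness flows from the single integer seed in the configuration.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .evaluation import perturb_network
from .netio import (
    AssociationMatrix,
    IndexedNetwork,
    ValidationError,
    write_associations,
    write_edge_list,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "Benchmark", "generate_benchmark",
           "summarize_benchmark", "write_benchmark"]


@dataclass
class SyntheticConfig:
    """Knobs of the benchmark generator.

    Defaults target the shape of curated association snapshots: ~1.1 genes
    per phenotype, most phenotypes single-gene, a sparse binary gene
    network with planted modules, and 10% singleton query phenotypes.
    """

    n_genes: int = 300
    n_phenotypes: int = 200
    n_modules: int = 10
    p_within: float = 0.3
    p_between: float = 0.01
    pheno_noise_sd: float = 0.1
    assoc_per_phenotype_mean: float = 1.1
    singleton_frac: float = 0.1
    fp_edge_frac: float = 0.0
    fn_edge_frac: float = 0.0
    holdout_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_phenotypes, self.n_modules) < 1:
            raise ValidationError("counts must be positive")
        if self.n_modules > min(self.n_genes, self.n_phenotypes):
            raise ValidationError("more modules than genes or phenotypes")
        for name in ("p_within", "p_between", "singleton_frac",
                     "fp_edge_frac", "fn_edge_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not self.p_within > self.p_between:
            raise ValidationError(
                "p_within must exceed p_between (no planted signal otherwise)"
            )
        if self.pheno_noise_sd < 0:
            raise ValidationError("pheno_noise_sd must be non-negative")
        if self.assoc_per_phenotype_mean <= 0:
            raise ValidationError("assoc_per_phenotype_mean must be positive")
        if not 0 < self.holdout_frac < 1:
            raise ValidationError("holdout_frac must lie in (0, 1)")


class Benchmark(NamedTuple):
    gene_net: IndexedNetwork
    pheno_net: IndexedNetwork
    train_assoc: AssociationMatrix
    test_pairs: list[tuple[str, str]]
    truth: dict


def _module_of(i: int, total: int, n_modules: int) -> int:
    return i * n_modules // total


def generate_benchmark(config: SyntheticConfig) -> Benchmark:
    """Generate one benchmark instance; a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    n, m, K = config.n_genes, config.n_phenotypes, config.n_modules
    gene_ids = [f"g{i:04d}" for i in range(n)]
    pheno_ids = [f"p{j:04d}" for j in range(m)]
    gene_mod = np.array([_module_of(i, n, K) for i in range(n)])
    pheno_mod = np.array([_module_of(j, m, K) for j in range(m)])

    # --- gene network: planted-partition Bernoulli edges, binary ----------
    same_g = gene_mod[:, None] == gene_mod[None, :]
    P = np.where(same_g, config.p_within, config.p_between)
    U = rng.random((n, n))
    upper = np.triu(U < P, k=1)
    W1 = (upper | upper.T).astype(float)
    clean_gene_net = IndexedNetwork(gene_ids, W1)

    # --- phenotype similarity: membership agreement + clipped noise ------
    same_p = (pheno_mod[:, None] == pheno_mod[None, :]).astype(float)
    noise = np.triu(rng.normal(0.0, config.pheno_noise_sd, (m, m)), k=1)
    W2 = np.clip(same_p + noise + noise.T, 0.0, None)
    np.fill_diagonal(W2, 1.0)
    pheno_net = IndexedNetwork(pheno_ids, W2)

    # --- associations: each phenotype draws genes from its own module ----
    Y = np.zeros((n, m))
    for j in range(m):
        members = np.flatnonzero(gene_mod == pheno_mod[j])
        count = max(1, int(rng.poisson(config.assoc_per_phenotype_mean)))
        if count > len(members):
            raise ValidationError(
                f"module {pheno_mod[j]} has {len(members)} genes but phenotype "
                f"{pheno_ids[j]} requires {count} associations"
            )
        chosen = rng.choice(members, size=count, replace=False)
        Y[chosen, j] = 1.0
    all_pairs = [
        (gene_ids[i], pheno_ids[j]) for i, j in zip(*np.nonzero(Y))
    ]

    # --- training-network corruption (false neg = delete, false pos = add)
    gene_net = clean_gene_net
    if config.fn_edge_frac > 0 or config.fp_edge_frac > 0:
        gene_net = perturb_network(
            clean_gene_net,
            delete_frac=config.fn_edge_frac,
            add_frac=config.fp_edge_frac,
            seed=int(rng.integers(2**31)),
        )

    # --- holdout: singleton phenotypes first, then extra random pairs ----
    n_singleton = int(round(config.singleton_frac * m))
    singleton_phenos = set(
        rng.choice(pheno_ids, size=n_singleton, replace=False).tolist()
    ) if n_singleton else set()
    test = [(g, p) for g, p in all_pairs if p in singleton_phenos]
    target_test = int(round(config.holdout_frac * len(all_pairs)))
    if len(test) < target_test:
        # eligible extras: pairs whose phenotype keeps >= 1 training pair
        remaining = [(g, p) for g, p in all_pairs if p not in singleton_phenos]
        per_pheno: dict[str, int] = {}
        for g, p in remaining:
            per_pheno[p] = per_pheno.get(p, 0) + 1
        eligible = [pair for pair in remaining if per_pheno[pair[1]] >= 2]
        need = target_test - len(test)
        if need > 0 and eligible:
            take = min(need, len(eligible))
            # sample pairs, re-checking the keep->=1 constraint greedily
            order = rng.permutation(len(eligible))
            kept: list[tuple[str, str]] = []
            counts = dict(per_pheno)
            for idx in order:
                g, p = eligible[idx]
                if counts[p] >= 2:
                    kept.append((g, p))
                    counts[p] -= 1
                if len(kept) == take:
                    break
            test.extend(kept)
        if len(test) < target_test:
            logger.info(
                "holdout target %d not reachable without creating unplanned "
                "singletons; held out %d pairs",
                target_test,
                len(test),
            )
    test_set = set(test)
    Y_train = Y.copy()
    gidx = {g: i for i, g in enumerate(gene_ids)}
    pidx = {p: j for j, p in enumerate(pheno_ids)}
    for g, p in test_set:
        Y_train[gidx[g], pidx[p]] = 0.0
    train_assoc = AssociationMatrix(gene_ids, pheno_ids, Y_train)

    truth = {
        "gene_modules": {g: int(mod) for g, mod in zip(gene_ids, gene_mod)},
        "phenotype_modules": {p: int(mod) for p, mod in zip(pheno_ids, pheno_mod)},
        "clean_gene_net": clean_gene_net,
        "singleton_phenotypes": sorted(singleton_phenos),
        "config": asdict(config),
    }
    return Benchmark(gene_net, pheno_net, train_assoc, sorted(test_set), truth)


def summarize_benchmark(benchmark: Benchmark) -> dict:
    """Dataset statistics: sizes, associations per phenotype, sparsity."""
    gene_net, pheno_net, train_assoc, test_pairs, _ = benchmark
    n, m = gene_net.n_nodes, pheno_net.n_nodes
    total = train_assoc.values.copy()
    gidx = train_assoc.gene_index
    pidx = train_assoc.phenotype_index
    for g, p in test_pairs:
        total[gidx[g], pidx[p]] = 1.0
    genes_per_pheno = total.sum(axis=0)
    phenos_per_gene = total.sum(axis=1)
    n_assoc = int(total.sum())
    return {
        "n_genes": n,
        "n_phenotypes": m,
        "n_associations": n_assoc,
        "n_train_associations": int(train_assoc.values.sum()),
        "n_test_associations": len(test_pairs),
        "mean_genes_per_phenotype": float(n_assoc / m),
        "mean_phenotypes_per_gene": float(n_assoc / max((phenos_per_gene > 0).sum(), 1)),
        "pct_single_gene_phenotypes": float(100.0 * (genes_per_pheno == 1).mean()),
        "ppi_sparsity_pct": float(
            100.0 * (1.0 - np.count_nonzero(gene_net.weights) / (n * n))
        ),
    }


def write_benchmark(benchmark: Benchmark, outdir: str | Path) -> None:
    """Write the benchmark as TSV edge/pair lists plus a JSON truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(benchmark.gene_net, outdir / "gene_net.tsv")
    write_edge_list(benchmark.pheno_net, outdir / "pheno_net.tsv")
    write_associations(benchmark.train_assoc, outdir / "train_assoc.tsv")
    with (outdir / "test_pairs.tsv").open("w") as fh:
        for g, p in benchmark.test_pairs:
            fh.write(f"{g}\t{p}\n")
    truth = dict(benchmark.truth)
    clean = truth.pop("clean_gene_net")
    write_edge_list(clean, outdir / "clean_gene_net.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
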