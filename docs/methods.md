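# Methods

## Model

The package scores gene–phenotype associations on a two-layer heterogeneous
network. Genes live on an undirected interaction network W₁, phenotypes on
an undirected similarity network W₂; the known associations form a binary
matrix Ŷ ∈ {0,1}^{n×m}. Both networks are symmetrically normalized,
S̄ᵢ = Dᵢ^{-1/2} Wᵢ Dᵢ^{-1/2} with Dᵢ the diagonal degree matrix, which
bounds the spectral radius by 1 whenever all degrees are positive (isolated
nodes are removed up front by `align_universe`, which also makes the
normalization well defined).

Plain label propagation on one network balances smoothness along edges
against fidelity to the initial labels; its minimizer is
Y = (1−α)(I − αS̄)⁻¹Ŷ. The model here extends this in two directions:

1. **Dual propagation.** Labels propagate on the gene side (columns of Y,
   one per query phenotype) *and* on the phenotype side (rows of Y, one per
   query gene). The phenotype side is what makes singleton phenotypes —
   queries with no known gene — rankable at all: their scores are borrowed
   from similar phenotypes' genes.
2. **Network learning.** Interaction data carry false-positive edges, so
   the normalized networks are replaced by variables S₁, S₂ penalized for
   deviating from S̄₁, S̄₂ (Frobenius norm, weights ν, η). Minimizing over
   S₁ given Y has the closed form S₁ = S̄₁ + γYYᵀ with γ = 1/(2ν): edge
   weight is shifted toward gene pairs that the current association scores
   say behave alike, and away (relatively) from edges the labels do not
   support.

The overall loss is not jointly convex, but it is convex per block, and the
solver does block coordinate descent in which *every* block update is a
closed-form minimizer (S₁ ← S̄₁+γYYᵀ; Y ← β(I−αS₁)⁻¹Ŷ; S₂ ← S̄₂+γ′YᵀY;
Y ← β′Ŷ(I−α′S₂)⁻¹). Linear systems are solved by LU factorization
(dense below dimension 2000, sparse LU above when the operator is sparse);
no explicit inverse is ever formed, which is both faster and more accurate.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| α, α′ | propagation weight per side, in (0,1); fidelity weight is 1−α | 0.1 | the historical grid is {0.0001, 0.001, 0.01, 0.1, 1−ε} |
| γ, γ′ | network-learning rate, ≥ 0 | 1000 | 0 = network pinned (the ν→∞ limit); realizes the `idlp-g`/`idlp-p`/`birw` variants |
| max_outer_iter | outer sweeps | 20 | non-convergence is recorded in the trace, not raised |
| tol | relative Frobenius change of Y to declare convergence | 1e-6 | stopping rule is ours; the update equations do not prescribe one |
| block_order | which side updates first | gene, phenotype | exchangeable; both orders converge on all shipped fixtures |

The γ default of 1000 matches the regime reported for OMIM-scale data. On
desk-scale synthetic benchmarks the useful γ range is orders of magnitude
smaller, because γ multiplies YYᵀ and the Frobenius mass of Y relative to
network size is far larger on a 300×200 instance with ~250 associations
than on a 3292×4120 instance with ~4700. The benchmark studies therefore
use the grid {0, 0.03, 0.1, 0.3} (module `idlp.study`), with γ chosen on a
validation split.

**Convex regime.** The Y-update is the *minimizer* of its sub-objective
only while I − αS₁ is positive definite, i.e. α·ρ(S₁) < 1. Large γ can push
ρ(S₁) past 1/α; the closed form remains valid (the solver proceeds whenever
the system is nonsingular, with an optional spectral-radius diagnostic) but
the update is then a stationary point, not a descent step, and the outer
loop may oscillate. The 50×40 convergence fixture and the solver tests use
α = 0.1, γ = γ′ = 0.1, which keeps α·ρ(S₁) < 1 throughout — there the block
descent inequality holds to machine precision and the outer loop reaches a
relative change below 1e-8 in well under 50 sweeps. Model selection in the
benchmark studies never deploys a non-converged fit: grid values whose fit
fails to converge are discarded at validation time and again at refit time,
falling back down the validation ranking (γ = 0 always converges, so the
procedure terminates).

**Initialization** is Y₀ = Ŷ. Ŷ is the only label source; starting from
zero would make the first S-update a no-op and produce the same iterates
after the first Y-update, so nothing substantive depends on this choice.

**Interpretation of the variants.** `idlp-g` ("only the gene network is
noisy") pins S₂ = S̄₂ and learns S₁; `idlp-p` pins S₁ and learns S₂. This is
the zero-learning-rate (infinite-penalty) reading of the variants: the
network that is *not* assumed noisy is held at its observed normalization.

**Returned scores.** A full sweep ends with the phenotype-side update, so
the returned Y is the phenotype-side closed form evaluated at the learned
S₂; gene-network information enters through the learned matrices (S₂
absorbs YᵀY from the gene-side update). In the γ = γ′ = 0 special case this
reduces to the right-walk closed form, and the left/gene-side closed form
is recoverable from the returned S₁ — the BiRW equivalence tests check both
sides.

## Baselines

**BiRW** alternates finite left walks Y ← αS₁Y + (1−α)Ŷ and right walks
Y ← αYS₂ + (1−α)Ŷ (defaults: 4 and 4 steps). The shipped variant is the
*averaged* one; since the combination rule of the averaged family is not
fully specified by its description, the implementation keeps the two walks
as independent recursions and averages their iterates — this makes each
side converge to its own closed-form limit, which is what the special-case
equivalence requires. **RWR** solves y = (1−r)S̄₁y + r·y₀ from a uniform
seed vector over a phenotype's known genes; it refuses an empty seed set by
default (configurable to return zeros), which is precisely its failure mode
on singleton phenotypes.

## Evaluation protocol

The headline metric is the ROC area truncated at the first k false
positives: walking a ranking, TP(f) = positives seen before the f-th
negative, and AUC-k = Σ_{f≤k} TP(f) / (k·P). The normalization by k·P (so
a perfect ranking scores 1) is a documented choice — the truncated-AUC
family does not have a single canonical normalization, and published
absolute values cannot disambiguate one without the original data. The
implementation is verified against a literal walk oracle on every labelled
ranking of up to 8 items. Top-k precision/recall are averaged over query
phenotypes; queries with no test positives are skipped with a logged count.

Candidates for a query phenotype are all universe genes minus that
phenotype's training-known genes. On universes smaller than a cutoff the
cutoff is clamped to the available negatives (only relevant for toy data).
Ties in every ranking break by ascending gene id, making all metrics
deterministic. Singleton and non-singleton query subsets are reported
separately.

Cross-validation partitions association *pairs* uniformly into folds
(sizes differing by at most one, deterministic per seed); grid search
rotates each fold as validation, averages the truncated AUC, and breaks
ties toward the smallest (α, γ) so the result is invariant to grid order.
Failed fits become NaN cells rather than aborting the grid.

The robustness protocol perturbs the gene network by deleting
⌊delete_frac·E⌋ existing edges and adding ⌊add_frac·E⌋ absent edges
(E = original edge count, weight 1 for added edges), uniformly and
deterministically per seed; the standard settings are 10%/20% deletion
with matched addition, repeated over seeds and summarized as
best/worst/median.

## Synthetic benchmarks

The generator plants K modules: genes get Bernoulli edges with probability
p_within inside a module and p_between across (binary, sparse); phenotype
similarity is module-membership agreement plus clipped symmetric Gaussian
noise with unit diagonal (dense, non-negative); each phenotype draws
max(1, Poisson(1.1)) genes from its own module. A singleton fraction of
phenotypes has *all* associations held out; further random pairs are held
out (never reducing a non-singleton phenotype to zero training genes)
until the holdout fraction is met. Training-network corruption reuses the
perturbation operator; the clean network and module labels stay in the
truth record. Defaults: 300 genes, 200 phenotypes, 10 modules,
p_within = 0.3, p_between = 0.01, noise sd 0.1, 10% singletons, 20%
holdout.

What this emulates: the extreme label sparsity (≈1.1–1.4 genes per
phenotype, mostly single-gene), PPI sparsity, dense noisy phenotype
similarity, and the singleton-query regime. What it does not: realistic
degree distributions (BioGRID is heavy-tailed, the planted-partition model
is not), text-mining-specific similarity artifacts, and OMIM-scale
dimensions. Passing benchmark studies therefore demonstrate the mechanics
and relative behavior of the methods under controlled noise, not absolute
performance on curated clinical data.

Problem sizes in the shipped studies — 300×200 benchmarks, 20 seeds for the
noise-robustness comparison, 5 seeds for the singleton study, a 50×40
instance for solver convergence — were chosen so the full suite and the
reproduction script each run in well under a minute of compute per study
while keeping the comparisons stable across seeds.

## Known limitations

* Convergence of the alternating scheme is only guaranteed in the convex
  regime α·ρ(Sᵢ) < 1; outside it the solver is a fixed-point iteration that
  may oscillate (detected and reported via the trace, and excluded by the
  convergence-filtered model selection).
* The noise-benefit of network learning on the synthetic benchmark is
  modest: the planted phenotype-similarity network is clean and highly
  informative, so tuned models often select γ = 0. The robustness claim
  verified here is the conservative one — validation-tuned learning never
  does worse than no learning (median over seeds).
* Learned S₁, S₂ are dense (γYYᵀ has no sparsity), so memory is O(n²+m²);
  fine at desk scale, a real-data run at n ≈ 20k would need low-rank or
  blocked handling, which is out of scope.
* No significance machinery is attached to metric differences; per-query
  values are exposed so users can run their own tests.
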