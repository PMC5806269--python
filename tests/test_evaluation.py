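"""Ranking metrics against brute-force oracles, CV plans, grid search,
holdout evaluation and network perturbation."""

import itertools

import numpy as np
import pytest

from idlp import (
    AssociationMatrix,
    IndexedNetwork,
    ScoreMatrix,
    ValidationError,
    auc_at_fp,
    evaluate_holdout,
    grid_search,
    make_cv_plan,
    perturb_network,
    precision_recall_at_k,
)


# ---------------------------------------------------------------------------
# Brute-force oracles: literal walks over a labelled ranking
# ---------------------------------------------------------------------------


def oracle_auc(labels, k):
    """Walk the ranking; TP(f) = positives seen before the f-th negative."""
    total = 0
    n_pos = sum(labels)
    f = 0
    seen_pos = 0
    for lab in labels:
        if lab:
            seen_pos += 1
        else:
            f += 1
            total += seen_pos
            if f == k:
                break
    return total / (k * n_pos)


def oracle_precision_recall(labels, k):
    tp = sum(labels[:k])
    return tp / k, tp / sum(labels)


def all_label_patterns(max_n=8):
    for n in range(2, max_n + 1):
        for pattern in itertools.product((0, 1), repeat=n):
            yield pattern


class TestAucAtFp:
    def test_perfect_ranking_scores_one(self):
        ranked = ["a", "b", "c", "d", "e"]
        assert auc_at_fp(ranked, {"a", "b"}, k=3) == 1.0

    def test_all_positives_below_k_negatives_scores_zero(self):
        ranked = ["n1", "n2", "n3", "p"]
        assert auc_at_fp(ranked, {"p"}, k=3) == 0.0

    def test_single_positive_at_rank_two(self):
        # TP(1) = 0, TP(2) = 1 => (0+1)/(2*1) = 0.5
        assert auc_at_fp(["n1", "p", "n2", "n3"], {"p"}, k=2) == 0.5

    def test_empty_positives_rejected(self):
        with pytest.raises(ValidationError):
            auc_at_fp(["a", "b"], set(), k=1)

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ValidationError):
            auc_at_fp(["p", "n"], {"p"}, k=2)

    def test_matches_oracle_on_all_patterns_up_to_8(self):
        """Exhaustive check over every labelled ranking of <= 8 items."""
        for pattern in all_label_patterns(8):
            n_pos = sum(pattern)
            n_neg = len(pattern) - n_pos
            if n_pos == 0 or n_neg == 0:
                continue
            items = [f"x{i}" for i in range(len(pattern))]
            pos = {it for it, lab in zip(items, pattern) if lab}
            for k in range(1, n_neg + 1):
                assert auc_at_fp(items, pos, k) == oracle_auc(pattern, k)

    def test_monotone_when_positive_moves_up(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 10))
            labels = list((rng.random(n) < 0.4).astype(int))
            if sum(labels) == 0 or sum(labels) >= n - 1:
                continue
            k = int(rng.integers(1, n - sum(labels) + 1))
            items = [f"x{i}" for i in range(n)]
            pos = {it for it, lab in zip(items, labels) if lab}
            base = auc_at_fp(items, pos, k)
            # swap a positive one rank up past a negative
            for i in range(1, n):
                if labels[i] == 1 and labels[i - 1] == 0:
                    swapped = items.copy()
                    swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
                    assert auc_at_fp(swapped, pos, k) >= base
                    break


class TestPrecisionRecall:
    def test_single_query_hit_at_one(self):
        table = precision_recall_at_k({"q": ["p", "n"]}, {"q": {"p"}}, [1])
        assert table.loc[0, "precision"] == 1.0
        assert table.loc[0, "recall"] == 1.0

    def test_miss_within_k(self):
        table = precision_recall_at_k(
            {"q": ["n1", "n2", "p"]}, {"q": {"p"}}, [2]
        )
        assert table.loc[0, "precision"] == 0.0
        assert table.loc[0, "recall"] == 0.0

    def test_mean_over_two_queries(self):
        # positives at ranks 1 and 4, k=3: precision (1/3+0)/2, recall (1+0)/2
        rankings = {
            "q1": ["p1", "n", "n", "n"],
            "q2": ["n", "n", "n", "p2"],
        }
        positives = {"q1": {"p1"}, "q2": {"p2"}}
        table = precision_recall_at_k(rankings, positives, [3])
        assert table.loc[0, "precision"] == pytest.approx(1 / 6)
        assert table.loc[0, "recall"] == pytest.approx(0.5)

    def test_matches_oracle_on_all_patterns_up_to_8(self):
        for pattern in all_label_patterns(8):
            if sum(pattern) == 0:
                continue
            items = [f"x{i}" for i in range(len(pattern))]
            pos = {it for it, lab in zip(items, pattern) if lab}
            for k in (1, 2, 5, 8):
                table = precision_recall_at_k({"q": items}, {"q": pos}, [k])
                p_exp, r_exp = oracle_precision_recall(pattern, k)
                assert table.loc[0, "precision"] == pytest.approx(p_exp)
                assert table.loc[0, "recall"] == pytest.approx(r_exp)


class TestCVPlan:
    def make_assoc(self, n_pairs=10):
        genes = [f"g{i}" for i in range(n_pairs)]
        Y = np.eye(n_pairs)
        return AssociationMatrix(genes, [f"p{i}" for i in range(n_pairs)], Y)

    def test_equal_fold_sizes(self):
        plan = make_cv_plan(self.make_assoc(10), n_folds=5, seed=0)
        sizes = [len(plan.val_pairs(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_deterministic_given_seed(self):
        a = self.make_assoc(10)
        p1 = make_cv_plan(a, 5, seed=7)
        p2 = make_cv_plan(a, 5, seed=7)
        assert np.array_equal(p1.fold_of, p2.fold_of)

    def test_partition_property(self):
        a = self.make_assoc(11)
        plan = make_cv_plan(a, 3, seed=1)
        folds = [set(plan.val_pairs(f)) for f in range(3)]
        assert set().union(*folds) == set(a.pairs())
        for f1, f2 in itertools.combinations(folds, 2):
            assert not f1 & f2

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValidationError):
            make_cv_plan(self.make_assoc(10), n_folds=1, seed=0)


class TestGridSearch:
    @staticmethod
    def deterministic_fit_fn(alpha, gamma):
        """Scorer whose quality improves with alpha (independent oracle)."""

        def scorer(train):
            rng = np.random.default_rng(123)
            noise = rng.random(train.values.shape)
            return ScoreMatrix(
                train.gene_ids,
                train.phenotype_ids,
                alpha * train.values + 0.5 * noise,
            )

        return scorer

    def make_assoc(self):
        rng = np.random.default_rng(5)
        Y = (rng.random((20, 10)) < 0.2).astype(float)
        Y[0, 0] = 1.0
        return AssociationMatrix(
            [f"g{i}" for i in range(20)], [f"p{j}" for j in range(10)], Y
        )

    def test_single_cell_grid(self):
        a = self.make_assoc()
        plan = make_cv_plan(a, 2, seed=0)
        best, table = grid_search(
            self.deterministic_fit_fn, a, plan, [0.5], [1.0], metric="auc5"
        )
        assert best["alpha"] == 0.5 and best["gamma"] == 1.0
        assert len(table) == 1

    def test_grid_order_invariance(self):
        a = self.make_assoc()
        plan = make_cv_plan(a, 2, seed=0)
        best1, _ = grid_search(
            self.deterministic_fit_fn, a, plan, [0.1, 0.9], [1, 2], "auc5"
        )
        best2, _ = grid_search(
            self.deterministic_fit_fn, a, plan, [0.9, 0.1], [2, 1], "auc5"
        )
        assert best1 == best2

    def test_failing_cell_recorded_as_nan(self):
        a = self.make_assoc()
        plan = make_cv_plan(a, 2, seed=0)

        def fit_fn(alpha, gamma):
            if gamma == 99:
                raise RuntimeError("boom")
            return self.deterministic_fit_fn(alpha, gamma)

        best, table = grid_search(fit_fn, a, plan, [0.5], [1.0, 99.0], "auc5")
        assert best["gamma"] == 1.0
        assert np.isnan(table.loc[table.gamma == 99.0, "auc5"]).all()

    def test_full_grid_enumerates_all_combinations(self):
        a = self.make_assoc()
        plan = make_cv_plan(a, 2, seed=0)
        alphas = [0.0001, 0.001, 0.01, 0.1, 1.0]
        gammas = [1, 10, 100, 1000, 10000]
        _, table = grid_search(
            self.deterministic_fit_fn, a, plan, alphas, gammas, "auc5"
        )
        assert len(table) == 25


class TestEvaluateHoldout:
    def setup_case(self):
        genes = [f"g{i}" for i in range(12)]
        phenos = ["p0", "p1", "p2"]
        Y = np.zeros((12, 3))
        Y[0, 0] = 1.0  # p0 has a training gene; p1/p2 are singletons
        train = AssociationMatrix(genes, phenos, Y)

        def fit_fn(train_assoc):
            rng = np.random.default_rng(0)
            vals = rng.random((12, 3)) * 0.1
            vals[1, 0] = 1.0  # test gene of p0 ranked first
            vals[2, 1] = 1.0  # test gene of p1 ranked first
            return ScoreMatrix(genes, phenos, vals)

        test_pairs = [("g1", "p0"), ("g2", "p1")]
        return fit_fn, train, test_pairs

    def test_ranks_and_subsets(self):
        fit_fn, train, test_pairs = self.setup_case()
        report = evaluate_holdout(fit_fn, train, test_pairs, cutoffs=(5,),
                                  k_values=(1,))
        assert set(report.per_query["rank"]) == {1}
        assert report.n_queries == 2
        assert report.n_singleton_queries == 1
        assert report.auc_at[5] == 1.0
        assert report.auc_at_singleton[5] == 1.0
        assert report.precision_at[1] == 1.0

    def test_training_gene_excluded_from_candidates(self):
        fit_fn, train, test_pairs = self.setup_case()
        report = evaluate_holdout(fit_fn, train, test_pairs, cutoffs=(5,),
                                  k_values=(1,))
        p0_rows = report.per_query[report.per_query.phenotype_id == "p0"]
        assert "g0" not in set(p0_rows.gene_id)

    def test_overlapping_test_pair_rejected(self):
        fit_fn, train, _ = self.setup_case()
        with pytest.raises(ValidationError, match="overlap"):
            evaluate_holdout(fit_fn, train, [("g0", "p0")])

    def test_random_scorer_auc_matches_permutation_expectation(self):
        """Average truncated AUC of random rankings matches the exhaustive
        permutation mean on a 10-gene instance with 1 positive."""
        n, k = 10, 3
        # exhaustive: positive equally likely at each of n positions
        exact = np.mean(
            [oracle_auc([1 if i == pos else 0 for i in range(n)], k)
             for pos in range(n)]
        )
        rng = np.random.default_rng(0)
        items = [f"x{i}" for i in range(n)]
        sims = []
        for _ in range(4000):
            order = list(rng.permutation(items))
            sims.append(auc_at_fp(order, {"x0"}, k))
        assert np.mean(sims) == pytest.approx(exact, abs=0.01)


class TestPerturbNetwork:
    def ring(self, n=30):
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        return IndexedNetwork([f"g{i}" for i in range(n)], W)

    def test_noop(self):
        net = self.ring()
        out = perturb_network(net, 0.0, 0.0, seed=0)
        assert np.array_equal(out.weights, net.weights)

    def test_delete_all(self):
        net = self.ring()
        out = perturb_network(net, 1.0, 0.0, seed=0)
        assert out.n_edges() == 0

    def test_exact_counts(self):
        net = self.ring(100)  # 100 edges
        out = perturb_network(net, 0.1, 0.1, seed=3)
        assert out.n_edges() == 100
        survived = int(((net.weights > 0) & (out.weights > 0)).sum() / 2)
        assert survived == 90
        added = int(((net.weights == 0) & (out.weights > 0)).sum() / 2)
        assert added == 10

    def test_reproducible_bit_for_bit(self):
        net = self.ring()
        a = perturb_network(net, 0.2, 0.2, seed=9)
        b = perturb_network(net, 0.2, 0.2, seed=9)
        assert np.array_equal(a.weights, b.weights)

    def test_symmetry_preserved(self):
        net = self.ring()
        out = perturb_network(net, 0.3, 0.5, seed=1)
        assert np.array_equal(out.weights, out.weights.T)

    def test_too_many_additions_rejected(self):
        net = self.ring(4)
        with pytest.raises(ValidationError):
            perturb_network(net, 0.0, 10.0, seed=0)
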