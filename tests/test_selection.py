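import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from amfeskit.selection import (
    AmfesSelector,
    assign_gene_indices,
    choose_pstar,
    compute_r,
    converged,
    feature_weight,
    fit_svm,
    make_artificial_genes,
    plan_splits,
    rank_stage,
    ranking_score,
    recursive_rank,
    select_genes,
)
from amfeskit.synthetic import SyntheticSpec, generate_dataset


class TestComputeR:
    @pytest.mark.parametrize("n,expected", [(28, 18), (500, 5), (5, 100), (40, 13)])
    def test_heuristic_values(self, n, expected):
        assert compute_r(n) == expected

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            compute_r(1)


class TestPlanSplits:
    def test_stratified_counts_14v14(self):
        labels = np.array([1] * 14 + [0] * 14)
        pairs = plan_splits(labels, 0.3, rng=0)
        assert len(pairs) == compute_r(28)
        for train, val in pairs:
            assert sorted(np.concatenate([train, val])) == list(range(28))
            val_labels = labels[val]
            assert set(val_labels) == {0, 1}
            assert (val_labels == 1).sum() in (4, 5)
            assert (val_labels == 0).sum() in (4, 5)

    def test_seeded_plans_reproduce(self):
        labels = np.array([1] * 10 + [0] * 12)
        a = plan_splits(labels, 0.3, rng=5)
        b = plan_splits(labels, 0.3, rng=5)
        assert all(
            np.array_equal(t1, t2) and np.array_equal(v1, v2)
            for (t1, v1), (t2, v2) in zip(a, b)
        )

    def test_bad_fraction_and_tiny_class_error(self):
        labels = np.array([1] * 10 + [0] * 10)
        with pytest.raises(ValueError):
            plan_splits(labels, 0.6)
        with pytest.raises(ValueError):
            plan_splits(np.array([1, 0, 0, 0]), 0.3)


def _dual_objective_bruteforce(fit):
    a = fit.dual_coefficients
    sv = fit.support_vectors
    total = 0.0
    for i in range(len(a)):
        for j in range(len(a)):
            total += a[i] * a[j] * float(sv[i] @ sv[j])
    return 0.5 * total


class TestFitSvm:
    def test_separable_points_classified(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array([0, 1])
        fit = fit_svm(X, y)
        assert np.array_equal((fit.decision_function(X) > 0).astype(int), y)

    def test_objective_matches_bruteforce_quadratic_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_svm(X, y, C=1.0)
        assert abs(fit.objective_value - _dual_objective_bruteforce(fit)) < 1e-6
        # ... and equals ½‖w‖² for the linear kernel
        assert abs(fit.objective_value - 0.5 * fit.primal_weights @ fit.primal_weights) < 1e-6

    def test_duplicated_feature_gets_equal_weight(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        X = np.column_stack([X, X[:, 0]])
        y = np.array([0, 1] * 4)
        fit = fit_svm(X, y)
        assert abs(fit.primal_weights[0] - fit.primal_weights[2]) < 1e-8

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_svm(np.eye(3), np.ones(3, dtype=int))


class TestFeatureWeight:
    @pytest.fixture
    def toy_fit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])
        return fit_svm(X, y)

    def test_matches_explicit_objective_recomputation(self, toy_fit):
        for g in range(4):
            a = toy_fit.dual_coefficients
            sv = np.delete(toy_fit.support_vectors, g, axis=1)
            dropped = 0.0
            for i in range(len(a)):
                for j in range(len(a)):
                    dropped += a[i] * a[j] * float(sv[i] @ sv[j])
            expected = toy_fit.objective_value - 0.5 * dropped
            assert abs(feature_weight(toy_fit, g) - expected) < 1e-8

    def test_linear_kernel_half_w_squared_identity(self, toy_fit):
        for g in range(4):
            assert abs(
                feature_weight(toy_fit, g) - 0.5 * toy_fit.primal_weights[g] ** 2
            ) < 1e-8

    def test_zero_feature_has_zero_weight(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        X[:, 1] = 0.0
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_svm(X, y)
        assert abs(feature_weight(fit, 1)) < 1e-12

    def test_identical_features_identical_weights(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        X = np.column_stack([X, X[:, 1]])
        y = np.array([0, 1] * 4)
        fit = fit_svm(X, y)
        assert abs(feature_weight(fit, 1) - feature_weight(fit, 3 - 1)) < 1e-10
        assert abs(feature_weight(fit, 1) - feature_weight(fit, 2)) < 1e-10

    def test_unknown_feature_errors(self, toy_fit):
        with pytest.raises(KeyError):
            feature_weight(toy_fit, 99)


class TestRankingScore:
    def test_average_over_containing_subsets(self):
        subsets = [np.array([0, 1]), np.array([0, 2]), np.array([1, 2])]
        weights = [np.array([0.5, 1.0]), np.array([0.3, 2.0]), np.array([4.0, 5.0])]
        assert ranking_score(subsets, weights, 0, 3) == pytest.approx(0.4)

    def test_single_subset_is_identity(self):
        assert ranking_score([np.array([7])], [np.array([1.25])], 7, 8) == 1.25

    def test_matches_bruteforce_indicator_table(self):
        rng = np.random.default_rng(5)
        n_genes, n_subsets = 5, 3
        subsets = [rng.choice(n_genes, size=3, replace=False) for _ in range(n_subsets)]
        weights = [rng.random(3) for _ in range(n_subsets)]
        for g in range(n_genes):
            num = sum(
                w[list(s).index(g)] for s, w in zip(subsets, weights) if g in s
            )
            den = sum(1 for s in subsets if g in s)
            if den == 0:
                with pytest.raises(ValueError):
                    ranking_score(subsets, weights, g, n_genes)
            else:
                assert ranking_score(subsets, weights, g, n_genes) == pytest.approx(
                    num / den, abs=1e-12
                )


class TestConverged:
    def test_identical_vectors_converge(self):
        assert converged(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_orthogonal_unit_vectors_do_not(self):
        assert not converged(np.array([1.0, 0.0]), np.array([0.0, 1.0]))

    def test_small_relative_change_converges(self):
        assert converged(np.array([10.0, 10.0]), np.array([10.1, 10.0]))

    def test_zero_previous_norm_reports_not_converged(self):
        assert not converged(np.zeros(3), np.ones(3))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            converged(np.ones(2), np.ones(3))


class TestRankStage:
    def test_two_gene_stage_ranks_both(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = np.array([0, 1] * 6)
        order, scores = rank_stage(X, y, np.array([0, 1]), np.random.default_rng(0))
        assert sorted(order) == [0, 1]
        assert len(scores) == 2

    def test_planted_strong_gene_ranks_first(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 20))
            y = np.array([1] * 15 + [0] * 15)
            X[:15, 0] += 3.0
            Xs = (X - X.mean(0)) / X.std(0)
            order, _ = rank_stage(Xs, y, np.arange(20), np.random.default_rng(seed))
            hits += order[0] == 0
        assert hits >= 4

    def test_fixed_seed_reproduces_order(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(16, 10))
        y = np.array([0, 1] * 8)
        a, _ = rank_stage(X, y, np.arange(10), np.random.default_rng(3))
        b, _ = rank_stage(X, y, np.arange(10), np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestRecursiveRank:
    def test_stage_sizes_follow_ceil_halving(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(14, 8))
        y = np.array([0, 1] * 7)
        _, _, sizes = recursive_rank(X, y, np.arange(8), np.random.default_rng(0))
        assert sizes == [8, 4, 3]

    @pytest.mark.parametrize("k,expected", [
        (3, [3]), (20, [20, 10, 5, 3]), (1000, [1000, 500, 250, 125, 63, 32, 16, 8, 4, 3]),
    ])
    def test_stage_size_schedule(self, k, expected):
        sizes = [k]
        while sizes[-1] > 3:
            sizes.append(max(3, math.ceil(sizes[-1] / 2)))
        assert sizes == expected

    def test_output_is_permutation_of_input(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(14, 17))
        y = np.array([0, 1] * 7)
        order, theta, _ = recursive_rank(X, y, np.arange(17), np.random.default_rng(1))
        assert sorted(order) == list(range(17))
        assert len(theta) == 17

    def test_three_genes_base_case(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        order, _, sizes = recursive_rank(X, y, np.arange(3), np.random.default_rng(2))
        assert sorted(order) == [0, 1, 2]
        assert sizes == [3]


class TestArtificialGenes:
    def test_count_doubles_the_matrix(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(100, 20))
        aug, flags = make_artificial_genes(values, 100, np.random.default_rng(0))
        assert aug.shape == (200, 20)
        assert flags.sum() == 100 and not flags[:100].any()

    def test_probe_marginals_match_some_original_gene(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(10, 8))
        aug, flags = make_artificial_genes(values, 5, np.random.default_rng(1))
        originals = {tuple(np.sort(row)) for row in values}
        for probe in aug[flags]:
            assert tuple(np.sort(probe)) in originals

    def test_probes_lose_class_association(self, planted_dataset):
        """Probe |Δmean| is stochastically below informative genes' (rank-sum)."""
        ds, truth, _ = planted_dataset
        aug, flags = make_artificial_genes(ds.values, ds.n_genes,
                                           np.random.default_rng(2))
        diffs = np.abs(
            aug[:, ds.labels == 1].mean(axis=1) - aug[:, ds.labels == 0].mean(axis=1)
        )
        truth_rows = [ds.gene_ids.index(g) for g in truth]
        stat = stats.mannwhitneyu(diffs[truth_rows], diffs[flags], alternative="greater")
        assert stat.pvalue < 0.01


class TestGeneIndices:
    def test_extremes_and_arithmetic(self):
        #                      g_top  p p p p p p p p p p  g_bottom  g_mid at 0.4
        order = ["a"] + [f"p{i}" for i in range(4)] + ["mid"] + [f"p{i}" for i in range(4, 10)] + ["z"]
        flags = np.array([s.startswith("p") for s in order])
        idx = assign_gene_indices(order, flags)
        assert idx["a"] == 0.0
        assert idx["mid"] == 0.4
        assert idx["z"] == 1.0

    def test_no_probes_errors(self):
        with pytest.raises(ValueError):
            assign_gene_indices(["a", "b"], np.array([False, False]))


class TestChoosePstar:
    def test_first_candidate_beating_baseline(self):
        assert choose_pstar([0.1, 0.2, 0.3], [0.6, 0.9, 0.9], 0.8) == 0.2

    def test_fallback_max_accuracy_smaller_p(self):
        assert choose_pstar([0.1, 0.2, 0.3], [0.7, 0.75, 0.75], 0.8) == 0.2

    def test_single_winning_candidate(self):
        assert choose_pstar([0.05], [0.9], 0.5) == 0.05

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            choose_pstar([], [], 0.5)


class TestSelectGenes:
    def test_recovers_planted_genes(self, planted_dataset):
        ds, truth, _ = planted_dataset
        res = select_genes(ds, seed=0)
        selected = set(res.panel.gene_ids)
        recall = len(selected & set(truth)) / len(truth)
        assert len(selected) < ds.n_genes * 0.25
        assert recall >= 0.5
        assert res.r == compute_r(ds.n_samples)

    def test_selected_set_matches_index_cutoff(self, planted_dataset):
        ds, _, _ = planted_dataset
        res = select_genes(ds, seed=1)
        by_cutoff = {g for g, v in res.gene_indices.items() if v <= res.p_star}
        assert set(res.panel.gene_ids) == by_cutoff

    def test_gene_index_monotone_along_ranking(self, planted_dataset):
        ds, _, _ = planted_dataset
        res = select_genes(ds, seed=1)
        idx = [res.gene_indices[g] for g in res.ranking.original_order]
        assert all(a <= b for a, b in zip(idx, idx[1:]))

    def test_deterministic_given_seed(self, planted_dataset):
        ds, _, _ = planted_dataset
        a = select_genes(ds, seed=3)
        b = select_genes(ds, seed=3)
        assert a.panel.gene_ids == b.panel.gene_ids
        assert a.p_star == b.p_star
        assert a.candidate_accuracies == b.candidate_accuracies

    def test_null_effect_negative_control_completes(self):
        spec = SyntheticSpec(
            n_genes=80, n_informative=0, n_samples_per_class=10,
            effect_size=0.0, seed=13,
        )
        ds, truth, _ = generate_dataset(spec)
        res = select_genes(ds, seed=13)
        assert truth == []
        assert 0 <= len(res.panel) <= ds.n_genes


class TestSklearnInterface:
    def test_clone_and_params_round_trip(self):
        sel = AmfesSelector(C=2.0, random_state=1)
        cloned = clone(sel)
        assert cloned.get_params()["C"] == 2.0
        cloned.set_params(C=0.5)
        assert cloned.C == 0.5

    def test_fit_transform_keeps_selected_columns(self, planted_dataset):
        ds, _, _ = planted_dataset
        sel = AmfesSelector(random_state=0, n_splits=5)
        X = ds.values.T
        Xt = sel.fit(X, ds.labels).transform(X)
        assert Xt.shape == (ds.n_samples, int(sel.support_.sum()))
        assert np.array_equal(Xt, X[:, sel.support_])
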