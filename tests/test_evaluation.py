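import numpy as np
import pytest

from lpidf.evaluation import (
    ConfusionCounts,
    PipelineConfig,
    compute_auc,
    compute_aupr,
    compute_point_metrics,
    featurize_dataset,
    make_cv_splits,
    pair_features,
    rank_unknown_pairs,
    run_cv_experiment,
    sample_negatives,
    top_n_true_fraction,
)
from lpidf.cascade_forest import fit_cascade
from lpidf.io_data import InteractionMatrix, ValidationError, count_unknown_pairs
from tests.conftest import auc_oracle, aupr_oracle, light_pipeline


def random_matrix(n, m, density, seed):
    rng = np.random.default_rng(seed)
    Y = (rng.random((n, m)) < density).astype(int)
    # ensure at least one positive and one zero
    Y[0, 0] = 1
    Y[-1, -1] = 0
    return InteractionMatrix(
        [f"l{i}" for i in range(n)], [f"p{j}" for j in range(m)], Y
    )


class TestSampleNegatives:
    def test_disjoint_from_positives_and_exact_count(self):
        Y = random_matrix(10, 6, 0.2, 1)
        pos = set(Y.positive_pairs())
        neg = sample_negatives(Y, len(pos), seed=0)
        assert len(neg) == len(pos)
        assert len(set(neg)) == len(neg)
        assert not set(neg) & pos

    def test_reproducible_under_seed(self):
        Y = random_matrix(10, 6, 0.2, 1)
        assert sample_negatives(Y, 5, seed=3) == sample_negatives(Y, 5, seed=3)

    def test_all_known_matrix_rejected(self):
        Y = InteractionMatrix(["l1", "l2"], ["p1", "p2"], np.ones((2, 2)))
        with pytest.raises(ValidationError, match="deficit"):
            sample_negatives(Y, 1, seed=0)

    def test_exclude_respected(self):
        Y = random_matrix(4, 4, 0.0, 0)
        Y.Y[:] = 0
        exclude = {(0, 0), (0, 1)}
        neg = sample_negatives(Y, 14, exclude=exclude, seed=0)
        assert not set(neg) & exclude

    def test_row_restriction(self):
        Y = random_matrix(6, 5, 0.1, 2)
        neg = sample_negatives(Y, 3, seed=1, rows=[2, 3])
        assert all(r in (2, 3) for r, _ in neg)


class TestMakeCVSplits:
    def test_cv1_partitions_rows_exhaustively(self):
        Y = random_matrix(10, 8, 0.25, 3)
        splits = make_cv_splits(Y, "cv1", n_folds=5, seed=0)
        test_rows = [sorted({r for r, _, _ in s.test_pairs}) for s in splits]
        assert all(len(rows) == 2 for rows in test_rows)
        assert sorted(r for rows in test_rows for r in rows) == list(range(10))

    def test_cv1_cold_start_no_test_row_in_training(self):
        Y = random_matrix(12, 8, 0.25, 4)
        for s in make_cv_splits(Y, "cv1", 4, seed=1):
            train_rows = {r for r, _, _ in s.train_pairs}
            test_rows = {r for r, _, _ in s.test_pairs}
            assert not train_rows & test_rows

    def test_cv2_cold_start_no_test_column_in_training(self):
        Y = random_matrix(8, 10, 0.25, 5)
        for s in make_cv_splits(Y, "cv2", 4, seed=1):
            train_cols = {c for _, c, _ in s.train_pairs}
            test_cols = {c for _, c, _ in s.test_pairs}
            assert not train_cols & test_cols

    def test_cv3_fold_sizes_balanced_pool(self):
        # 50 positives -> pool of 100 labeled pairs -> 20 test pairs per fold
        rng = np.random.default_rng(6)
        Y = np.zeros((25, 8), dtype=int)
        ones = rng.choice(200, size=50, replace=False)
        Y.flat[ones] = 1
        m = InteractionMatrix(
            [f"l{i}" for i in range(25)], [f"p{j}" for j in range(8)], Y
        )
        splits = make_cv_splits(m, "cv3", 5, seed=0)
        assert all(len(s.test_pairs) == 20 for s in splits)
        all_test = [tuple(t) for s in splits for t in s.test_pairs]
        assert len(set(all_test)) == 100

    def test_balanced_labels_in_every_fold_set(self):
        Y = random_matrix(20, 10, 0.25, 7)
        for scheme in ("cv1", "cv2", "cv3"):
            for s in make_cv_splits(Y, scheme, 4, seed=2):
                tr = [lab for _, _, lab in s.train_pairs]
                te = [lab for _, _, lab in s.test_pairs]
                assert sum(tr) * 2 == len(tr)
                assert sum(te) * 2 == len(te)

    def test_train_test_disjoint(self):
        Y = random_matrix(15, 10, 0.25, 8)
        for scheme in ("cv1", "cv2", "cv3"):
            for s in make_cv_splits(Y, scheme, 3, seed=3):
                assert not {(r, c) for r, c, _ in s.train_pairs} & {
                    (r, c) for r, c, _ in s.test_pairs
                }

    def test_unknown_scheme_rejected(self):
        Y = random_matrix(6, 6, 0.3, 9)
        with pytest.raises(ValueError):
            make_cv_splits(Y, "cv4", 3, seed=0)

    def test_too_few_rows_rejected(self):
        Y = random_matrix(3, 6, 0.4, 10)
        with pytest.raises(ValidationError):
            make_cv_splits(Y, "cv1", 5, seed=0)


class TestPointMetrics:
    def test_forced_arithmetic(self):
        m = compute_point_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-4)

    def test_degenerate_denominators_warn_and_zero(self):
        with pytest.warns(UserWarning):
            m = compute_point_metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
        assert m["precision"] == 0.0 and m["recall"] == 0.0
        assert m["accuracy"] == 1.0

    def test_perfect_prediction(self):
        m = compute_point_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert all(v == 1.0 for v in m.values())


class TestRankingMetrics:
    def test_auc_perfect_separation(self):
        assert compute_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_auc_all_ties_is_half(self):
        assert compute_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_auc_enumerated_pairs(self):
        # pairs (0.9 vs 0.8, 0.9 vs 0.1, 0.4 vs 0.8, 0.4 vs 0.1): 3 wins of 4
        assert compute_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]) == pytest.approx(0.75)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_auc([1, 1], [0.5, 0.6])

    def test_aupr_perfect_separation(self):
        assert compute_aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_aupr_all_ties_equals_prevalence(self):
        assert compute_aupr([1, 0, 0, 0], [0.5] * 4) == pytest.approx(0.25)

    def test_aupr_matches_threshold_sweep(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.4, 0.1]
        assert compute_aupr(labels, scores) == pytest.approx(
            aupr_oracle(labels, scores), abs=1e-12
        )

    def test_aupr_without_positives_rejected(self):
        with pytest.raises(ValidationError):
            compute_aupr([0, 0], [0.5, 0.6])

    def test_both_metrics_match_oracles_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)  # induce ties
            assert compute_auc(labels, scores) == pytest.approx(
                auc_oracle(labels, scores), abs=1e-12
            )
            assert compute_aupr(labels, scores) == pytest.approx(
                aupr_oracle(labels, scores), abs=1e-12
            )


class TestRunCVExperiment:
    def test_report_bookkeeping_and_determinism(self, tiny_dataset):
        cfg = light_pipeline(seed=5)
        r1 = run_cv_experiment(tiny_dataset, "cv3", repeats=2, config=cfg)
        assert r1.n_repeats == 2
        assert set(r1.mean) == set(r1.METRICS)
        assert all(0 <= r1.mean[m] <= 1 for m in r1.METRICS)
        r2 = run_cv_experiment(tiny_dataset, "cv3", repeats=2, config=cfg)
        assert r1.per_repeat == r2.per_repeat

    def test_summary_table_shape(self, tiny_dataset):
        cfg = light_pipeline(seed=5)
        rep = run_cv_experiment(tiny_dataset, "cv3", repeats=2, config=cfg)
        df = rep.summary()
        assert list(df.index) == ["repeat_0", "repeat_1", "mean", "std"]
        assert list(df.columns) == list(rep.METRICS)

    def test_cv1_feature_substitution_changes_scores(self, tiny_dataset):
        """Replacing the test rows' lncRNA features with training-row copies
        must change the scores: guards against index bugs that silently leak
        training features into cold-start evaluation."""
        cfg = light_pipeline(seed=5)
        L, P = featurize_dataset(tiny_dataset, cfg)
        split = make_cv_splits(tiny_dataset.interactions, "cv1", 2, seed=1)[0]
        X_tr = pair_features(L, P, [(r, c) for r, c, _ in split.train_pairs])
        y_tr = np.array([lab for _, _, lab in split.train_pairs])
        model = fit_cascade(X_tr, y_tr, cfg.cascade)

        from lpidf.cascade_forest import predict_proba

        test_pairs = [(r, c) for r, c, _ in split.test_pairs]
        scores = predict_proba(model, pair_features(L, P, test_pairs))
        train_rows = sorted({r for r, _, _ in split.train_pairs})
        L_sub = L.copy()
        for r in {r for r, _ in test_pairs}:
            L_sub[r] = L[train_rows[r % len(train_rows)]]
        scores_sub = predict_proba(model, pair_features(L_sub, P, test_pairs))
        assert not np.allclose(scores, scores_sub)


class TestRanking:
    @pytest.fixture(scope="class")
    def fitted(self, tiny_dataset):
        cfg = light_pipeline(seed=2)
        L, P = featurize_dataset(tiny_dataset, cfg)
        Y = tiny_dataset.interactions
        pos = Y.positive_pairs()
        neg = sample_negatives(Y, len(pos), seed=2)
        X = pair_features(L, P, pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        return fit_cascade(X, y, cfg.cascade), L, P

    def test_ranking_covers_all_unknown_pairs(self, fitted, tiny_dataset):
        model, L, P = fitted
        ranked = rank_unknown_pairs(model, tiny_dataset, L, P)
        assert len(ranked) == count_unknown_pairs(tiny_dataset.interactions)
        assert [r for _, _, _, r in ranked] == list(range(1, len(ranked) + 1))
        scores = [s for _, _, s, _ in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_restrict_to_one_lncrna(self, fitted, tiny_dataset):
        model, L, P = fitted
        lid = tiny_dataset.interactions.lncrna_ids[0]
        ranked = rank_unknown_pairs(model, tiny_dataset, L, P, restrict=lid)
        assert all(entry[0] == lid for entry in ranked)
        row = tiny_dataset.interactions.Y[0]
        assert len(ranked) == int((row == 0).sum())

    def test_unknown_restrict_id_rejected(self, fitted, tiny_dataset):
        model, L, P = fitted
        with pytest.raises(ValidationError):
            rank_unknown_pairs(model, tiny_dataset, L, P, restrict="nope")

    def test_all_known_matrix_gives_empty_ranking(self, fitted, tiny_dataset):
        from lpidf.io_data import Dataset, InteractionMatrix

        model, L, P = fitted
        Y = tiny_dataset.interactions
        full = InteractionMatrix(
            Y.lncrna_ids, Y.protein_ids, np.ones_like(Y.Y)
        )
        ds = Dataset(tiny_dataset.lncrnas, tiny_dataset.proteins, full)
        assert rank_unknown_pairs(model, ds, L, P) == []

    def test_equal_scores_tie_broken_by_id(self):
        ranked = [("l2", "p1", 0.7, 1), ("l1", "p9", 0.7, 2)]
        # the contract is lexicographic order on (lncrna_id, protein_id) at
        # equal score; rebuild through the sort used by rank_unknown_pairs
        entries = [(lid, pid, s) for lid, pid, s, _ in ranked]
        entries.sort(key=lambda e: (-e[2], e[0], e[1]))
        assert [e[0] for e in entries] == ["l1", "l2"]


class TestTopNTrueFraction:
    RANKED = [(f"l{i}", "p0", 1.0 - i / 100, i + 1) for i in range(50)]

    def test_all_true(self):
        truth = {(f"l{i}", "p0"): 1 for i in range(50)}
        assert top_n_true_fraction(self.RANKED, truth, 10) == 100.0

    def test_none_true(self):
        assert top_n_true_fraction(self.RANKED, {}, 10) == 0.0

    def test_partial_fraction(self):
        truth = {(f"l{i}", "p0"): 1 for i in range(47)}
        assert top_n_true_fraction(self.RANKED, truth, 50) == pytest.approx(94.0)

    def test_cutoff_beyond_list_rejected(self):
        with pytest.raises(ValidationError):
            top_n_true_fraction(self.RANKED, {}, 51)
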