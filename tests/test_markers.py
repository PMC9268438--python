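"""Permutation importance, IV>0 selection, marker refit, external prediction."""

import dataclasses

import numpy as np
import pytest

from ginsengms import (
    ImportanceReport,
    SyntheticSpec,
    accuracy_from_pairs,
    generate_feature_table,
    load_published_test_pairs,
    load_published_training_pairs,
    normalize_zscore,
    permutation_importance,
    select_markers,
)
from ginsengms.markers import predict_external, refit_on_markers


class TestAccuracyFromPairs:
    def test_published_training_blocks(self):
        df = load_published_training_pairs()
        raw = list(zip(df.actual, df.recognized_raw))
        norm = list(zip(df.actual, df.recognized_normalized))
        assert len(raw) == 31
        assert accuracy_from_pairs(raw) == 83
        assert accuracy_from_pairs(norm) == 100

    def test_published_test_block(self):
        df = load_published_test_pairs()
        assert len(df) == 8
        assert accuracy_from_pairs(list(zip(df.actual, df.recognized))) == 100

    def test_truncation_not_rounding(self):
        # 26/31 = 83.87%; the convention truncates to 83
        pairs = [("a", "a")] * 26 + [("a", "b")] * 5
        assert accuracy_from_pairs(pairs) == 83

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_pairs([])


class TestPermutationImportance:
    def test_no_change_null(self):
        # a scorer that never moves yields importance exactly 0
        X = np.random.default_rng(0).normal(size=(12, 3))
        labels = ["A", "B", "C"] * 4
        rep = permutation_importance(
            X, labels, n_repeats=1, seed=0, scorer=lambda X_, l_: 0.75
        )
        np.testing.assert_array_equal(rep.importances, 0.0)
        assert list(rep.selected) == []

    def test_sole_informative_feature_dominates(self):
        rng = np.random.default_rng(2)
        n = 30
        labels = list(np.repeat(["A", "B", "C"], 10))
        X = rng.normal(size=(n, 5))
        X[:, 2] = np.repeat([0.0, 5.0, 10.0], 10) + rng.normal(scale=0.1, size=n)
        rep = permutation_importance(X, labels, C=1, gamma=0.1, n_repeats=20, seed=0)
        assert rep.importances[2] == pytest.approx(rep.baseline_score - 1 / 3, abs=0.15)
        noise = np.delete(rep.importances, 2)
        assert np.all(np.abs(noise) <= 0.1 + 1e-12)
        assert rep.ranking[0] == 2

    def test_label_independent_features_near_zero(self):
        # with labels independent of X the null importances are centred
        # at zero; their spread is set by the CV-accuracy sampling noise
        # at n=30 (sd ~ sqrt(1/3*2/3/30) ~ 0.09), so individual values
        # stay within ~2.5 sd while the per-seed mean stays close to 0
        imps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 8))
            labels = list(np.repeat(["A", "B", "C"], 10))
            rep = permutation_importance(X, labels, C=1, gamma=0.03, n_repeats=10, seed=seed)
            imps.append(rep.importances)
        allimp = np.concatenate(imps)
        assert np.abs(allimp).max() <= 0.25
        assert abs(allimp.mean()) <= 0.05

    def test_seed_reproducibility(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        a = permutation_importance(Z, labels, n_repeats=3, seed=9)
        b = permutation_importance(Z, labels, n_repeats=3, seed=9)
        np.testing.assert_array_equal(a.permuted_scores, b.permuted_scores)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_fast_path_matches_generic_scorer(self, strong_signal_zscores):
        # the Gram-updating fast path must agree with naive rescoring
        from ginsengms import cross_validate

        Z, labels, _ = strong_signal_zscores
        Z = Z[:, :12].copy()

        def naive(X, l):
            acc, _ = cross_validate(X, l, C=1, gamma=0.03, k=10, seed=4)
            return acc

        fast = permutation_importance(Z, labels, C=1, gamma=0.03, n_repeats=2, seed=4)
        slow = permutation_importance(Z, labels, n_repeats=2, seed=4, scorer=naive)
        np.testing.assert_allclose(fast.permuted_scores, slow.permuted_scores, atol=1e-12)

    def test_sum_aggregate_is_dimensioned_sum(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        Z = Z[:, :6].copy()
        mean_rep = permutation_importance(Z, labels, n_repeats=4, seed=0)
        sum_rep = permutation_importance(Z, labels, n_repeats=4, seed=0, aggregate="sum")
        np.testing.assert_allclose(
            sum_rep.importances,
            mean_rep.baseline_score - mean_rep.permuted_scores.sum(axis=1),
            atol=1e-12,
        )

    def test_invalid_repeats(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        with pytest.raises(ValueError):
            permutation_importance(Z, labels, n_repeats=0)


class TestSelectMarkers:
    @staticmethod
    def _report(importances):
        imp = np.asarray(importances, float)
        ranking = np.lexsort((np.arange(len(imp)), -imp))
        return ImportanceReport(
            baseline_score=1.0,
            permuted_scores=np.zeros((len(imp), 1)),
            importances=imp,
            ranking=ranking,
            selected=ranking[imp[ranking] > 0],
            n_repeats=1,
            seed=0,
        )

    def test_strict_positivity(self):
        assert select_markers(self._report([0.2, 0.0, -0.1])) == [0]

    def test_all_nonpositive_gives_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ginsengms.markers"):
            assert select_markers(self._report([-0.2, 0.0])) == []
        assert "no feature" in caplog.text

    def test_descending_order(self):
        assert select_markers(self._report([0.1, 0.5, 0.3])) == [1, 2, 0]

    def test_planted_markers_recalled(self):
        # recovery of the planted set: the informative features should
        # rank above chance consistently (recall side of the property)
        hits = 0
        for seed in range(10):
            table, truth = generate_feature_table(SyntheticSpec(seed=seed, effect_size=2.0))
            Z = normalize_zscore(table).values
            rep = permutation_importance(Z, table.origins, C=1, gamma=0.03, n_repeats=10, seed=seed)
            sel = set(select_markers(rep))
            recall = len(sel & set(truth.informative.tolist())) / len(truth.informative)
            hits += recall >= 2 / 3
        assert hits >= 8


class TestRefitAndPredict:
    def test_all_features_equals_full_fit(self, strong_signal_zscores):
        from ginsengms import cross_validate

        Z, labels, _ = strong_signal_zscores
        model, report, gs = refit_on_markers(
            Z, labels, list(range(Z.shape[1])), C_grid=[1.0], gamma_grid=[0.03], k=10, seed=0
        )
        acc_direct, oof = cross_validate(Z, labels, C=1.0, gamma=0.03, k=10, seed=0)
        assert report.recognized == oof
        assert report.accuracy_percent == int(100 * acc_direct // 1)

    def test_true_markers_reach_ceiling(self, strong_signal_zscores):
        Z, labels, truth = strong_signal_zscores
        _, report, _ = refit_on_markers(
            Z, labels, truth.informative.tolist(), C_grid=[1.0], gamma_grid=[0.03], k=10, seed=0
        )
        assert report.accuracy_percent == 100

    def test_single_useless_marker_is_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        labels = list(np.repeat(["A", "B", "C"], 10))
        _, report, _ = refit_on_markers(
            X, labels, [0], C_grid=[1.0], gamma_grid=[0.03], k=10, seed=0
        )
        assert report.accuracy_percent <= 60

    def test_empty_markers_rejected(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        with pytest.raises(ValueError):
            refit_on_markers(Z, labels, [])

    def test_training_data_refed_is_consistent(self, strong_signal_table):
        table, truth = strong_signal_table
        norm = normalize_zscore(table)
        markers = truth.informative.tolist()
        model, _, _ = refit_on_markers(
            norm.values, table.origins, markers, C_grid=[1.0], gamma_grid=[0.03], k=10, seed=0
        )
        marker_ids = [table.feature_ids[j] for j in markers]
        rep = predict_external(
            model, table.areas, table.feature_ids, norm, marker_ids, table.sample_ids,
            actual=table.origins,
        )
        refit_preds = model.predict(norm.values[:, markers])
        assert rep.recognized == refit_preds

    def test_heldout_generalization(self):
        # same-population held-out batches are predicted perfectly
        # under a strong planted signal in nearly every trial
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(seed=seed, effect_size=2.5)
            table, truth = generate_feature_table(spec)
            norm = normalize_zscore(table)
            markers = truth.informative.tolist()
            model, _, _ = refit_on_markers(
                norm.values, table.origins, markers,
                C_grid=[1.0], gamma_grid=[0.03], k=10, seed=seed,
            )
            test_spec = dataclasses.replace(spec, n_per_class=3)
            test_table, _ = generate_feature_table(test_spec, sample_seed=900 + seed)
            rep = predict_external(
                model, test_table.areas, test_table.feature_ids, norm,
                [table.feature_ids[j] for j in markers],
                test_table.sample_ids, actual=test_table.origins,
            )
            wins += rep.accuracy_percent == 100
        assert wins >= 18

    def test_missing_marker_column_named(self, strong_signal_table):
        table, truth = strong_signal_table
        norm = normalize_zscore(table)
        markers = truth.informative.tolist()
        model, _, _ = refit_on_markers(
            norm.values, table.origins, markers, C_grid=[1.0], gamma_grid=[0.03], k=10, seed=0
        )
        marker_ids = [table.feature_ids[j] for j in markers]
        keep = [i for i, fid in enumerate(table.feature_ids) if fid != marker_ids[0]]
        with pytest.raises(ValueError, match=marker_ids[0]):
            predict_external(
                model,
                table.areas[:, keep],
                [table.feature_ids[i] for i in keep],
                norm,
                marker_ids,
                table.sample_ids,
            )
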