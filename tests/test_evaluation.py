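"""Hierarchical metrics, baselines, confusion matrices, and fold
assignment."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from notecode import (
    CNNConfig,
    MatchLevel,
    PredictionPair,
    compute_metrics,
    cross_validate,
    full_report,
    majority_baseline,
    normalized_confusion_matrix,
    parse_code,
    stratified_folds,
)

CODE_POOL = [
    "518.81", "518.82", "486", "466.0", "770.8", "770.6", "431", "434.91",
    "410.9", "250.0", "250.4", "008.8", "599.0", "780.6", "553.3", "820.8",
]


def pairs_from_codes(code_pairs, table, fold_id=0):
    return [
        PredictionPair(parse_code(p, table), parse_code(a, table), fold_id)
        for p, a in code_pairs
    ]


def random_pairs(rng, table, n):
    return pairs_from_codes(
        [(CODE_POOL[rng.integers(len(CODE_POOL))], CODE_POOL[rng.integers(len(CODE_POOL))])
         for _ in range(n)],
        table,
    )


def brute_force_metrics(pairs, level):
    """Independent oracle: enumerate the full confusion table and average
    per-group metrics by actual-group support."""
    y_true = [p.actual.at_level(level) for p in pairs]
    y_pred = [p.predicted.at_level(level) for p in pairs]
    groups = sorted(set(y_true) | set(y_pred))
    n = len(pairs)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    precision = recall = f1 = 0.0
    for g in groups:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == g and p == g)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != g and p == g)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == g and p != g)
        support = tp + fn
        prec_g = tp / (tp + fp) if tp + fp else 0.0
        rec_g = tp / (tp + fn) if tp + fn else 0.0
        f1_g = 2 * prec_g * rec_g / (prec_g + rec_g) if prec_g + rec_g else 0.0
        w = support / n
        precision += w * prec_g
        recall += w * rec_g
        f1 += w * f1_g
    return acc, precision, recall, f1


class TestComputeMetrics:
    def test_hand_computed_example(self, table):
        # predictions (A,A),(B,A),(B,B) with A=431, B=486 at FULL:
        # accuracy 2/3; precision(431)=1 (support 2), precision(486)=1/2
        # (support 1) -> weighted precision 5/6; weighted recall 2/3
        pairs = pairs_from_codes([("431", "431"), ("486", "431"), ("486", "486")], table)
        row = compute_metrics(pairs, MatchLevel.FULL, table)
        assert row.accuracy == pytest.approx(2 / 3)
        assert row.recall == pytest.approx(2 / 3)
        assert row.precision == pytest.approx(5 / 6)

    def test_all_correct_gives_ones(self, table):
        pairs = pairs_from_codes([(c, c) for c in CODE_POOL], table)
        for level in MatchLevel:
            row = compute_metrics(pairs, level, table)
            assert (row.recall, row.precision, row.f1, row.accuracy) == (1, 1, 1, 1)

    def test_weighted_recall_equals_accuracy(self, table):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pairs = random_pairs(rng, table, int(rng.integers(1, 60)))
            for level in MatchLevel:
                row = compute_metrics(pairs, level, table)
                assert abs(row.recall - row.accuracy) < 1e-12

    def test_agrees_with_brute_force_oracle(self, table):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pairs = random_pairs(rng, table, int(rng.integers(1, 200)))
            for level in MatchLevel:
                row = compute_metrics(pairs, level, table)
                acc, prec, rec, f1 = brute_force_metrics(pairs, level)
                assert row.accuracy == pytest.approx(acc, abs=1e-12)
                assert row.precision == pytest.approx(prec, abs=1e-12)
                assert row.recall == pytest.approx(rec, abs=1e-12)
                assert row.f1 == pytest.approx(f1, abs=1e-12)

    def test_empty_pairs_error(self, table):
        with pytest.raises(ValueError):
            compute_metrics([], MatchLevel.FULL, table)

    def test_macro_and_micro_modes_exist(self, table):
        pairs = pairs_from_codes([("431", "431"), ("486", "431")], table)
        macro = compute_metrics(pairs, MatchLevel.FULL, table, average="macro")
        micro = compute_metrics(pairs, MatchLevel.FULL, table, average="micro")
        assert micro.recall == pytest.approx(micro.accuracy)
        assert 0 <= macro.f1 <= 1


class TestMajorityBaseline:
    def test_single_code(self, table):
        codes = [parse_code("431", table)] * 5
        for level in MatchLevel:
            assert majority_baseline(codes, level, table) == 1.0

    def test_full_level_count(self, table):
        codes = [parse_code(c, table) for c in ["431", "431", "770.8"]]
        assert majority_baseline(codes, MatchLevel.FULL, table) == pytest.approx(2 / 3)

    def test_chapter_pooling_grows_majority(self, table):
        # 431 and 434.91 share the circulatory chapter; 770.8 does not
        codes = [parse_code(c, table) for c in ["431", "434.91", "770.8"]]
        assert majority_baseline(codes, MatchLevel.CHAPTER, table) == pytest.approx(2 / 3)
        assert majority_baseline(codes, MatchLevel.FULL, table) == pytest.approx(1 / 3)

    def test_empty_errors(self, table):
        with pytest.raises(ValueError):
            majority_baseline([], MatchLevel.FULL, table)


class TestMonotonicity:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_accuracy_and_baseline_non_increasing_chapter_to_full(self, seed):
        """Coarser match levels can only merge groups, so accuracy and the
        majority baseline never increase from Chapter to Full."""
        from notecode import load_hierarchy

        table = load_hierarchy()
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, table, int(rng.integers(1, 80)))
        rows = [compute_metrics(pairs, level, table) for level in MatchLevel]
        for a, b in zip(rows, rows[1:]):
            assert a.accuracy >= b.accuracy - 1e-12
            assert a.baseline >= b.baseline - 1e-12


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self, table):
        pairs = pairs_from_codes([(c, c) for c in CODE_POOL for _ in range(2)], table)
        cm = normalized_confusion_matrix(pairs, MatchLevel.FULL, top_n=10, table=table)
        assert np.allclose(np.diag(cm.matrix[:, :-1][: len(cm.labels)]), 1.0)
        assert np.allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_sum_to_one(self, table):
        rng = np.random.default_rng(3)
        pairs = random_pairs(rng, table, 150)
        for level in MatchLevel:
            cm = normalized_confusion_matrix(pairs, level, top_n=5, table=table)
            sums = cm.matrix.sum(axis=1)
            assert np.allclose(sums[cm.supports > 0], 1.0, atol=1e-9)

    def test_out_of_top_n_mass_goes_to_other(self, table):
        # actual groups 431 (x2) and 486 (x2) are the top 2; one prediction
        # into the excluded group 770.8 must land in "other"
        pairs = pairs_from_codes(
            [("431", "431"), ("431", "431"), ("486", "486"), ("770.8", "486"),
             ("770.8", "770.8")],
            table,
        )
        cm = normalized_confusion_matrix(pairs, MatchLevel.FULL, top_n=2, table=table)
        assert cm.labels == ["431", "486"]
        row_486 = cm.matrix[cm.labels.index("486")]
        assert row_486[-1] == pytest.approx(0.5)  # the "other" column

    def test_rank_ties_break_lexicographically(self, table):
        pairs = pairs_from_codes([("431", "431"), ("486", "486")], table)
        cm = normalized_confusion_matrix(pairs, MatchLevel.FULL, top_n=1, table=table)
        assert cm.labels == ["431"]


class TestStratifiedFolds:
    def test_partition_arithmetic(self):
        labels = [f"c{i % 5}" for i in range(100)]
        folds = stratified_folds(labels, 10, seed=1)
        assert len(folds) == 100
        assert Counter(folds) == {f: 10 for f in range(10)}

    def test_stratification_of_common_classes(self):
        labels = ["a"] * 50 + ["b"] * 30 + ["rare"] * 2
        folds = stratified_folds(labels, 10, seed=3)
        a_folds = Counter(folds[:50])
        assert all(v == 5 for v in a_folds.values())
        b_folds = Counter(folds[50:80])
        assert set(b_folds.values()) == {3}
        assert (folds >= 0).all()

    def test_determinism(self):
        labels = [f"c{i % 7}" for i in range(83)]
        assert np.array_equal(stratified_folds(labels, 10, 5),
                              stratified_folds(labels, 10, 5))

    def test_k_below_two_errors(self):
        with pytest.raises(ValueError):
            stratified_folds(["a", "b"], 1, 0)

    def test_fewer_records_than_k_errors(self):
        with pytest.raises(ValueError):
            stratified_folds(["a"] * 3, 10, 0)


class TestCrossValidate:
    def test_one_pair_per_record_and_determinism(self, small_corpus, table):
        _, records, lexicon = small_corpus
        cfg = CNNConfig(embedding_dim=12, n_filters=8, epochs=2, batch_size=32,
                        max_len=60, conv_window=3, seed=2)
        runs = []
        for _ in range(2):
            pairs = cross_validate(records[:120], 4, cfg, seed=9,
                                   table=table, lexicon=lexicon)
            assert len(pairs) == 120
            assert Counter(p.fold_id for p in pairs) == {f: 30 for f in range(4)}
            runs.append([(p.predicted.full_code, p.actual.full_code, p.fold_id)
                         for p in pairs])
        assert runs[0] == runs[1]

    def test_k_larger_than_corpus_errors(self, small_corpus, table):
        _, records, lexicon = small_corpus
        cfg = CNNConfig(embedding_dim=12, n_filters=8, epochs=1, max_len=60,
                        conv_window=3)
        with pytest.raises(ValueError):
            cross_validate(records[:5], 10, cfg, seed=0, table=table, lexicon=lexicon)


class TestFullReport:
    def test_report_shape_and_ordering(self, table):
        rng = np.random.default_rng(11)
        pairs = random_pairs(rng, table, 120)
        report = full_report(pairs, table, top_n=5)
        assert [r.level for r in report.rows] == list(MatchLevel)
        accs = [r.accuracy for r in report.rows]
        assert accs == sorted(accs, reverse=True)
        baselines = [r.baseline for r in report.rows]
        assert baselines == sorted(baselines, reverse=True)
        tsv = report.metrics_tsv()
        assert tsv.splitlines()[0].startswith("Rule (Match Criteria)\tRecall")
        assert len(tsv.splitlines()) == 5

    def test_all_correct_pairs_rows_of_ones(self, table):
        pairs = pairs_from_codes([(c, c) for c in CODE_POOL], table)
        report = full_report(pairs, table)
        for row in report.rows:
            assert row.accuracy == 1.0 and row.f1 == 1.0

    def test_report_files_written(self, tmp_path, table):
        rng = np.random.default_rng(2)
        pairs = random_pairs(rng, table, 60)
        report = full_report(pairs, table, top_n=4)
        report.write(tmp_path)
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "confusion_full.tsv").exists()
        text = (tmp_path / "metrics.tsv").read_text(encoding="utf-8")
        assert "Chapter Match" in text and "Full Code Match" in text
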