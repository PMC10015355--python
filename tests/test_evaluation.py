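"""Entity / token / character metrics, splits, stats and delta tables."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from crossner.evaluation import (
    char_label_f1,
    compare_models,
    dataset_stats,
    entity_prf,
    report_from_table,
    split_dataset,
    token_iob_eval,
)
from crossner.sentencize import Sentence
from crossner.standoff_io import Annotation


def brute_force_entity_counts(gold, pred):
    """Independent exact-match counter: greedy one-to-one pairing of equal
    (start, end, label) triples per sentence."""
    tp = fp = fn = 0
    for g_sent, p_sent in zip(gold, pred):
        g_left = [(a.start, a.end, a.label) for a in g_sent]
        for a in p_sent:
            key = (a.start, a.end, a.label)
            if key in g_left:
                g_left.remove(key)
                tp += 1
            else:
                fp += 1
        fn += len(g_left)
    return tp, fp, fn


class TestEntityPrf:
    def test_perfect_match(self):
        spans = [[Annotation(0, 5, "Drug", "aspir")]]
        report = entity_prf(spans, spans)
        assert report.per_tag["Drug"].precision == 100
        assert report.per_tag["Drug"].recall == 100
        assert report.per_tag["Drug"].f1 == 100

    def test_extra_prediction_halves_precision(self):
        gold = [[Annotation(0, 5, "Drug")]]
        pred = [[Annotation(0, 5, "Drug"), Annotation(6, 8, "Drug")]]
        report = entity_prf(gold, pred)
        s = report.per_tag["Drug"]
        assert (s.precision, s.recall) == (50, 100)
        assert s.f1 == pytest.approx(66.67, abs=0.01)

    def test_empty_pred_scores_zero(self):
        report = entity_prf([[Annotation(0, 5, "Drug")]], [[]])
        s = report.per_tag["Drug"]
        assert (s.precision, s.recall, s.f1) == (0, 0, 0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force_matcher(self, seed):
        import random

        rng = random.Random(seed)
        labels = ["Drug", "Route", "Dosage"]

        def random_spans():
            return [
                Annotation(s, s + rng.randint(1, 3), rng.choice(labels))
                for s in rng.sample(range(0, 40, 4), rng.randint(0, 5))
            ]

        gold = [random_spans() for _ in range(4)]
        pred = [random_spans() for _ in range(4)]
        report = entity_prf(gold, pred)
        tp, fp, fn = brute_force_entity_counts(gold, pred)
        # reconstruct aggregate counts from the report
        agg_tp = sum(
            s.support * s.recall / 100 for s in report.per_tag.values()
        )
        assert agg_tp == pytest.approx(tp, abs=1e-6)
        total_support = sum(s.support for s in report.per_tag.values())
        assert total_support == tp + fn


class TestTokenIob:
    def test_identical_sequences_all_100(self):
        tags = [["B-Drug", "I-Drug", "O"]]
        report = token_iob_eval(tags, tags)
        assert report.total.f1 == 100

    def test_partial_overlap_token_counts(self):
        gold = [["B-Drug", "I-Drug", "O"]]
        pred = [["B-Drug", "O", "O"]]
        report = token_iob_eval(gold, pred)
        s = report.per_tag["Drug"]
        assert (s.precision, s.recall) == (100, 50)
        assert s.f1 == pytest.approx(66.67, abs=0.01)

    def test_all_outside_yields_empty_report(self):
        report = token_iob_eval([["O", "O"]], [["O", "O"]])
        assert report.per_tag == {}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            token_iob_eval([["O", "O"]], [["O"]])


class TestCharLabelF1:
    def test_partial_span_character_counts(self):
        gold = [("aspirin", [Annotation(0, 7, "Drug", "aspirin")])]
        pred = [("aspirin", [Annotation(0, 4, "Drug", "aspi")])]
        report = char_label_f1(gold, pred)
        s = report.per_tag["Drug"]
        assert s.precision == 100
        assert s.recall == pytest.approx(57.14, abs=0.01)
        assert s.f1 == pytest.approx(72.73, abs=0.01)

    def test_exact_match(self):
        gold = [("aspirin", [Annotation(0, 7, "Drug")])]
        assert char_label_f1(gold, gold).per_tag["Drug"].f1 == 100

    def test_disjoint_spans_zero(self):
        gold = [("aspirin forte", [Annotation(0, 7, "Drug")])]
        pred = [("aspirin forte", [Annotation(8, 13, "Drug")])]
        assert char_label_f1(gold, pred).per_tag["Drug"].f1 == 0

    def test_conflicting_overlap_rejected(self):
        gold = [("aspirin", [Annotation(0, 5, "Drug"), Annotation(3, 7, "Route")])]
        with pytest.raises(ValueError, match="conflicting"):
            char_label_f1(gold, gold)

    def test_invariant_to_splitting_adjacent_same_label_spans(self):
        whole = [("aspirin", [Annotation(0, 7, "Drug")])]
        split = [("aspirin", [Annotation(0, 3, "Drug"), Annotation(3, 7, "Drug")])]
        pred = [("aspirin", [Annotation(0, 5, "Drug")])]
        a = char_label_f1(whole, pred).per_tag["Drug"]
        b = char_label_f1(split, pred).per_tag["Drug"]
        assert (a.precision, a.recall, a.f1) == (b.precision, b.recall, b.f1)


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n,expected",
        [(8599, (6879, 860, 860)), (10, (8, 1, 1)), (100, (80, 10, 10))],
    )
    def test_split_sizes(self, n, expected):
        train, val, test = split_dataset(n, seed=0)
        assert (len(train), len(val), len(test)) == expected

    def test_partition_exact_and_disjoint(self):
        train, val, test = split_dataset(537, seed=3)
        combined = sorted(itertools.chain(train, val, test))
        assert combined == list(range(537))

    def test_seeded_shuffle_reproducible(self):
        assert split_dataset(50, seed=9) == split_dataset(50, seed=9)
        assert split_dataset(50, seed=9) != split_dataset(50, seed=10)


class TestDatasetStats:
    def test_empty_corpus(self):
        stats = dataset_stats([])
        assert stats == {"sentences": 0, "annotations": 0, "per_label": {}, "tokens": 0}

    def test_matches_generator_bookkeeping(self, annotated_sentences, small_corpus):
        _, books = small_corpus
        stats = dataset_stats(annotated_sentences)
        assert stats["per_label"] == books.per_label
        assert stats["annotations"] == sum(books.per_label.values())

    def test_grand_total_is_sum_of_labels(self, annotated_sentences):
        stats = dataset_stats(annotated_sentences)
        assert stats["annotations"] == sum(stats["per_label"].values())


class TestWeightedTotals:
    def test_total_between_min_and_max_per_tag(self):
        gold = [[Annotation(0, 2, "Drug"), Annotation(3, 5, "Route")]] * 4
        pred = [[Annotation(0, 2, "Drug")]] * 4
        report = entity_prf(gold, pred)
        f1s = [s.f1 for s in report.per_tag.values()]
        assert min(f1s) <= report.total.f1 <= max(f1s)

    def test_single_tag_total_equals_tag_value(self):
        gold = [[Annotation(0, 2, "Drug")]]
        pred = [[Annotation(0, 2, "Drug"), Annotation(3, 5, "Drug")]]
        report = entity_prf(gold, pred)
        assert report.total.f1 == report.per_tag["Drug"].f1


class TestCompareModels:
    def test_identical_reports_zero_deltas(self):
        report = report_from_table("entity", {"Drug": (90.0, 80.0, 84.7, 10)})
        deltas = compare_models(report, report)
        assert deltas == {"Drug": 0.0, "Total": 0.0}

    def test_mismatched_labels_rejected(self):
        a = report_from_table("entity", {"Drug": (1, 1, 1, 1)})
        b = report_from_table("entity", {"Route": (1, 1, 1, 1)})
        with pytest.raises(ValueError):
            compare_models(a, b)

    def test_delta_sign_is_a_minus_b(self):
        a = report_from_table("entity", {"Drug": (0, 0, 66.74, 5)})
        b = report_from_table("entity", {"Drug": (0, 0, 81.47, 5)})
        deltas = compare_models(a, b)
        assert deltas["Drug"] == pytest.approx(-14.73, abs=1e-9)
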