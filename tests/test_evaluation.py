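from fractions import Fraction

import pytest

from consort_check.detectors import ItemMatch
from consort_check.evaluation import (
    AccuracyRow,
    AccuracyTable,
    GroundTruth,
    GroundTruthEntry,
    TriageResult,
    bin_accuracies,
    dump_ground_truth,
    load_ground_truth,
    per_item_accuracy,
    score_corpus,
    score_item_on_article,
    triage_sentences,
)


def match(status, coords=(), item_id="19"):
    return ItemMatch(
        item_id, status,
        matched=tuple((s, i, f"text-{s}-{i}") for s, i in coords),
        notification_code="WRONG_SECTION" if status == "notification" else None,
    )


class TestScoreItem:
    def test_exhaustive_outcome_table(self, registry):
        """Enumerate status x truth x overlap; compare with the definition:
        correct iff (extracted sentence in truth) or (null finding and truly
        absent)."""
        truth_present = GroundTruthEntry(True, (("RESULTS", 2),))
        truth_absent = GroundTruthEntry(False)
        cases = [
            (match("found", [("RESULTS", 2)]), truth_present, True),
            (match("found", [("RESULTS", 3)]), truth_present, False),
            (match("found", [("RESULTS", 3), ("RESULTS", 2)]), truth_present,
             True),
            (match("found", [("METHODS", 2)]), truth_present, False),
            (match("found", [("RESULTS", 2)]), truth_absent, False),
            (match("notification", [("RESULTS", 2)]), truth_present, True),
            (match("notification", []), truth_present, False),
            (match("notification", []), truth_absent, False),
            (match("not_found"), truth_absent, True),
            (match("not_found"), truth_present, False),
        ]
        for m, truth, expected in cases:
            assert score_item_on_article(m, truth, registry) is expected, \
                (m.status, m.matched, truth)

    def test_scoring_excluded_item_is_usage_error(self, registry):
        m = match("not_found", item_id="13a")
        with pytest.raises(ValueError, match="excluded"):
            score_item_on_article(m, GroundTruthEntry(False), registry)


class TestAccuracy:
    def test_rational_division(self, registry):
        scores = {it.item_id: [True] * 9 + [False]
                  for it in registry.scored_items()}
        table = per_item_accuracy(scores, registry)
        assert all(r.accuracy == Fraction(9, 10) for r in table.rows.values())

    def test_all_correct_and_null_items(self, registry):
        scores = {it.item_id: [True, True] for it in registry.scored_items()}
        table = per_item_accuracy(scores, registry)
        assert all(r.accuracy == 1 for r in table.rows.values())
        assert len(table.rows) == 30

    def test_zero_articles_rejected(self, registry):
        with pytest.raises(ValueError):
            per_item_accuracy({it.item_id: [] for it in
                               registry.scored_items()}, registry)

    def test_accuracy_equals_brute_force_recount(self, small_corpus, registry):
        reports, truths = small_corpus["reports"], small_corpus["truths"]
        table = per_item_accuracy(score_corpus(reports, truths, registry),
                                  registry)
        truth_by_id = {t.article_id: t for t in truths}
        for item in registry.scored_items():
            n_correct = 0
            for report in reports:  # independent naive recount
                m = report.matches[item.item_id]
                entry = truth_by_id[report.source].entry(item.item_id)
                extracted = {(s, i) for s, i, _t in m.matched}
                if m.status in ("found", "notification"):
                    ok = bool(extracted & set(entry.sentences))
                else:
                    ok = m.status == "not_found" and not entry.present
                n_correct += ok
            assert table.rows[item.item_id].accuracy == \
                Fraction(n_correct, len(reports))


class TestBands:
    @pytest.mark.parametrize("acc,band", [
        (Fraction(79, 100), "LT80"),
        (Fraction(80, 100), "B80_90"),
        (Fraction(85, 100), "B80_90"),
        (Fraction(90, 100), "B80_90"),  # boundary stays in the middle band
        (Fraction(91, 100), "GT90"),
        (Fraction(1, 1), "GT90"),
    ])
    def test_boundaries(self, acc, band, registry):
        scores = {it.item_id: [True] * acc.numerator +
                  [False] * (acc.denominator - acc.numerator)
                  for it in registry.scored_items()}
        table = per_item_accuracy(scores, registry)
        assert all(r.band == band for r in table.rows.values())

    def test_counts_sum_to_30(self, small_corpus, registry):
        table = per_item_accuracy(
            score_corpus(small_corpus["reports"], small_corpus["truths"],
                         registry), registry)
        assert sum(bin_accuracies(table).values()) == 30


class TestTriage:
    def _reports_truths(self, registry, extractions, truths_map):
        reports, truths = [], []
        for art, ext in extractions.items():
            matches = {}
            for item in registry:
                coords = ext.get(item.item_id, [])
                if item.status == "not_implemented":
                    matches[item.item_id] = ItemMatch(item.item_id,
                                                      "not_implemented")
                elif coords:
                    matches[item.item_id] = match("found", coords,
                                                  item.item_id)
                else:
                    matches[item.item_id] = match("not_found",
                                                  item_id=item.item_id)
            from consort_check.detectors import ChecklistReport
            reports.append(ChecklistReport(source=art, matches=matches))
            items = {
                iid: GroundTruthEntry(True, tuple(coords))
                for iid, coords in truths_map.get(art, {}).items()
            }
            truths.append(GroundTruth(article_id=art, items=items))
        return reports, truths

    def test_perfect_detector(self, registry):
        ext = {"a1": {"19": [("RESULTS", 0)], "4a": [("METHODS", 1)]}}
        reports, truths = self._reports_truths(registry, ext, {
            "a1": {"19": [("RESULTS", 0)], "4a": [("METHODS", 1)]}})
        tri = triage_sentences(reports, truths, registry)
        assert (tri.positive, tri.negative, tri.undetected) == (2, 0, 0)
        assert tri.proportion_bad == 0

    def test_detector_extracting_nothing(self, registry):
        reports, truths = self._reports_truths(registry, {"a1": {}}, {
            "a1": {"19": [("RESULTS", 0)]}})
        tri = triage_sentences(reports, truths, registry)
        assert tri.positive == 0 and tri.undetected == 1
        assert tri.proportion_bad == 1

    def test_mixed_three_article_hand_oracle(self, registry):
        ext = {
            "a1": {"19": [("RESULTS", 0)], "4a": [("METHODS", 5)]},
            "a2": {"19": [("RESULTS", 1), ("RESULTS", 2)]},
            "a3": {},
        }
        truth = {
            "a1": {"19": [("RESULTS", 0)]},              # 4a extra -> negative
            "a2": {"19": [("RESULTS", 1)], "20": [("DISCUSSION", 0)]},
            "a3": {"25": [("OTHER_INFO", 0)]},
        }
        reports, truths = self._reports_truths(registry, ext, truth)
        tri = triage_sentences(reports, truths, registry)
        # hand enumeration: positives a1/19, a2/19-1; negatives a1/4a,
        # a2/19-2; undetected a2/20, a3/25
        assert (tri.positive, tri.negative, tri.undetected) == (2, 2, 2)
        assert tri.proportion_bad == Fraction(4, 6)

    def test_order_invariance(self, small_corpus, registry):
        reports, truths = small_corpus["reports"], small_corpus["truths"]
        t1 = triage_sentences(reports, truths, registry)
        t2 = triage_sentences(list(reversed(reports)),
                              list(reversed(truths)), registry)
        assert t1 == t2

    def test_id_mismatch_rejected(self, registry):
        reports, truths = self._reports_truths(registry, {"a1": {}}, {})
        truths[0].article_id = "other"
        with pytest.raises(ValueError, match="mismatch"):
            triage_sentences(reports, truths, registry)


class TestGroundTruthIO:
    def test_round_trip(self, small_corpus, tmp_path):
        truths = small_corpus["truths"]
        path = tmp_path / "truth.json"
        path.write_text(dump_ground_truth(truths))
        again = load_ground_truth(path)
        assert {t.article_id for t in again} == \
            {t.article_id for t in truths}
        by_id = {t.article_id: t for t in again}
        for t in truths:
            assert by_id[t.article_id].items == t.items

    def test_entry_invariant(self):
        with pytest.raises(ValueError):
            GroundTruthEntry(True, ())
        with pytest.raises(ValueError):
            GroundTruthEntry(False, (("METHODS", 0),))
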