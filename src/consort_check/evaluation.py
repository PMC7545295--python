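"""Performance machinery: per-item accuracy, banding, and sentence triage.

An article-item assessment is *correct* when the checker either extracts a
truly relevant sentence (exact sentence identity by (section, index) — the
synthetic truth is exact, and fuzzy matching would mask offset bugs) or
reports a null finding for an article that truly lacks the item.  A
notification whose matched sentences include a true sentence counts as a
correct extraction (an incomplete-but-located finding is still a detection).

Accuracy per item is the exact rational n_correct / n_articles over a corpus,
restricted to the 30 scored sub-items, and is banded into <80%, 80–90%, and
>90% (the 0.90 boundary belongs to the middle band; ">90%" is strict).

Triage mirrors tool-training bookkeeping: every extracted sentence is
*positive* (truly relevant) or *negative* (irrelevant), and every truth
sentence the checker missed is *undetected*; the tuning criterion is
(negative + undetected) / total < 10%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

from .detectors import ChecklistReport, ItemMatch
from .registry import Registry, load_registry

__all__ = [
    "GroundTruthEntry",
    "GroundTruth",
    "AccuracyRow",
    "AccuracyTable",
    "TriageResult",
    "score_item_on_article",
    "per_item_accuracy",
    "bin_accuracies",
    "triage_sentences",
    "score_corpus",
    "load_ground_truth",
    "dump_ground_truth",
    "accuracy_table_tsv",
]

BANDS = ("LT80", "B80_90", "GT90")


@dataclass(frozen=True)
class GroundTruthEntry:
    present: bool
    sentences: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.present != bool(self.sentences):
            raise ValueError("truth sentences must be non-empty iff present")


@dataclass
class GroundTruth:
    article_id: str
    items: dict[str, GroundTruthEntry] = field(default_factory=dict)

    def entry(self, item_id: str) -> GroundTruthEntry:
        return self.items.get(item_id, GroundTruthEntry(present=False))


@dataclass(frozen=True)
class AccuracyRow:
    item_id: str
    accuracy: Fraction
    band: str
    n_articles: int


@dataclass
class AccuracyTable:
    rows: dict[str, AccuracyRow]

    def band_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BANDS}
        for row in self.rows.values():
            counts[row.band] += 1
        return counts


@dataclass(frozen=True)
class TriageResult:
    positive: int
    negative: int
    undetected: int

    @property
    def total(self) -> int:
        return self.positive + self.negative + self.undetected

    @property
    def proportion_bad(self) -> Fraction:
        if self.total == 0:
            return Fraction(0)
        return Fraction(self.negative + self.undetected, self.total)


def _band(acc: Fraction) -> str:
    if acc < Fraction(4, 5):
        return "LT80"
    if acc <= Fraction(9, 10):
        return "B80_90"
    return "GT90"


def score_item_on_article(match: ItemMatch, truth: GroundTruthEntry,
                          registry: Registry | None = None) -> bool:
    """Whether the checker assessed one article-item correctly.

    Raises ``ValueError`` when asked to score a sub-item that is excluded
    from the accuracy metric.
    """
    registry = registry if registry is not None else load_registry()
    if not registry[match.item_id].in_accuracy:
        raise ValueError(
            f"item {match.item_id} is excluded from accuracy scoring"
        )
    extracted = {(sec, idx) for sec, idx, _text in match.matched}
    truth_set = set(truth.sentences)
    if match.status in ("found", "notification"):
        return bool(extracted & truth_set)
    if match.status == "not_found":
        return not truth.present
    return False


def score_corpus(reports: list[ChecklistReport], truths: list[GroundTruth],
                 registry: Registry | None = None) -> dict[str, list[bool]]:
    """Per-item lists of per-article correctness, corpora aligned by id."""
    registry = registry if registry is not None else load_registry()
    truth_by_id = {t.article_id: t for t in truths}
    scores: dict[str, list[bool]] = {it.item_id: []
                                     for it in registry.scored_items()}
    for report in reports:
        truth = truth_by_id.get(report.source)
        if truth is None:
            raise ValueError(f"no ground truth for article {report.source!r}")
        for item in registry.scored_items():
            scores[item.item_id].append(
                score_item_on_article(report.matches[item.item_id],
                                      truth.entry(item.item_id), registry)
            )
    return scores


def per_item_accuracy(scores: dict[str, list[bool]],
                      registry: Registry | None = None) -> AccuracyTable:
    """Exact rational accuracy per scored item."""
    registry = registry if registry is not None else load_registry()
    rows: dict[str, AccuracyRow] = {}
    for item in registry.scored_items():
        article_scores = scores.get(item.item_id, [])
        if not article_scores:
            raise ValueError("accuracy needs at least one article")
        acc = Fraction(sum(article_scores), len(article_scores))
        rows[item.item_id] = AccuracyRow(item.item_id, acc, _band(acc),
                                         len(article_scores))
    return AccuracyTable(rows)


def bin_accuracies(table: AccuracyTable) -> dict[str, int]:
    """Band counts; sums to the number of scored items."""
    return table.band_counts()


def triage_sentences(reports: list[ChecklistReport],
                     truths: list[GroundTruth],
                     registry: Registry | None = None) -> TriageResult:
    """Partition extracted/missed sentences into positive/negative/undetected.

    The universe is every (article, scored item) sentence either extracted by
    the checker or marked in the truth; order of articles does not matter.
    """
    registry = registry if registry is not None else load_registry()
    truth_by_id = {t.article_id: t for t in truths}
    if len(truth_by_id) != len(truths):
        raise ValueError("duplicate article ids in ground truth")
    positive = negative = undetected = 0
    for report in reports:
        if report.source not in truth_by_id:
            raise ValueError(
                f"article id mismatch: no truth for {report.source!r}"
            )
        truth = truth_by_id[report.source]
        for item in registry.scored_items():
            match = report.matches[item.item_id]
            extracted = {(sec, idx) for sec, idx, _text in match.matched}
            truth_set = set(truth.entry(item.item_id).sentences)
            positive += len(extracted & truth_set)
            negative += len(extracted - truth_set)
            undetected += len(truth_set - extracted)
    return TriageResult(positive=positive, negative=negative,
                        undetected=undetected)


# ---------------------------------------------------------------- file I/O

def dump_ground_truth(truths: list[GroundTruth]) -> str:
    payload = {
        "schema_version": 1,
        "articles": [
            {
                "id": t.article_id,
                "items": {
                    item_id: {
                        "present": e.present,
                        "sentences": [list(s) for s in e.sentences],
                    }
                    for item_id, e in sorted(t.items.items())
                },
            }
            for t in truths
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def load_ground_truth(path) -> list[GroundTruth]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    truths = []
    for art in payload["articles"]:
        items = {
            item_id: GroundTruthEntry(
                present=rec["present"],
                sentences=tuple((s, i) for s, i in rec["sentences"]),
            )
            for item_id, rec in art["items"].items()
        }
        truths.append(GroundTruth(article_id=art["id"], items=items))
    return truths


def accuracy_table_tsv(table: AccuracyTable) -> str:
    lines = ["item_id\taccuracy\tband\tn_articles"]
    for item_id, row in table.rows.items():
        lines.append(f"{item_id}\t{float(row.accuracy):.4f}\t{row.band}"
                     f"\t{row.n_articles}")
    return "\n".join(lines) + "\n"
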