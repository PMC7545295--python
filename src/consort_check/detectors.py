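"""Per-item evidence detection and checklist assembly.

Each checklist sub-item has a rule in ``data/detector_rules.json``: one or
more clauses of lemma-sequence/regex cue groups, optionally tied to an entity
kind that must co-occur in the same sentence (the co-occurrence realization of
relationship extraction).  Title- and abstract-scoped items have dedicated
logic.  Three outcomes beyond found/not-found are modeled as notifications:

* ``MISSING_ALLOCATION_RATIO`` — item 3a found a trial-design sentence but no
  allocation ratio (for example ``1:1``) anywhere in it;
* ``CHECK_FIGURE_OR_TABLE`` — a participant-flow item (13a/13b/16) or the
  baseline table (15) has no body evidence but a candidate figure/table
  caption exists, so the information may be embedded in the graphic;
* ``WRONG_SECTION`` — evidence was found, but only outside the section the
  checklist expects.

Items 2a, 22, and 17b are registered as not implemented and short-circuit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

from .ingest import Manuscript
from .nlp import (
    AnnotatedSentence,
    ConfigurationError,
    EntityMention,
    annotate_sentence,
    tag_entities,
)
from .registry import ChecklistItem, Registry, load_registry

__all__ = [
    "ItemMatch",
    "ChecklistReport",
    "DetectorRules",
    "load_rules",
    "detect_item",
    "assess_section_placement",
    "run_checklist",
    "NOTIFICATION_CODES",
]

NOTIFICATION_CODES = ("WRONG_SECTION", "MISSING_ALLOCATION_RATIO",
                      "CHECK_FIGURE_OR_TABLE")

_RULES_RESOURCE = "detector_rules.json"


@dataclass(frozen=True)
class ItemMatch:
    """Detection result for one checklist sub-item on one manuscript."""

    item_id: str
    status: str  # found | not_found | notification | not_implemented
    matched: tuple[tuple[str, int, str], ...] = ()  # (section, index, text)
    notification_code: str | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.status == "found" and not self.matched:
            raise ValueError(f"item {self.item_id}: found requires matches")
        if self.status == "not_found" and self.matched:
            raise ValueError(f"item {self.item_id}: not_found must be empty")
        if (self.notification_code is not None) != (self.status == "notification"):
            raise ValueError(
                f"item {self.item_id}: notification code iff notification status"
            )


@dataclass
class ChecklistReport:
    source: str
    matches: dict[str, ItemMatch]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.matches) != 37:
            raise ValueError(f"report must carry 37 matches, got {len(self.matches)}")

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.matches.values():
            counts[m.status] = counts.get(m.status, 0) + 1
        return counts

    def notifications(self) -> list[ItemMatch]:
        return [m for m in self.matches.values() if m.status == "notification"]


# ------------------------------------------------------------------ rules

class DetectorRules:
    """Parsed detector-rule resource with compiled clause structures."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.items: dict[str, dict] = raw["items"]
        for item_id, cfg in self.items.items():
            for clause in cfg.get("clauses", []):
                for group in clause.get("all", []):
                    for alt in group:
                        if isinstance(alt, str):
                            if not alt.startswith("re:"):
                                raise ConfigurationError(
                                    f"item {item_id}: string alternative must "
                                    f"start with 're:', got {alt!r}"
                                )
                            try:
                                re.compile(alt[3:], re.IGNORECASE)
                            except re.error as exc:
                                raise ConfigurationError(
                                    f"item {item_id}: bad regex {alt!r}: {exc}"
                                ) from exc

    def for_item(self, item_id: str) -> dict:
        return self.items.get(item_id, {})


def load_rules(path=None) -> DetectorRules:
    """Load detector rules from ``path`` or the packaged resource."""
    if path is None:
        text = resources.files("consort_check.data") \
            .joinpath(_RULES_RESOURCE).read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return DetectorRules(json.loads(text))


_DEFAULT_RULES: DetectorRules | None = None


def _default_rules() -> DetectorRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


# ------------------------------------------------------------- annotation cache

def _annotations(manuscript: Manuscript) -> dict[str, list[tuple[AnnotatedSentence, list[EntityMention]]]]:
    """Annotate every in-scope sentence once per manuscript (cached)."""
    cache = getattr(manuscript, "_nlp_cache", None)
    if cache is None:
        cache = {}
        for sec in manuscript.sections:
            if not sec.in_scope:
                continue
            annotated = []
            for sent in sec.sentences:
                if not sent.text.strip():
                    continue
                ann = annotate_sentence(sent)
                annotated.append((ann, tag_entities(ann)))
            cache[sec.canonical_label] = annotated
        manuscript._nlp_cache = cache  # type: ignore[attr-defined]
    return cache


# ------------------------------------------------------------- clause engine

def _group_hits(group, ann: AnnotatedSentence) -> bool:
    lemmas = ann.lemmas
    for alt in group:
        if isinstance(alt, str):  # "re:" regex alternative; spaces = any ws
            if re.search(alt[3:].replace(" ", r"\s+"), ann.text, re.IGNORECASE):
                return True
            continue
        seq = tuple(alt)
        k = len(seq)
        for i in range(len(lemmas) - k + 1):
            if lemmas[i:i + k] == seq:
                return True
    return False


def _clause_matches(clause: dict, ann: AnnotatedSentence,
                    entities: list[EntityMention]) -> bool:
    for group in clause.get("all", []):
        if not _group_hits(group, ann):
            return False
    wanted = clause.get("entities")
    if wanted:
        kinds = {e.kind for e in entities}
        if not kinds.intersection(wanted):
            return False
    return True


def _search_sections(manuscript: Manuscript, cfg: dict) -> list[str]:
    wanted = cfg.get("sections")
    labels = []
    for sec in manuscript.sections:
        if not sec.in_scope:
            continue
        if wanted is not None:
            if sec.canonical_label in wanted:
                labels.append(sec.canonical_label)
        elif sec.canonical_label != "ABSTRACT":
            labels.append(sec.canonical_label)
    return labels


# ---------------------------------------------------------------- detection

def _detect_title(manuscript: Manuscript, item: ChecklistItem,
                  cfg: dict) -> ItemMatch:
    pattern = cfg.get("title_regex", "")
    if pattern and manuscript.title and re.search(pattern, manuscript.title,
                                                 re.IGNORECASE):
        return ItemMatch(item.item_id, "found",
                         matched=(("TITLE", 0, manuscript.title),),
                         message="Identified as randomized in the title.")
    return ItemMatch(item.item_id, "not_found",
                     message="Title does not identify the study as a "
                             "randomized trial.")


_LABEL_SENT_RE_CACHE: dict[tuple[str, ...], re.Pattern] = {}


def _detect_abstract(manuscript: Manuscript, item: ChecklistItem,
                     cfg: dict) -> ItemMatch:
    sec = manuscript.section("ABSTRACT")
    if sec is None:
        return ItemMatch(item.item_id, "not_found",
                         message="No abstract section was found.")
    labels = tuple(cfg.get("abstract_labels", ()))
    pattern = _LABEL_SENT_RE_CACHE.get(labels)
    if pattern is None:
        pattern = re.compile(r"^\s*(" + "|".join(labels) + r")\s*[:.]",
                             re.IGNORECASE)
        _LABEL_SENT_RE_CACHE[labels] = pattern
    seen: dict[str, tuple[str, int, str]] = {}
    for sent in sec.sentences:
        m = pattern.match(sent.text)
        if m:
            seen.setdefault(m.group(1).lower(),
                            ("ABSTRACT", sent.index, sent.text))
    if len(seen) >= cfg.get("min_labels", 2):
        return ItemMatch(item.item_id, "found",
                         matched=tuple(seen.values()),
                         message="Structured abstract with labeled sections.")
    return ItemMatch(item.item_id, "not_found",
                     message="The abstract does not appear to be a "
                             "structured summary.")


def _caption_candidate(manuscript: Manuscript, cfg: dict) -> tuple[str, str] | None:
    pattern = cfg.get("caption_regex")
    if not pattern:
        return None
    kind = cfg.get("caption_kind", "figure")
    for cap_kind, label, text in manuscript.captions:
        if cap_kind == kind and re.search(pattern, text, re.IGNORECASE):
            return label, text
    return None


def detect_item(manuscript: Manuscript, item: ChecklistItem,
                rules: DetectorRules | None = None) -> ItemMatch:
    """Detect the evidence for one checklist sub-item.

    Returns an :class:`ItemMatch` whose matched sentences are ordered by
    document position.  Section placement is assessed separately by
    :func:`assess_section_placement`.
    """
    if item.status == "not_implemented":
        return ItemMatch(item.item_id, "not_implemented",
                         message=f"Item {item.item_id} is not implemented "
                                 "(subjective or recommendation-only).")
    rules = rules if rules is not None else _default_rules()
    cfg = rules.for_item(item.item_id)

    if item.scope == "TITLE":
        return _detect_title(manuscript, item, cfg)
    if item.scope == "ABSTRACT":
        return _detect_abstract(manuscript, item, cfg)

    cache = _annotations(manuscript)
    clauses = cfg.get("clauses", [])
    matched: list[tuple[str, int, str]] = []
    ratio_seen = False
    for label in _search_sections(manuscript, cfg):
        for ann, entities in cache.get(label, []):
            if any(_clause_matches(c, ann, entities) for c in clauses):
                sent = ann.sentence
                matched.append((label, sent.index, sent.text))
                if any(e.kind == "ALLOCATION_RATIO" for e in entities):
                    ratio_seen = True

    if matched and cfg.get("ratio_required") and not ratio_seen:
        return ItemMatch(
            item.item_id, "notification", matched=tuple(matched),
            notification_code="MISSING_ALLOCATION_RATIO",
            message="A trial-design sentence was found, but the allocation "
                    "ratio (such as 1:1) is not stated.",
        )
    if matched:
        return ItemMatch(item.item_id, "found", matched=tuple(matched),
                         message="Relevant sentence(s) identified.")

    caption = _caption_candidate(manuscript, cfg)
    if caption is not None:
        label, text = caption
        return ItemMatch(
            item.item_id, "notification",
            notification_code="CHECK_FIGURE_OR_TABLE",
            message=f"No sentence in the text reports this item; please "
                    f"check whether {label} ({text[:80]}...) contains the "
                    f"information.",
        )
    return ItemMatch(item.item_id, "not_found",
                     message="No relevant information was identified in "
                             "the article.")


_NICE_SECTION = {
    "INTRODUCTION": "Introduction", "METHODS": "Methods", "RESULTS": "Results",
    "DISCUSSION": "Discussion", "OTHER_INFO": "Other information",
    "ABSTRACT": "Abstract", "UNLABELED": "Unlabeled", "TITLE": "Title",
}


def assess_section_placement(match: ItemMatch, item: ChecklistItem) -> ItemMatch:
    """Demote a found item to a WRONG_SECTION notification when every matched
    sentence sits outside the checklist's expected section(s)."""
    if match.status != "found" or item.scope != "BODY":
        return match
    if not item.expected_sections or not match.matched:
        return match
    found_sections = {sec for sec, _idx, _txt in match.matched}
    if found_sections & item.expected_sections:
        return match
    found_nice = ", ".join(sorted(_NICE_SECTION.get(s, s) for s in found_sections))
    expected_nice = ", ".join(sorted(_NICE_SECTION[s]
                                     for s in item.expected_sections))
    return ItemMatch(
        match.item_id, "notification", matched=match.matched,
        notification_code="WRONG_SECTION",
        message=f"Evidence for item {item.item_id} was found in the "
                f"{found_nice} section, but the CONSORT checklist expects it "
                f"in the {expected_nice} section.",
    )


def run_checklist(manuscript: Manuscript, source: str = "",
                  registry: Registry | None = None,
                  rules: DetectorRules | None = None) -> ChecklistReport:
    """Run every registry item against the manuscript (deterministic)."""
    registry = registry if registry is not None else load_registry()
    rules = rules if rules is not None else _default_rules()
    matches: dict[str, ItemMatch] = {}
    for item in registry:
        match = detect_item(manuscript, item, rules)
        match = assess_section_placement(match, item)
        matches[item.item_id] = match
    return ChecklistReport(source=source, matches=matches,
                           warnings=list(manuscript.warnings))
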