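"""Shared linguistic primitives: annotation, entity tagging, cue matching.

Everything here is deterministic and rule-based.  Lemmatization is a small
suffix-rule engine with an irregular-form table and British→American spelling
normalization at the lemma level (``randomised`` → ``randomize``), which is
what the detectors key on; it is deliberately lemmatization, not stemming
(``randomization`` stays a noun).  Entity tagging combines regular-expression
patterns (registry IDs, allocation ratios, confidence intervals, counts,
percentages, date ranges, P values) with a small packaged gazetteer plus
capitalization heuristics for organizations and locations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .ingest import Sentence

__all__ = [
    "AnnotatedSentence",
    "EntityMention",
    "CuePattern",
    "CueHit",
    "ConfigurationError",
    "annotate_sentence",
    "tag_entities",
    "match_cues",
    "lemmatize_word",
]


class ConfigurationError(Exception):
    """A cue pattern or resource is malformed."""


# ------------------------------------------------------------- lemmatizer

# British suffixes rewritten before inflection stripping.
_BRITISH_SUFFIXES = (
    ("isation", "ization"), ("isations", "izations"),
    ("ising", "izing"), ("ised", "ized"), ("ises", "izes"), ("ise", "ize"),
    ("ysing", "yzing"), ("ysed", "yzed"), ("yse", "yze"),
    ("isability", "izability"), ("isable", "izable"),
)
_BRITISH_EXCEPTIONS = frozenset({
    "wise", "otherwise", "likewise", "clockwise", "promise", "premise",
    "expertise", "exercise", "comprise", "precise", "concise", "disguise",
    "advise", "raise", "praise", "surprise", "devise", "revise", "arise",
    "noise", "disease",
})
_BRITISH_WORDS = {
    "centre": "center", "centres": "centers", "multicentre": "multicenter",
    "colour": "color", "behaviour": "behavior", "oedema": "edema",
    "anaemia": "anemia", "foetal": "fetal", "paediatric": "pediatric",
}

#: Irregular or domain-critical forms the suffix rules would mangle.
_IRREGULAR = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "underwent": "undergo", "undergone": "undergo", "undergoing": "undergo",
    "withdrew": "withdraw", "withdrawn": "withdraw", "withdrawing": "withdraw",
    "withdrawal": "withdrawal", "withdrawals": "withdrawal",
    "lost": "lose", "losing": "lose", "loses": "lose",
    "took": "take", "taken": "take",
    "gave": "give", "given": "give",
    "shown": "show", "showed": "show",
    "criteria": "criterion",
    "analyses": "analysis", "analysed": "analyze", "analysing": "analyzing",
    "men": "man", "women": "woman", "children": "child",
    "completed": "complete", "completing": "complete", "completes": "complete",
    "changed": "change", "changing": "change",
    "included": "include", "including": "include",
    "excluded": "exclude", "excluding": "exclude",
    "enrolled": "enrol", "enrolling": "enrol", "enrols": "enrol",
    "enrolls": "enrol", "enroll": "enrol",
    "controlled": "control", "controlling": "control",
    "discontinued": "discontinue", "discontinuing": "discontinue",
    "dispensed": "dispense", "dispensing": "dispense",
    "described": "describe", "describing": "describe",
    "achieved": "achieve", "achieving": "achieve",
    "received": "receive", "receiving": "receive",
    "used": "use", "using": "use",
    "died": "die", "dying": "die",
    "ended": "end", "ending": "end",
    "bias": "bias", "biases": "bias", "biased": "bias",
    "monitored": "monitor", "monitoring": "monitoring",
}

# stems ending with these get a final 'e' restored after -ed/-ing stripping
_E_RESTORE = ("iz", "yz", "at", "iv", "ut", "uc", "as", "os")
_NO_DEDUP = frozenset("slfzw")
_VOWELS = frozenset("aeiou")


def _strip_inflection(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    for suffix in ("ing", "ed"):
        if word.endswith(suffix) and len(word) > len(suffix) + 2:
            stem = word[: -len(suffix)]
            if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _NO_DEDUP:
                stem = stem[:-1]
            elif stem.endswith(_E_RESTORE):
                stem += "e"
            if any(c in _VOWELS for c in stem):
                return stem
    if word.endswith("es") and len(word) > 4 and (
            word[-4:-2] in ("ss", "zz", "ch", "sh") or word[-3] == "x"):
        return word[:-2]
    if (word.endswith("s") and len(word) > 3
            and not word.endswith(("ss", "us", "is"))):
        return word[:-1]
    return word


@lru_cache(maxsize=65536)
def lemmatize_word(surface: str) -> str:
    """Deterministic lemma for one token (lowercased, spelling-normalized)."""
    w = surface.lower()
    if not w.isalpha() and "-" not in w and "'" not in w:
        return w
    w = _BRITISH_WORDS.get(w, w)
    if w not in _BRITISH_EXCEPTIONS:
        for brit, amer in _BRITISH_SUFFIXES:
            if w.endswith(brit):
                w = w[: -len(brit)] + amer
                break
    if w in _IRREGULAR:
        return _IRREGULAR[w]
    return _strip_inflection(w)


# ------------------------------------------------------------- annotation

_TOKEN_RE = re.compile(
    r"[A-Za-z][A-Za-z]*(?:[-'’][A-Za-z][A-Za-z]*)*|\d+(?:[.,]\d+)*%?|\S"
)

_VERB_SUFFIX = ("ed", "ing", "ize", "yze", "ify")
_ADJ_SUFFIX = ("al", "ive", "ous", "able", "ible", "ic")
_COMMON_VERBS = frozenset({
    "be", "have", "do", "use", "show", "include", "exclude", "receive",
    "assign", "randomize", "enrol", "recruit", "assess", "measure", "compare",
    "conceal", "blind", "mask", "stratify", "calculate", "detect", "report",
    "perform", "occur", "withdraw", "lose", "discontinue", "fund", "support",
    "register", "provide", "conduct", "undergo", "complete", "change",
})


def _coarse_pos(surface: str, lemma: str) -> str:
    if surface[0].isdigit():
        return "NUM"
    if not surface[0].isalpha():
        return "OTHER"
    if lemma in _COMMON_VERBS or lemma.endswith(_VERB_SUFFIX):
        return "VERB"
    if lemma.endswith(_ADJ_SUFFIX):
        return "ADJ"
    return "NOUN"


@dataclass(frozen=True)
class AnnotatedSentence:
    sentence: Sentence
    tokens: tuple[tuple[str, int, int], ...]  # (surface, start, end) in-sentence
    lemmas: tuple[str, ...]
    pos: tuple[str, ...]

    @property
    def text(self) -> str:
        return self.sentence.text


def annotate_sentence(sentence: Sentence) -> AnnotatedSentence:
    """Tokenize, lemmatize, and coarsely POS-tag one sentence."""
    if not sentence.text:
        raise ValueError("cannot annotate an empty sentence")
    tokens, lemmas, pos = [], [], []
    for m in _TOKEN_RE.finditer(sentence.text):
        surface = m.group(0)
        lemma = lemmatize_word(surface)
        tokens.append((surface, m.start(), m.end()))
        lemmas.append(lemma)
        pos.append(_coarse_pos(surface, lemma))
    return AnnotatedSentence(
        sentence=sentence, tokens=tuple(tokens),
        lemmas=tuple(lemmas), pos=tuple(pos),
    )


# ---------------------------------------------------------------- entities

ENTITY_KINDS = (
    "REGISTRY_ID", "ALLOCATION_RATIO", "CONFIDENCE_INTERVAL", "PERCENTAGE",
    "COUNT", "DATE_RANGE", "ORG", "LOCATION", "P_VALUE",
)


@dataclass(frozen=True)
class EntityMention:
    kind: str
    start: int
    end: int
    normalized: str


_MONTH = (r"(?:January|February|March|April|May|June|July|August|September|"
          r"October|November|December|Jan|Feb|Mar|Apr|Jun|Jul|Aug|Sep|Sept|"
          r"Oct|Nov|Dec)")

_ENTITY_PATTERNS = {
    "REGISTRY_ID": re.compile(
        r"\b(?:NCT\d{8}|ISRCTN\d{8}"
        r"|(?:EudraCT[ :,-]*(?:number\s*)?)?\d{4}-\d{6}-\d{2}"
        r"|ACTRN\d{14}|ChiCTR-?[A-Za-z0-9][A-Za-z0-9-]{4,}|UMIN\d{9})\b"
    ),
    "ALLOCATION_RATIO": re.compile(
        r"(?<![\d.:])\d{1,2}\s*:\s*\d{1,2}(?:\s*:\s*\d{1,2})?(?![\d.:])"
    ),
    "CONFIDENCE_INTERVAL": re.compile(
        r"\d{1,2}(?:\.\d+)?%\s*(?:CI|confidence\s+interval)"
        r"|\bCI\b\s*[,:]?\s*[-−]?\d+(?:\.\d+)?\s*(?:to|–|—|-|,)\s*"
        r"[-−]?\d+(?:\.\d+)?",
        re.IGNORECASE,
    ),
    "PERCENTAGE": re.compile(r"\d+(?:\.\d+)?\s*%"),
    "COUNT": re.compile(
        r"(?<![\w.,:%-])\d{1,3}(?:,\d{3})+(?![\w%.:])"
        r"|(?<![\w.,:%-])\d+(?![\w%.:,])"
    ),
    "DATE_RANGE": re.compile(
        _MONTH + r"\s+\d{4}\s*(?:to|through|until|and|–|—|-)\s*(?:"
        + _MONTH + r"\s+)?\d{4}"
    ),
    "P_VALUE": re.compile(r"\b[Pp](?:\s*value)?\s*[<=>≤≥]\s*0?\.\d+"),
}

_ORG_HEURISTIC = re.compile(
    r"(?:[A-Z][\w&'’.-]*\s+){0,6}"
    r"(?:Foundation|Institutes?|University|Council|Ministry|Society|"
    r"Association|Organi[sz]ation|Hospital|Centre|Center|Trust|Agency|"
    r"Pharmaceuticals|Inc|Ltd)\b"
)


def _gazetteer() -> dict[str, tuple[str, ...]]:
    return _load_gazetteer()


@lru_cache(maxsize=1)
def _load_gazetteer() -> dict[str, tuple[str, ...]]:
    text = resources.files("consort_check.data").joinpath("gazetteer.txt") \
        .read_text("utf-8")
    table: dict[str, list[str]] = {"ORG": [], "LOCATION": []}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, _, name = line.partition("\t")
        if kind not in table:
            raise ConfigurationError(f"gazetteer: unknown kind {kind!r}")
        table[kind].append(name.strip())
    # longest names first so greedy matching prefers the full span
    return {k: tuple(sorted(v, key=len, reverse=True)) for k, v in table.items()}


def _normalize_entity(kind: str, text: str) -> str:
    if kind == "REGISTRY_ID":
        compact = re.sub(r"\s+", "", text)
        m = re.search(r"\d{4}-\d{6}-\d{2}$", compact)
        return m.group(0) if m else compact  # EudraCT prefix stripped
    if kind == "ALLOCATION_RATIO":
        return re.sub(r"\s*", "", text)
    if kind == "CONFIDENCE_INTERVAL":
        m = re.match(r"(\d{1,2}(?:\.\d+)?)%", text)
        return f"{m.group(1)}% CI" if m else "CI"
    if kind in ("PERCENTAGE", "COUNT", "P_VALUE"):
        return re.sub(r"\s+", "", text)
    return re.sub(r"\s+", " ", text.strip())


def _keep_longest_nonoverlapping(spans: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    kept: list[tuple[int, int, str]] = []
    for start, end, text in sorted(spans, key=lambda s: (s[0], -(s[1] - s[0]))):
        if not kept or start >= kept[-1][1]:
            kept.append((start, end, text))
    return kept


def tag_entities(annotated: AnnotatedSentence) -> list[EntityMention]:
    """All pattern- and gazetteer-driven entities, longest-match per kind."""
    text = annotated.text
    mentions: list[EntityMention] = []
    for kind, pattern in _ENTITY_PATTERNS.items():
        spans = [(m.start(), m.end(), m.group(0)) for m in pattern.finditer(text)]
        for start, end, surf in _keep_longest_nonoverlapping(spans):
            mentions.append(EntityMention(kind, start, end,
                                          _normalize_entity(kind, surf)))
    gaz = _gazetteer()
    for kind in ("ORG", "LOCATION"):
        spans = []
        for name in gaz[kind]:
            for m in re.finditer(rf"(?<!\w){re.escape(name)}(?!\w)", text):
                spans.append((m.start(), m.end(), m.group(0)))
        if kind == "ORG":
            for m in _ORG_HEURISTIC.finditer(text):
                spans.append((m.start(), m.end(), m.group(0)))
        for start, end, surf in _keep_longest_nonoverlapping(spans):
            mentions.append(EntityMention(kind, start, end,
                                          _normalize_entity(kind, surf)))
    mentions.sort(key=lambda e: (e.start, e.end, e.kind))
    return mentions


# -------------------------------------------------------------- cue match

@dataclass(frozen=True)
class CuePattern:
    cue_id: str
    lemma_sequence: tuple[str, ...] | None = None
    regex: str | None = None
    scope: tuple[str, ...] | None = None  # section filter, None = everywhere
    weight: str = "required"  # required | supporting

    def __post_init__(self) -> None:
        if self.lemma_sequence is None and self.regex is None:
            raise ConfigurationError(
                f"cue {self.cue_id}: needs a lemma_sequence or a regex"
            )


@dataclass(frozen=True)
class CueHit:
    cue_id: str
    start: int
    end: int


@lru_cache(maxsize=1024)
def _compiled(cue_id: str, pattern: str) -> re.Pattern:
    try:
        return re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ConfigurationError(f"cue {cue_id}: bad regex: {exc}") from exc


def match_cues(annotated: AnnotatedSentence,
               patterns: list[CuePattern]) -> list[CueHit]:
    """Evaluate every pattern; return all hits (overlaps are not suppressed).

    Lemma sequences match contiguously over the lemma stream; regexes match
    the raw sentence text.  Section-scoped cues are skipped outside their
    scope.
    """
    hits: list[CueHit] = []
    lemmas = annotated.lemmas
    tokens = annotated.tokens
    label = annotated.sentence.section_label
    for pat in patterns:
        if pat.scope is not None and label not in pat.scope:
            continue
        if pat.lemma_sequence is not None:
            seq = pat.lemma_sequence
            k = len(seq)
            for i in range(len(lemmas) - k + 1):
                if tuple(lemmas[i:i + k]) == seq:
                    hits.append(CueHit(pat.cue_id, tokens[i][1],
                                       tokens[i + k - 1][2]))
        if pat.regex is not None:
            for m in _compiled(pat.cue_id, pat.regex).finditer(annotated.text):
                hits.append(CueHit(pat.cue_id, m.start(), m.end()))
    hits.sort(key=lambda h: (h.start, h.end, h.cue_id))
    return hits
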