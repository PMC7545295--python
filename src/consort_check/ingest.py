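"""Document ingestion: PDF/plain-text input, section segmentation, sentences.

The pipeline's native input is a small plain-text dialect (optional ``TITLE:``
line, headings on their own line, ``Figure N.``/``Table N.`` caption lines);
PDF support is an adapter in front of it so the detector logic never touches
binary parsing.  Segmentation canonicalizes printed headings against a synonym
lexicon into the IMRaD labels used by the checklist, and sentence splitting
records exact character offsets so every detected sentence can be traced back
to the manuscript.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace

from . import _pdf

__all__ = [
    "IngestError",
    "RawDocument",
    "Sentence",
    "Section",
    "Manuscript",
    "extract_pdf_text",
    "parse_plaintext",
    "segment_sections",
    "split_sentences",
    "ingest_path",
]

SECTION_LABELS = (
    "ABSTRACT", "INTRODUCTION", "METHODS", "RESULTS",
    "DISCUSSION", "OTHER_INFO", "UNLABELED",
)

#: Printed-heading synonyms, lowercased, mapped to canonical labels.
#: REFERENCES is internal: such sections keep label UNLABELED but are flagged
#: out of detection scope (citations otherwise trigger keyword cues).
HEADING_SYNONYMS: dict[str, str] = {}
for _label, _names in {
    "ABSTRACT": ("abstract", "summary", "structured abstract"),
    "INTRODUCTION": ("introduction", "background"),
    "METHODS": (
        "methods", "method", "patients and methods", "materials and methods",
        "subjects and methods", "participants and methods", "methods and materials",
    ),
    "RESULTS": ("results", "findings"),
    "DISCUSSION": ("discussion", "comment", "comments"),
    "OTHER_INFO": (
        "acknowledgments", "acknowledgements", "funding", "trial registration",
        "other information", "declarations", "funding and support",
        "acknowledgments and funding", "data sharing",
    ),
    "REFERENCES": ("references", "bibliography", "literature cited"),
}.items():
    for _n in _names:
        HEADING_SYNONYMS[_n] = _label

_CAPTION_RE = re.compile(r"^(Figure|Fig\.?|Table)\s+([A-Za-z0-9]+)\s*[.:]\s*(.*)$")

#: Abbreviations after which a period never ends a sentence.  Checked as
#: whole final tokens ("forms." must not match "ms."); "et al." is handled
#: as a two-token unit.
PROTECTED_ABBREVIATIONS = (
    "e.g.", "i.e.", "vs.", "dr.", "fig.", "no.", "approx.",
    "mr.", "ms.", "prof.", "st.", "etc.",
)


class IngestError(Exception):
    """Unreadable or unsupported manuscript input."""


@dataclass(frozen=True)
class Sentence:
    """One sentence within a section body (0-based, half-open offsets)."""

    text: str
    section_label: str
    index: int
    start: int
    end: int


@dataclass
class Section:
    canonical_label: str
    raw_heading: str
    body: str
    sentences: list[Sentence] = field(default_factory=list)
    in_scope: bool = True  # False for reference lists


@dataclass
class RawDocument:
    pages: list[str]
    source_kind: str  # "pdf" | "text"
    warnings: list[str] = field(default_factory=list)


@dataclass
class Manuscript:
    title: str
    sections: list[Section]
    captions: list[tuple[str, str, str]]  # (kind, label, text)
    warnings: list[str] = field(default_factory=list)

    def section(self, label: str) -> Section | None:
        for sec in self.sections:
            if sec.canonical_label == label and sec.in_scope:
                return sec
        return None

    def sentence_at(self, section_label: str, index: int) -> Sentence | None:
        sec = self.section(section_label)
        if sec is None or not 0 <= index < len(sec.sentences):
            return None
        return sec.sentences[index]

    def flatten(self) -> str:
        """Re-emit the manuscript in the plain-text dialect."""
        parts = [f"TITLE: {self.title}", ""]
        for sec in self.sections:
            if sec.raw_heading:
                parts.append(sec.raw_heading)
            parts.append(sec.body)
            parts.append("")
        for _kind, label, text in self.captions:
            parts.append(f"{label}. {text}")
        return "\n".join(parts)


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFC", text)
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    # drop raw control characters other than newline and tab
    return "".join(ch for ch in text if ch == "\n" or ch == "\t" or ord(ch) >= 32)


def parse_plaintext(text: str) -> RawDocument:
    """Wrap dialect plain text as a single-page :class:`RawDocument`."""
    if text is None:
        raise IngestError("text must not be None")
    return RawDocument(pages=[_normalize(text)] if text else [], source_kind="text")


def extract_pdf_text(pdf_path) -> RawDocument:
    """Extract per-page text from a text-layer PDF.

    Multi-column pages written by the fixture generator are linearized
    column-major (the order the text was typeset in).  Line-break hyphenation
    is repaired when the fragment clearly ends mid-token.
    """
    try:
        with open(pdf_path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise IngestError(f"cannot read {pdf_path}: {exc}") from exc
    try:
        pages = _pdf.extract_page_texts(data)
    except _pdf.PdfError as exc:
        raise IngestError(str(exc)) from exc
    return RawDocument(pages=[_normalize(p) for p in pages], source_kind="pdf")


def _match_heading(line: str) -> str | None:
    stripped = line.strip().rstrip(":").strip()
    if not stripped or len(stripped) > 60:
        return None
    return HEADING_SYNONYMS.get(stripped.lower())


def segment_sections(raw: RawDocument) -> Manuscript:
    """Reconstruct title, canonical sections, and figure/table captions."""
    if not raw.pages:
        raise IngestError("document has no pages")
    text = "\n".join(raw.pages)
    lines = text.split("\n")
    warnings = list(raw.warnings)

    title = ""
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        if s.upper().startswith("TITLE:"):
            title = s[6:].strip()
        elif _match_heading(s) is None:
            title = s
        else:
            i -= 1  # first content line is a heading; no title line
        break
    body_lines = lines[i + 1:]

    captions: list[tuple[str, str, str]] = []
    # (canonical, raw_heading, in_scope, lines)
    chunks: list[tuple[str, str, bool, list[str]]] = []
    current: tuple[str, str, bool, list[str]] | None = None
    saw_heading = False
    in_caption = False
    for line in body_lines:
        cm = _CAPTION_RE.match(line.strip())
        if cm:
            kind = "table" if cm.group(1).lower().startswith("table") else "figure"
            word = "Table" if kind == "table" else "Figure"
            captions.append((kind, f"{word} {cm.group(2)}", cm.group(3).strip()))
            in_caption = True
            continue
        if not line.strip():
            in_caption = False
        label = _match_heading(line)
        if in_caption and label is None:
            # wrapped caption continuation (PDF extraction breaks long lines)
            kind, cap_label, cap_text = captions[-1]
            captions[-1] = (kind, cap_label, (cap_text + " " + line.strip()).strip())
            continue
        if label is not None:
            in_caption = False
            saw_heading = True
            in_scope = label != "REFERENCES"
            canonical = "UNLABELED" if label == "REFERENCES" else label
            current = (canonical, line.strip(), in_scope, [])
            chunks.append(current)
            continue
        if current is None:
            if line.strip():
                current = ("INTRODUCTION", "", True, [])
                chunks.append(current)
            else:
                continue
        current[3].append(line)

    if not saw_heading and chunks:
        chunks = [("UNLABELED", "", True, [c for ch in chunks for c in ch[3]])]
        warnings.append("no recognizable section headings; using a single "
                        "UNLABELED section")

    # merge chunks sharing (label, scope) so sentence coordinates are unique
    merged: dict[tuple[str, bool], Section] = {}
    ordered: list[Section] = []
    for canonical, heading, in_scope, body in chunks:
        body_text = "\n".join(body).strip("\n")
        key = (canonical, in_scope)
        if key in merged:
            sec = merged[key]
            sec.body = (sec.body + "\n" + body_text).strip("\n")
        else:
            sec = Section(canonical, heading, body_text, in_scope=in_scope)
            merged[key] = sec
            ordered.append(sec)
    for sec in ordered:
        sec.sentences = split_sentences(sec.body, sec.canonical_label)

    return Manuscript(title=title, sections=ordered, captions=captions,
                      warnings=warnings)


_OPENERS = "([{"
_CLOSERS = ")]}"


def _ends_with_abbreviation(body: str, pos: int) -> bool:
    head = body[: pos + 1].lower()
    if head.endswith("et al."):
        return True
    for abbr in PROTECTED_ABBREVIATIONS:
        if head.endswith(abbr):
            before = len(head) - len(abbr) - 1
            if before < 0 or not head[before].isalpha():
                return True
    return False


def split_sentences(body: str, section_label: str = "UNLABELED") -> list[Sentence]:
    """Split a section body into sentences with exact character offsets.

    Boundaries sit at ``. ? !`` followed by whitespace and an uppercase letter
    or digit; suppressed after protected abbreviations and inside bracketed
    spans.  Reassembling ``body[start:end]`` spans plus the whitespace gaps
    reproduces the body byte-for-byte.
    """
    sentences: list[Sentence] = []
    n = len(body)

    def first_nonspace(from_pos: int) -> int:
        while from_pos < n and body[from_pos].isspace():
            from_pos += 1
        return from_pos

    start = first_nonspace(0)
    depth = 0
    pos = start
    while pos < n:
        ch = body[pos]
        if ch in _OPENERS:
            depth += 1
        elif ch in _CLOSERS:
            depth = max(0, depth - 1)
        elif ch in ".?!" and depth == 0:
            j = pos + 1
            if j < n and body[j].isspace():
                k = first_nonspace(j)
                if k < n and (body[k].isupper() or body[k].isdigit()):
                    if not (ch == "." and _ends_with_abbreviation(body, pos)):
                        sentences.append(Sentence(
                            text=body[start:pos + 1],
                            section_label=section_label,
                            index=len(sentences),
                            start=start, end=pos + 1,
                        ))
                        start = k
                        pos = k
                        continue
        pos += 1

    if start < n:
        end = n
        while end > start and body[end - 1].isspace():
            end -= 1
        if end > start:
            sentences.append(Sentence(
                text=body[start:end], section_label=section_label,
                index=len(sentences), start=start, end=end,
            ))
    return sentences


def ingest_path(path) -> Manuscript:
    """Convenience: read a ``.pdf`` or plain-text file and segment it."""
    p = str(path)
    if p.lower().endswith(".pdf"):
        raw = extract_pdf_text(p)
    else:
        try:
            with open(p, encoding="utf-8") as fh:
                raw = parse_plaintext(fh.read())
        except OSError as exc:
            raise IngestError(f"cannot read {p}: {exc}") from exc
    return segment_sections(raw)
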