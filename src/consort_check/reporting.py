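"""Rendering of the filled checklist and notification summary.

Outputs: a lossless JSON report, a markdown checklist/notifications pair, and
a minimal-but-valid ``.docx`` rendering (WordprocessingML written with the
standard-library ``zipfile``; no Word automation involved).  Markdown and docx
renderings of the same report contain identical cell texts: both are built
from :func:`build_rows`.

The original checklist's "reported on page" column is replaced by a section
reference plus sentence excerpt, because page identity does not survive text
linearization from PDF.
"""

from __future__ import annotations

import json
import os
import tempfile
import zipfile
from xml.sax.saxutils import escape

from .detectors import ChecklistReport, ItemMatch
from .registry import Registry, load_registry

__all__ = [
    "to_json_report",
    "from_json_report",
    "build_rows",
    "render_checklist_markdown",
    "render_notifications_markdown",
    "render_checklist_docx",
    "render_notifications_docx",
    "write_text_atomic",
]

SCHEMA_VERSION = 1
EXCERPT_LIMIT = 300


# ------------------------------------------------------------------- JSON

def to_json_report(report: ChecklistReport) -> str:
    """Serialize a report losslessly; ``from_json_report`` inverts exactly."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "source": report.source,
        "warnings": list(report.warnings),
        "matches": [
            {
                "item_id": m.item_id,
                "status": m.status,
                "matched": [list(t) for t in m.matched],
                "notification_code": m.notification_code,
                "message": m.message,
            }
            for m in report.matches.values()
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=False, ensure_ascii=False)


def from_json_report(text: str) -> ChecklistReport:
    payload = json.loads(text)
    matches = {}
    for rec in payload["matches"]:
        matches[rec["item_id"]] = ItemMatch(
            item_id=rec["item_id"],
            status=rec["status"],
            matched=tuple((s, i, t) for s, i, t in rec["matched"]),
            notification_code=rec.get("notification_code"),
            message=rec.get("message", ""),
        )
    return ChecklistReport(source=payload.get("source", ""),
                           matches=matches,
                           warnings=list(payload.get("warnings", [])))


# ------------------------------------------------------------------- rows

_NICE = {
    "INTRODUCTION": "Introduction", "METHODS": "Methods", "RESULTS": "Results",
    "DISCUSSION": "Discussion", "OTHER_INFO": "Other information",
    "ABSTRACT": "Abstract", "UNLABELED": "Unlabeled", "TITLE": "Title",
}


def _excerpt(text: str) -> str:
    if len(text) <= EXCERPT_LIMIT:
        return text
    return text[: EXCERPT_LIMIT - 1] + "…"


def build_rows(report: ChecklistReport,
               registry: Registry | None = None) -> list[tuple[str, str, str]]:
    """(item_id, prompt, reported-location) for all 37 rows in CONSORT order."""
    registry = registry if registry is not None else load_registry()
    rows = []
    for item in registry:
        m = report.matches[item.item_id]
        if m.status == "not_implemented":
            cell = "Not implemented"
        elif m.status == "not_found":
            cell = "Not found"
        elif m.status == "found":
            sec, _idx, text = m.matched[0]
            cell = f"{_NICE.get(sec, sec)}: “{_excerpt(text)}”"
        else:  # notification
            cell = f"Notification: {m.message}"
            if m.matched:
                sec, _idx, text = m.matched[0]
                cell += f" ({_NICE.get(sec, sec)}: “{_excerpt(text)}”)"
        rows.append((item.item_id, item.prompt, cell))
    return rows


# --------------------------------------------------------------- markdown

def render_checklist_markdown(report: ChecklistReport,
                              registry: Registry | None = None) -> str:
    rows = build_rows(report, registry)
    out = [
        "# CONSORT 2010 checklist",
        "",
        f"Source: {report.source or '(unnamed manuscript)'}",
        "",
        "| Item | Checklist description | Reported |",
        "| --- | --- | --- |",
    ]
    for item_id, prompt, cell in rows:
        out.append(f"| {item_id} | {_md(prompt)} | {_md(cell)} |")
    return "\n".join(out) + "\n"


def render_notifications_markdown(report: ChecklistReport) -> str:
    out = ["# Notifications", ""]
    notes = report.notifications()
    if not notes:
        out.append("No notifications.")
    else:
        for m in notes:
            out.append(f"- **Item {m.item_id}** [{m.notification_code}]: "
                       f"{_md(m.message)}")
    return "\n".join(out) + "\n"


def _md(text: str) -> str:
    return text.replace("|", "\\|").replace("\n", " ")


# ------------------------------------------------------------------- docx

_CONTENT_TYPES = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="http://schemas.openxmlformats.org/package/2006/content-types">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Override PartName="/word/document.xml" ContentType="application/vnd.openxmlformats-officedocument.wordprocessingml.document.main+xml"/>
</Types>
"""

_RELS = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="word/document.xml"/>
</Relationships>
"""

_W = "http://schemas.openxmlformats.org/wordprocessingml/2006/main"


def _para(text: str, bold: bool = False) -> str:
    rpr = "<w:rPr><w:b/></w:rPr>" if bold else ""
    return (f"<w:p><w:r>{rpr}<w:t xml:space=\"preserve\">{escape(text)}"
            f"</w:t></w:r></w:p>")


def _cell(text: str) -> str:
    return f"<w:tc>{_para(text)}</w:tc>"


def _docx_bytes(body_xml: str) -> list[tuple[str, str]]:
    document = (
        f"<?xml version=\"1.0\" encoding=\"UTF-8\" standalone=\"yes\"?>"
        f"<w:document xmlns:w=\"{_W}\"><w:body>{body_xml}"
        f"<w:sectPr/></w:body></w:document>"
    )
    return [
        ("[Content_Types].xml", _CONTENT_TYPES),
        ("_rels/.rels", _RELS),
        ("word/document.xml", document),
    ]


def _write_docx(path, body_xml: str) -> None:
    tmp_fd, tmp_path = tempfile.mkstemp(dir=os.path.dirname(os.path.abspath(path))
                                        or ".", suffix=".docx.tmp")
    os.close(tmp_fd)
    try:
        with zipfile.ZipFile(tmp_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, content in _docx_bytes(body_xml):
                zf.writestr(name, content)
        os.replace(tmp_path, path)
    except OSError:
        if os.path.exists(tmp_path):
            os.unlink(tmp_path)
        raise


def render_checklist_docx(report: ChecklistReport, path,
                          registry: Registry | None = None) -> None:
    """Write the filled checklist as a one-table .docx document."""
    rows = build_rows(report, registry)
    parts = [_para("CONSORT 2010 checklist", bold=True),
             _para(f"Source: {report.source or '(unnamed manuscript)'}")]
    header = "".join(_cell(h) for h in ("Item", "Checklist description",
                                        "Reported"))
    body_rows = "".join(
        f"<w:tr>{_cell(i)}{_cell(p)}{_cell(c)}</w:tr>" for i, p, c in rows
    )
    parts.append(f"<w:tbl><w:tr>{header}</w:tr>{body_rows}</w:tbl>")
    _write_docx(path, "".join(parts))


def render_notifications_docx(report: ChecklistReport, path) -> None:
    parts = [_para("Notifications", bold=True)]
    notes = report.notifications()
    if not notes:
        parts.append(_para("No notifications."))
    for m in notes:
        parts.append(_para(f"Item {m.item_id} [{m.notification_code}]: "
                           f"{m.message}"))
    _write_docx(path, "".join(parts))


def write_text_atomic(path, text: str) -> None:
    """Write text via a temp file + rename so outputs are never partial."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    tmp_fd, tmp_path = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(tmp_fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp_path, path)
    except OSError:
        if os.path.exists(tmp_path):
            os.unlink(tmp_path)
        raise
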