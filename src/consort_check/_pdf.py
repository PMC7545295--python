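"""Minimal PDF writer/reader for text-layer PDFs.

This is deliberately not a general PDF library.  It supports exactly what the
pipeline needs: writing simple one- or two-column text PDFs (used by the
synthetic-corpus generator) and recovering per-page text in reading order from
PDFs whose content streams use the standard ``Tj``/``TJ`` text-showing
operators (uncompressed or Flate-compressed).  Encrypted files and files
without a text layer are rejected with specific errors.
"""

from __future__ import annotations

import re
import zlib

__all__ = [
    "PdfError",
    "PdfFormatError",
    "PdfEncryptedError",
    "PdfNoTextError",
    "write_pdf",
    "extract_page_texts",
]


class PdfError(Exception):
    pass


class PdfFormatError(PdfError):
    """The bytes are not a PDF file."""


class PdfEncryptedError(PdfError):
    """The PDF is encrypted; decryption is unsupported."""


class PdfNoTextError(PdfError):
    """The PDF has pages but no extractable text layer (image-only scan)."""


# ---------------------------------------------------------------- writing

_PAGE_W, _PAGE_H = 612, 792  # US letter, points
_MARGIN = 50
_LEADING = 12
_FONT_SIZE = 9


def _escape_string(s: str) -> str:
    out = []
    for ch in s:
        o = ord(ch)
        if ch in "\\()":
            out.append("\\" + ch)
        elif 32 <= o < 127:
            out.append(ch)
        elif o < 256:
            out.append(f"\\{o:03o}")
        else:
            raise ValueError(f"character {ch!r} not representable in simple PDF text")
    return "".join(out)


def _wrap_line(line: str, width: int) -> list[str]:
    if len(line) <= width:
        return [line]
    words, out, cur = line.split(" "), [], ""
    for w in words:
        cand = w if not cur else cur + " " + w
        if len(cand) <= width or not cur:
            cur = cand
        else:
            out.append(cur)
            cur = w
    if cur:
        out.append(cur)
    return out


def _page_stream(lines: list[str], columns: int) -> bytes:
    """Lay lines out top-to-bottom (column-major for two columns)."""
    per_col = (_PAGE_H - 2 * _MARGIN) // _LEADING
    col_w = (_PAGE_W - 2 * _MARGIN) // columns
    ops = ["BT", f"/F1 {_FONT_SIZE} Tf"]
    for i, line in enumerate(lines):
        col, row = divmod(i, per_col)
        if col >= columns:  # overflow is the caller's problem; clamp
            col, row = columns - 1, per_col - 1
        x = _MARGIN + col * col_w
        y = _PAGE_H - _MARGIN - row * _LEADING
        ops.append(f"1 0 0 1 {x} {y} Tm ({_escape_string(line)}) Tj")
    ops.append("ET")
    return "\n".join(ops).encode("latin-1")


def write_pdf(path, pages: list[list[str]], columns: int = 1) -> None:
    """Write ``pages`` (lists of text lines) as an uncompressed PDF.

    With ``columns=2`` each page is typeset in two columns filled
    column-major, i.e. the stream order (= reading order) is preserved.
    """
    if columns not in (1, 2):
        raise ValueError("columns must be 1 or 2")
    objs: list[bytes] = []
    n_pages = len(pages)
    page_obj_nums = [4 + 2 * i for i in range(n_pages)]
    kids = " ".join(f"{n} 0 R" for n in page_obj_nums)
    objs.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objs.append(
        f"<< /Type /Pages /Kids [{kids}] /Count {n_pages} >>".encode("latin-1")
    )
    objs.append(
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>"
    )
    bodies: list[bytes] = []
    for i, lines in enumerate(pages):
        stream = _page_stream(lines, columns)
        page = (
            f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 {_PAGE_W} {_PAGE_H}] "
            f"/Resources << /Font << /F1 3 0 R >> >> /Contents {5 + 2 * i} 0 R >>"
        ).encode("latin-1")
        objs.append(page)
        objs.append(
            b"<< /Length %d >>\nstream\n%s\nendstream" % (len(stream), stream)
        )
        bodies.append(stream)
    buf = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for num, obj in enumerate(objs, start=1):
        offsets.append(len(buf))
        buf += b"%d 0 obj\n" % num + obj + b"\nendobj\n"
    xref_off = len(buf)
    buf += b"xref\n0 %d\n" % (len(objs) + 1)
    buf += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        buf += b"%010d 00000 n \n" % off
    buf += (
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objs) + 1, xref_off)
    )
    with open(path, "wb") as fh:
        fh.write(bytes(buf))


def wrap_text_pages(text: str, width: int = 88, lines_per_page: int = 114,
                    columns: int = 1) -> list[list[str]]:
    """Wrap manuscript text into page line-lists suitable for ``write_pdf``."""
    if columns == 2:
        width = 40
        lines_per_page *= 2
    lines: list[str] = []
    title_seen = False
    for raw in text.split("\n"):
        if not raw:
            lines.append("")
        elif not title_seen:
            lines.append(raw)  # keep the title on one physical line
            title_seen = True
        else:
            lines.extend(_wrap_line(raw, width))
    return [lines[i:i + lines_per_page] for i in range(0, len(lines), lines_per_page)] or [[]]


# ---------------------------------------------------------------- reading

_STREAM_RE = re.compile(rb"<<(.*?)>>\s*stream\r?\n(.*?)\r?\nendstream", re.S)
_TJ_RE = re.compile(rb"\((?P<s>(?:\\.|[^\\()])*)\)\s*Tj|\[(?P<a>[^\]]*)\]\s*TJ")
_PAGE_RE = re.compile(rb"/Type\s*/Page\b(?!s)")


def _unescape_string(raw: bytes) -> str:
    out, i = [], 0
    simple = {b"n": "\n", b"r": "\r", b"t": "\t", b"b": "\b", b"f": "\f",
              b"(": "(", b")": ")", b"\\": "\\"}
    while i < len(raw):
        c = raw[i:i + 1]
        if c == b"\\":
            nxt = raw[i + 1:i + 2]
            if nxt.isdigit():
                oct_digits = raw[i + 1:i + 4]
                m = re.match(rb"[0-7]{1,3}", oct_digits)
                out.append(chr(int(m.group(0), 8)))
                i += 1 + len(m.group(0))
            else:
                out.append(simple.get(nxt, nxt.decode("latin-1")))
                i += 2
        else:
            out.append(c.decode("latin-1"))
            i += 1
    return "".join(out)


def _stream_text(content: bytes) -> str | None:
    """Extract shown text from one content stream; None if no text ops."""
    if b"BT" not in content:
        return None
    lines = []
    for m in _TJ_RE.finditer(content):
        if m.group("s") is not None:
            lines.append(_unescape_string(m.group("s")))
        else:  # TJ array: concatenate its string elements
            parts = re.findall(rb"\((?:\\.|[^\\()])*\)", m.group("a"))
            lines.append("".join(_unescape_string(p[1:-1]) for p in parts))
    if not lines:
        return None
    return "\n".join(lines)


def _dehyphenate(text: str) -> str:
    # join "frag-\ncontinuation" when the break is clearly mid-token
    return re.sub(r"([A-Za-z]{2,})-\n([a-z])", r"\1\2", text)


def extract_page_texts(data: bytes) -> list[str]:
    """Return per-page text (reading order) from raw PDF bytes.

    Raises ``PdfFormatError`` for non-PDF input, ``PdfEncryptedError`` for
    encrypted files, and ``PdfNoTextError`` when pages exist but carry no
    text-showing operators.
    """
    if not data.lstrip()[:5] == b"%PDF-":
        raise PdfFormatError("input does not look like a PDF (missing %PDF- header)")
    if re.search(rb"/Encrypt\b", data):
        raise PdfEncryptedError("PDF is encrypted; cannot extract text")
    n_pages = len(_PAGE_RE.findall(data))
    if n_pages == 0:
        return []
    texts: list[str] = []
    for m in _STREAM_RE.finditer(data):
        head, content = m.group(1), m.group(2)
        if b"/FlateDecode" in head:
            try:
                content = zlib.decompress(content)
            except zlib.error:
                continue
        text = _stream_text(content)
        if text is not None:
            texts.append(_dehyphenate(text))
    if not texts:
        raise PdfNoTextError(
            "PDF has no text layer (image-only scan?); OCR is out of scope"
        )
    return texts
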