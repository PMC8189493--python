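"""Document model: section-structured articles and sentence segmentation.

Full-text articles arrive either as JATS XML (the PMC article tag suite) or as
plain text with blank-line paragraph breaks.  Both are normalised into a
:class:`Document`: an ordered list of named sections, each an ordered list of
paragraph strings, with figure/table legends flagged so that downstream snippet
windows can treat them as their own context units.

Sentence segmentation is rule-based and abbreviation-aware.  Biomedical prose
is dense with dotted abbreviations ("Cat. No. 803003", "Fig. 2", "et al.") that
naive terminal-punctuation splitting would shred, and the snippet windows built
on top of these sentences are the unit of every later classification step, so
the segmenter errs on the side of not splitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from lxml import etree

__all__ = [
    "Document",
    "Section",
    "SentenceSpan",
    "SentenceSegmenter",
    "parse_document",
    "split_sentences",
]


class ParseError(ValueError):
    """Raised when an input document cannot be parsed."""


@dataclass(frozen=True)
class Section:
    """A named block of paragraphs; legends are flagged separately."""

    name: str
    paragraphs: tuple[str, ...]
    is_legend: bool = False

    def __post_init__(self) -> None:
        if any(not p.strip() for p in self.paragraphs):
            raise ValueError("paragraphs must be non-empty strings")


@dataclass(frozen=True)
class Document:
    """A parsed article: an identifier plus ordered sections."""

    doc_id: str
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def iter_paragraphs(self) -> Iterable[tuple[int, Section, str]]:
        """Yield (global paragraph index, owning section, paragraph text)."""
        idx = 0
        for sec in self.sections:
            for para in sec.paragraphs:
                yield idx, sec, para
                idx += 1


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence with half-open character offsets into its paragraph."""

    text: str
    para_index: int
    sent_index: int
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError("require 0 <= char_start < char_end")


# Dotted tokens that must never terminate a sentence.  Case matters for a few
# ("No." the abbreviation vs "no." ending a clause is rare enough to ignore).
_DEFAULT_ABBREVIATIONS = frozenset(
    {
        "al",
        "approx",
        "cat",
        "cf",
        "dr",
        "e.g",
        "eq",
        "eqs",
        "et",
        "et al",
        "etc",
        "fig",
        "figs",
        "i.e",
        "inc",
        "jr",
        "ltd",
        "no",
        "nos",
        "prof",
        "ref",
        "refs",
        "sec",
        "st",
        "suppl",
        "tab",
        "vol",
        "vs",
    }
)

# A candidate boundary: terminal punctuation, optional closing bracket/quote,
# then whitespace.  Whether it really ends a sentence is decided by context.
_BOUNDARY = re.compile(r"[.!?]+[)\]\"'”’]*\s+")
_WORD_BEFORE = re.compile(r"(\S+)$")


@dataclass
class SentenceSegmenter:
    """Rule-based sentence splitter with a pluggable abbreviation list.

    A period ends a sentence only when (a) the token carrying it is not a known
    abbreviation or a single initial, and (b) the following character opens a
    plausible new sentence (uppercase letter, digit or opening quote/bracket).
    """

    abbreviations: frozenset[str] = field(default_factory=lambda: _DEFAULT_ABBREVIATIONS)

    def split(self, paragraph: str, para_index: int = 0) -> list[SentenceSpan]:
        if not paragraph.strip():
            return []
        starts = [self._lstrip_offset(paragraph)]
        cuts: list[int] = []
        for m in _BOUNDARY.finditer(paragraph):
            if self._is_boundary(paragraph, m):
                cuts.append(m.end())
        spans: list[SentenceSpan] = []
        pos = starts[0]
        for cut in cuts + [len(paragraph)]:
            raw = paragraph[pos:cut]
            text = raw.rstrip()
            if not text.strip():
                pos = cut
                continue
            end = pos + len(text)
            spans.append(
                SentenceSpan(
                    text=paragraph[pos:end],
                    para_index=para_index,
                    sent_index=len(spans),
                    char_start=pos,
                    char_end=end,
                )
            )
            pos = cut
        return spans

    @staticmethod
    def _lstrip_offset(text: str) -> int:
        return len(text) - len(text.lstrip())

    def _is_boundary(self, text: str, m: re.Match) -> bool:
        punct = m.group(0).strip()
        # What follows must look like a sentence opener.
        nxt = text[m.end() : m.end() + 1]
        if nxt and not (nxt.isupper() or nxt.isdigit() or nxt in "\"'(“‘["):
            return False
        if not punct.startswith("."):
            return True  # ! and ? always terminate
        before = _WORD_BEFORE.search(text, 0, m.start() + 1)
        if before is None:
            return False
        token = before.group(1).rstrip(".").strip("()[]\"'“”")
        low = token.lower()
        if low in self.abbreviations:
            return False
        # Single uppercase initials ("A.") and dotted acronyms ("i.e.", "U.S.").
        if len(token) == 1 and token.isalpha() and token.isupper():
            return False
        if "." in token and all(len(p) <= 2 for p in token.split(".")):
            return False
        return True


_DEFAULT_SEGMENTER = SentenceSegmenter()


def split_sentences(
    paragraph: str,
    para_index: int = 0,
    segmenter: SentenceSegmenter | None = None,
) -> list[SentenceSpan]:
    """Split one paragraph into :class:`SentenceSpan` objects.

    Deterministic, offset-preserving: each span's text equals the paragraph
    slice at ``[char_start, char_end)``.  Whitespace-only input yields ``[]``.
    """
    seg = segmenter or _DEFAULT_SEGMENTER
    return seg.split(paragraph, para_index=para_index)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_LEGEND_TAGS = {"fig", "table-wrap", "boxed-text"}


def parse_document(raw: str, format: str = "plain", doc_id: str = "doc") -> Document:
    """Parse raw article text or JATS XML into a :class:`Document`.

    ``format="plain"``: paragraphs are separated by blank lines; a single
    unnamed body section is produced.  ``format="jats"``: each ``<sec>``
    becomes a section (title text as its name) and each ``<fig>``/
    ``<table-wrap>`` caption becomes a legend section.
    """
    if format not in {"jats", "plain"}:
        raise ValueError(f"unknown format {format!r}; expected 'jats' or 'plain'")
    if not raw or not raw.strip():
        raise ParseError("empty document")
    if format == "plain":
        paras = tuple(p.strip() for p in re.split(r"\n\s*\n", raw) if p.strip())
        return Document(doc_id=doc_id, sections=(Section(name="body", paragraphs=paras),))
    return _parse_jats(raw, doc_id)


def _text_of(el: etree._Element) -> str:
    return re.sub(r"\s+", " ", "".join(el.itertext())).strip()


def _parse_jats(raw: str, doc_id: str) -> Document:
    try:
        root = etree.fromstring(raw.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc

    # Prefer an explicit article id when present.
    for el in root.iter("article-id"):
        if _text_of(el):
            doc_id = _text_of(el)
            break

    sections: list[Section] = []

    def walk(node: etree._Element) -> None:
        for child in node:
            tag = etree.QName(child).localname if isinstance(child.tag, str) else ""
            if tag == "sec":
                title = child.find("title")
                name = _text_of(title) if title is not None else "section"
                paras = tuple(
                    _text_of(p)
                    for p in child.iterchildren("p")
                    if _text_of(p)
                )
                if paras:
                    sections.append(Section(name=name or "section", paragraphs=paras))
                walk(child)
            elif tag in _LEGEND_TAGS:
                caption = child.find("caption")
                if caption is not None and _text_of(caption):
                    label = child.find("label")
                    name = _text_of(label) if label is not None else tag
                    sections.append(
                        Section(
                            name=name or tag,
                            paragraphs=(_text_of(caption),),
                            is_legend=True,
                        )
                    )
            else:
                walk(child)

    body = root.find("body") if root.find("body") is not None else root
    walk(body)
    if not sections:
        raise ParseError("no <sec> or legend content found in JATS body")
    return Document(doc_id=doc_id, sections=tuple(sections))
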