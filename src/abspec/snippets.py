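"""Snippet extraction: specificity-cue windows and single-RRID context windows.

Two kinds of evidence snippets are cut out of a parsed article:

* **Specificity snippets** — a window of at most three consecutive sentences
  from one paragraph, centred on a sentence matching a specificity cue
  (``specific``, ``background staining``, ``cross-reactiv``).  Snippets whose
  text never mentions an antibody are discarded, since bare "specific" is
  overwhelmingly about assays, primers or binding sites rather than reagents.

* **RRID snippets** — a window of at most three sentences around a mention of
  an antibody Research Resource Identifier (``AB_<digits>``), post-processed so
  that each snippet contains *exactly one* RRID: neighbouring sentences holding
  other RRIDs are dropped, and a sentence holding several RRIDs is split at the
  mention boundaries with only the target's sub-string retained.

Windows never cross a paragraph (or figure-legend) boundary, so snippets at a
boundary may hold fewer than three sentences.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .documents import Document, SentenceSpan, SentenceSegmenter, split_sentences

__all__ = [
    "DEFAULT_CUES",
    "ANTIBODY_PATTERN",
    "CueMatch",
    "SpecSnippet",
    "RRIDMention",
    "RRIDSnippet",
    "match_specificity_cues",
    "extract_spec_snippets",
    "filter_antibody_snippets",
    "find_antibody_mentions",
    "find_rrid_mentions",
    "extract_rrid_snippets",
    "write_snippets_jsonl",
    "read_snippets_jsonl",
]

# The three cue patterns, applied as unanchored substring regexes.  The set is
# deliberately small — a minimum filter, extensible through configuration.
DEFAULT_CUES: Mapping[str, str] = {
    "specific": r"(S|s)pecific",
    "background-staining": r"((B|b)ackground staining)",
    "cross-reactiv": r"(C|c)ross(|-)reactiv",
}

ANTIBODY_PATTERN = re.compile(r"(A|a)ntibod(y|ies)")

# AB_<digits> with a non-word guard so tokens like "LAB_123" never match, and
# an optional case-insensitive "RRID:" prefix absorbed into the raw surface.
_RRID_CORE = r"AB_[0-9]+"
_RRID_GUARDED = re.compile(r"(?<!\w)(?:(?i:RRID)\s*:\s*)?(" + _RRID_CORE + r")")
_RRID_BARE = re.compile(r"(?:(?i:RRID)\s*:\s*)?(" + _RRID_CORE + r")")
RRID_VALUE = re.compile(r"^AB_[0-9]+$")


@dataclass(frozen=True)
class CueMatch:
    cue: str
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class SpecSnippet:
    """A 1–3 sentence window around a specificity-cue sentence."""

    doc_id: str
    sentences: tuple[SentenceSpan, ...]
    center_index: int
    cue: str
    has_antibody_term: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.sentences) <= 3:
            raise ValueError("a snippet holds 1 to 3 sentences")
        if not 0 <= self.center_index < len(self.sentences):
            raise ValueError("center_index out of range")

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)

    @property
    def center_sentence(self) -> str:
        return self.sentences[self.center_index].text

    @property
    def para_index(self) -> int:
        return self.sentences[0].para_index


@dataclass(frozen=True)
class RRIDMention:
    rrid: str
    raw: str
    para_index: int
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not RRID_VALUE.match(self.rrid):
            raise ValueError(f"not a normalized antibody RRID: {self.rrid!r}")


@dataclass(frozen=True)
class RRIDSnippet:
    """A snippet containing exactly one RRID mention after isolation rules."""

    doc_id: str
    rrid: str
    text: str
    n_sentences: int
    para_index: int

    def __post_init__(self) -> None:
        if not RRID_VALUE.match(self.rrid):
            raise ValueError(f"not a normalized antibody RRID: {self.rrid!r}")
        if not 1 <= self.n_sentences <= 3:
            raise ValueError("a snippet holds 1 to 3 sentences")
        if len(_RRID_GUARDED.findall(self.text)) != 1:
            raise ValueError("RRID snippet must contain exactly one RRID mention")


def _compile_cues(cues: Mapping[str, str] | None) -> dict[str, re.Pattern]:
    return {name: re.compile(pat) for name, pat in (cues or DEFAULT_CUES).items()}


def match_specificity_cues(
    sentence: str, cues: Mapping[str, str] | None = None
) -> list[CueMatch]:
    """Return every cue match in a sentence (cue id plus match span)."""
    out: list[CueMatch] = []
    for name, pat in _compile_cues(cues).items():
        for m in pat.finditer(sentence):
            out.append(CueMatch(cue=name, start=m.start(), end=m.end(), text=m.group(0)))
    out.sort(key=lambda c: (c.start, c.end, c.cue))
    return out


def extract_spec_snippets(
    doc: Document,
    cues: Mapping[str, str] | None = None,
    segmenter: SentenceSegmenter | None = None,
) -> list[SpecSnippet]:
    """One snippet per cue-matching sentence, in document order.

    The cue sentence sits in the middle of the window, flanked by the previous
    and next sentence of the same paragraph where they exist.  Adjacent cue
    sentences each get their own (overlapping) snippet; no de-duplication.
    """
    compiled = _compile_cues(cues)
    snippets: list[SpecSnippet] = []
    for para_index, _sec, para in doc.iter_paragraphs():
        spans = split_sentences(para, para_index=para_index, segmenter=segmenter)
        for i, span in enumerate(spans):
            matched = [name for name, pat in compiled.items() if pat.search(span.text)]
            if not matched:
                continue
            lo = max(0, i - 1)
            hi = min(len(spans), i + 2)
            window = tuple(spans[lo:hi])
            snippets.append(
                SpecSnippet(
                    doc_id=doc.doc_id,
                    sentences=window,
                    center_index=i - lo,
                    cue=matched[0],
                )
            )
    return snippets


def filter_antibody_snippets(snippets: Sequence[SpecSnippet]) -> list[SpecSnippet]:
    """Keep snippets whose concatenated text mentions an antibody."""
    kept = []
    for sn in snippets:
        if ANTIBODY_PATTERN.search(sn.text):
            kept.append(dataclasses.replace(sn, has_antibody_term=True))
    return kept


def find_antibody_mentions(text: str) -> list[str]:
    """Surface forms of antibody-term mentions, in order of appearance."""
    return [m.group(0) for m in ANTIBODY_PATTERN.finditer(text)]


def find_rrid_mentions(
    text: str, para_index: int = 0, boundary_guard: bool = True
) -> list[RRIDMention]:
    """All antibody-RRID mentions in a text block.

    ``boundary_guard`` (default) requires a non-word character or string start
    before the match, rejecting embedded tokens such as ``LAB_123``.  The raw
    surface absorbs an optional ``RRID:`` prefix; ``rrid`` is the bare value.
    """
    pat = _RRID_GUARDED if boundary_guard else _RRID_BARE
    return [
        RRIDMention(
            rrid=m.group(1),
            raw=m.group(0),
            para_index=para_index,
            char_start=m.start(),
            char_end=m.end(),
        )
        for m in pat.finditer(text)
    ]


def _mentions_in(text: str) -> list[re.Match]:
    return list(_RRID_GUARDED.finditer(text))


def extract_rrid_snippets(
    doc: Document,
    segmenter: SentenceSegmenter | None = None,
    boundary_guard: bool = True,
) -> list[RRIDSnippet]:
    """One single-RRID snippet per RRID mention, in document order.

    Isolation rules: neighbouring sentences containing other RRIDs are not
    included; a sentence with several RRIDs is split at the character position
    immediately before each subsequent mention's raw surface, and only the
    sub-string holding the target mention is kept as the centre.
    """
    snippets: list[RRIDSnippet] = []
    for para_index, _sec, para in doc.iter_paragraphs():
        spans = split_sentences(para, para_index=para_index, segmenter=segmenter)
        per_sentence = [
            find_rrid_mentions(s.text, para_index=para_index, boundary_guard=boundary_guard)
            for s in spans
        ]
        for i, mentions in enumerate(per_sentence):
            if not mentions:
                continue
            for k, mention in enumerate(mentions):
                center = spans[i].text
                if len(mentions) > 1:
                    cuts = [m.char_start for m in mentions]
                    lo = cuts[k]if k > 0 else 0
                    hi = cuts[k + 1] if k + 1 < len(mentions) else len(center)
                    center = center[lo:hi].strip()
                parts: list[str] = []
                n = 1
                if i > 0 and not per_sentence[i - 1] and len(mentions) == 1:
                    parts.append(spans[i - 1].text)
                    n += 1
                parts.append(center)
                if i + 1 < len(spans) and not per_sentence[i + 1] and len(mentions) == 1:
                    parts.append(spans[i + 1].text)
                    n += 1
                snippets.append(
                    RRIDSnippet(
                        doc_id=doc.doc_id,
                        rrid=mention.rrid,
                        text=" ".join(parts),
                        n_sentences=n,
                        para_index=para_index,
                    )
                )
    return snippets


# ---------------------------------------------------------------------------
# JSONL interchange
# ---------------------------------------------------------------------------


def snippet_record(sn: SpecSnippet | RRIDSnippet) -> dict:
    if isinstance(sn, SpecSnippet):
        return {
            "doc_id": sn.doc_id,
            "kind": "spec",
            "text": sn.text,
            "sentences": [s.text for s in sn.sentences],
            "center_index": sn.center_index,
            "cue": sn.cue,
            "rrid": None,
        }
    return {
        "doc_id": sn.doc_id,
        "kind": "rrid",
        "text": sn.text,
        "sentences": None,
        "center_index": None,
        "cue": None,
        "rrid": sn.rrid,
    }


def write_snippets_jsonl(
    snippets: Iterable[SpecSnippet | RRIDSnippet], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sn in snippets:
            fh.write(json.dumps(snippet_record(sn), ensure_ascii=False) + "\n")


def read_snippets_jsonl(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]
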