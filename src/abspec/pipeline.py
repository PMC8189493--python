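"""End-to-end workflow: extract -> classify -> link -> knowledge-base triples.

For each document the pipeline extracts specificity and single-RRID snippets,
classifies each antibody-mentioning specificity snippet against its antibody
aspect, scores every within-document (specificity, RRID) snippet pair with the
selected linker, and emits one knowledge-base entry per linked pair whose class
is not neutral: a triple (antibody RRID, specificity class, evidence snippet).
Neutral snippets are excluded from the knowledge base but retained in the joint
predictions so the workflow can be scored against gold triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .documents import Document
from .snippets import (
    RRIDSnippet,
    SpecSnippet,
    extract_rrid_snippets,
    extract_spec_snippets,
    filter_antibody_snippets,
)
from .linking import LinkPrediction, SnippetPair

__all__ = ["KBEntry", "run_workflow", "assemble_entries", "write_kb", "read_kb"]

KB_SCHEMA_VERSION = 1

# classify(snippet_text, aspect|None) -> (label, probability of that label)
Classifier = Callable[[str, str | None], tuple[str, float]]
# link(pair) -> LinkPrediction
Linker = Callable[[SnippetPair], LinkPrediction]


@dataclass(frozen=True)
class KBEntry:
    """One knowledge-base triple with its provenance and model confidences."""

    rrid: str
    specificity: str
    evidence: str
    doc_id: str
    class_probability: float
    link_probability: float

    def __post_init__(self) -> None:
        if self.specificity == "neutral":
            raise ValueError("neutral snippets are excluded from the knowledge base")
        if self.specificity not in ("nonspecific", "specific"):
            raise ValueError(f"unknown specificity class {self.specificity!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")


@dataclass(frozen=True)
class JointPrediction:
    """Per-pair prediction kept for evaluation (neutral retained here)."""

    pair_id: tuple[str, int, str]  # (doc_id, spec snippet position, rrid)
    link: str
    specificity: str
    link_probability: float
    class_probability: float


def run_workflow(
    documents: Sequence[Document],
    classify: Classifier,
    link: Linker,
) -> tuple[list[KBEntry], list[JointPrediction]]:
    """Run the full extract/classify/link workflow over parsed documents.

    Returns knowledge-base entries (non-neutral, linked) plus the complete
    joint predictions over every within-document snippet pair.
    """
    if not documents:
        raise ValueError("no documents to process")
    entries: list[KBEntry] = []
    joint: list[JointPrediction] = []
    for doc in documents:
        spec_snips = filter_antibody_snippets(extract_spec_snippets(doc))
        rrid_snips = extract_rrid_snippets(doc)
        classified: list[tuple[int, SpecSnippet, str, float]] = []
        for pos, sn in enumerate(spec_snips):
            label, prob = classify(sn.text, None)
            classified.append((pos, sn, label, prob))
        decisions: dict[tuple[int, str], tuple[LinkPrediction, RRIDSnippet]] = {}
        for pos, sn, label, prob in classified:
            for rn in rrid_snips:
                pair = SnippetPair(spec_text=sn.text, rrid_text=rn.text, rrid=rn.rrid)
                pred = link(pair)
                decisions[(pos, rn.rrid)] = (pred, rn)
                joint.append(
                    JointPrediction(
                        pair_id=(doc.doc_id, pos, rn.rrid),
                        link=pred.decision,
                        specificity=label,
                        link_probability=pred.probability_yes,
                        class_probability=prob,
                    )
                )
        entries.extend(
            assemble_entries(
                [(pos, sn, label, prob) for pos, sn, label, prob in classified],
                decisions,
                doc_id=doc.doc_id,
            )
        )
    return entries, joint


def assemble_entries(
    classified: Sequence[tuple[int, SpecSnippet, str, float]],
    decisions: dict[tuple[int, str], tuple[LinkPrediction, RRIDSnippet]],
    doc_id: str,
) -> list[KBEntry]:
    """Turn classified snippets plus link decisions into knowledge-base entries.

    One entry per linked (snippet, RRID) pair; neutral snippets are dropped; a
    snippet may link to several RRIDs.  Output is ordered by snippet position
    then RRID.
    """
    by_pos = {pos: (sn, label, prob) for pos, sn, label, prob in classified}
    for (pos, _rrid) in decisions:
        if pos not in by_pos:
            raise ValueError(f"link decision refers to unknown snippet position {pos}")
    entries: list[KBEntry] = []
    for (pos, rrid) in sorted(decisions, key=lambda k: (k[0], k[1])):
        pred, _rn = decisions[(pos, rrid)]
        sn, label, prob = by_pos[pos]
        if pred.decision != "yes" or label == "neutral":
            continue
        entries.append(
            KBEntry(
                rrid=rrid,
                specificity=label,
                evidence=sn.text,
                doc_id=doc_id,
                class_probability=prob,
                link_probability=pred.probability_yes,
            )
        )
    return entries


def write_kb(entries: Iterable[KBEntry], path: str | Path) -> None:
    """Write entries as JSONL with a schema-versioned header line."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"schema": "kb", "version": KB_SCHEMA_VERSION}) + "\n")
            for e in entries:
                fh.write(
                    json.dumps(
                        {
                            "rrid": e.rrid,
                            "specificity": e.specificity,
                            "evidence": e.evidence,
                            "doc_id": e.doc_id,
                            "class_probability": e.class_probability,
                            "link_probability": e.link_probability,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write knowledge base to {path}: {exc}") from exc


def read_kb(path: str | Path) -> list[KBEntry]:
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("schema") != "kb":
            raise ValueError(f"{path} is not a knowledge-base file")
        return [
            KBEntry(**json.loads(line))
            for line in fh
            if line.strip()
        ]
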